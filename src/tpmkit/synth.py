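"""Seeded synthetic-data generators with recorded ground truth.

Every generator is a pure function of its arguments (seed included) and
returns ``(data, truth)`` where ``truth`` is a JSON-serializable record of
the parameters that generated the data.  ``write`` helpers emit the data
file plus a ``<stem>.truth.json`` sidecar, so downstream pipelines can never
accidentally read the answer out of the data file itself.

What the generators emulate, and what they do not:

* ``gen_coiled_coil`` / ``gen_overlap_bundle`` / ``gen_trajectory`` stand in
  for structures and production-run snapshots of a head-to-tail coiled-coil
  overlap junction.  The bundle is two ideal dimers sharing one continuous
  superhelical phase, placed side by side; the imposed twist/bend/radial
  offsets are exact rigid transformations, not force-field dynamics.
* ``gen_melt_curve`` emulates a CD thermal melt at 222 nm, 20-65 degC:
  logistic two-state transitions on sloped linear baselines plus Gaussian
  noise.  No thermodynamic model (dH, heat-capacity baseline curvature) is
  implied.
* ``gen_isotherm`` emulates a co-sedimentation saturation-binding series
  (2-fold serial dilutions, 0.25-64 uM) read out by scintillation counting:
  a one-site hyperbola converted to expected dpm through the specific
  activity, Poisson-sampled, with a constant instrument background.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import dpm_per_uM
from .coilgeom import JunctionSpec
from .errors import ClashError, ParameterError
from .modeler import CrickParameters, crick_ca_coords
from .structure import Atom, Chain, Residue, Structure, write_pdb


def _truth_json(truth: dict) -> dict:
    def conv(x):
        if is_dataclass(x):
            return asdict(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        return x

    return conv(truth)


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_truth_json(truth), indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def _structure_from_chain_coords(chain_coords, chain_start, res_name="ALA") -> Structure:
    chains = []
    for cid, xyz in chain_coords.items():
        start = chain_start[cid]
        residues = [
            Residue(seq_id=start + i, name=res_name, atoms=[Atom("CA", "C", c)])
            for i, c in enumerate(np.asarray(xyz, float))
        ]
        chains.append(Chain(chain_id=cid, residues=residues))
    return Structure(models=[chains])


def gen_coiled_coil(
    seed: int = 0,
    params: CrickParameters | None = None,
    n_residues: int = 60,
    jitter_sd: float = 0.0,
    chain_ids: Sequence[str] | None = None,
    start_res: int = 1,
) -> tuple[Structure, dict]:
    """Ideal coiled coil with optional isotropic coordinate jitter."""
    params = params or CrickParameters()
    rng = np.random.default_rng(seed)
    if chain_ids is None:
        chain_ids = [chr(ord("A") + k) for k in range(params.n_chains)]
    coords = {}
    for cid, off in zip(chain_ids, params.offsets):
        xyz = crick_ca_coords(params, n_residues, chain_offset_deg=off)
        if jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, jitter_sd, size=xyz.shape)
        coords[cid] = xyz
    st = _structure_from_chain_coords(coords, {c: start_res for c in chain_ids})
    truth = {
        "kind": "coiled_coil",
        "seed": seed,
        "params": params,
        "n_residues": n_residues,
        "jitter_sd": jitter_sd,
        "chain_ids": list(chain_ids),
    }
    return st, truth


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


@dataclass(frozen=True)
class BundleLayout:
    """Residue bookkeeping of the synthetic 4-helix overlap bundle.

    The C-terminal dimer covers global residue indices [0, side_len +
    overlap_len); the N-terminal dimer covers [side_len, 2*side_len +
    overlap_len), i.e. the two dimers coexist over ``overlap_len`` residues
    around the junction midpoint.  Author numbering restarts at
    ``n_start_res`` / ``c_start_res`` per side (mirroring an N-terminal
    fragment numbered from 1 against a C-terminal fragment numbered from
    169).
    """

    side_len: int = 45
    overlap_len: int = 8
    n_start_res: int = 1
    c_start_res: int = 169
    n_chain_ids: tuple[str, str] = ("A", "B")
    c_chain_ids: tuple[str, str] = ("C", "D")

    @property
    def c_len(self) -> int:
        return self.side_len + self.overlap_len

    @property
    def n_len(self) -> int:
        return self.side_len + self.overlap_len

    def junction_spec(self, flank: int = 15, gap: int = 2, reference: str = "extrapolate") -> JunctionSpec:
        """Flank windows just outside the interdigitated overlap."""
        n_lo = self.n_start_res + self.overlap_len + gap
        c_hi = self.c_start_res + self.side_len - 1 - gap
        return JunctionSpec(
            n_chains=self.n_chain_ids,
            c_chains=self.c_chain_ids,
            n_flank=(n_lo, n_lo + flank - 1),
            c_flank=(c_hi - flank + 1, c_hi),
            reference=reference,
        )


def gen_overlap_bundle(
    seed: int = 0,
    theta: float = 0.0,
    omega: float = 0.0,
    radial_displacement: dict[str, float] | None = None,
    params: CrickParameters | None = None,
    layout: BundleLayout | None = None,
    n_radial_bulge: float = 6.5,
    jitter_sd: float = 0.0,
    clash_cutoff: float = 2.0,
) -> tuple[Structure, dict]:
    """Two ideal dimers forming a head-to-tail junction with imposed twist
    theta (about the junction axis) and bend omega (about a perpendicular
    axis), both applied to the N-terminal dimer about the junction midpoint.

    Both dimers share one continuous superhelical phase and axis, so with
    theta = omega = 0 the measured junction angles are zero.  The N-side is
    built at superhelical radius r0 + ``n_radial_bulge`` so its helices run
    just outside the C-side helices through the interdigitated span instead
    of colliding with them (changes neither angle).  ``radial_displacement``
    maps chain ids to an additional outward radial offset in Angstrom,
    realized the same way.
    """
    if not -180.0 < theta <= 180.0:
        raise ParameterError("theta must be in (-180, 180]")
    if not 0.0 <= omega <= 60.0:
        raise ParameterError("omega must be in [0, 60]")
    params = params or CrickParameters()
    layout = layout or BundleLayout()
    disp = radial_displacement or {}
    rng = np.random.default_rng(seed)

    # junction midpoint sits at global index side_len + overlap_len/2
    g_mid = layout.side_len + layout.overlap_len / 2.0
    transform = _rot_x(omega) @ _rot_z(theta)

    coords: dict[str, np.ndarray] = {}
    starts: dict[str, int] = {}
    for side, cids, g0, length, start in (
        ("c", layout.c_chain_ids, 0, layout.c_len, layout.c_start_res),
        ("n", layout.n_chain_ids, layout.side_len, layout.n_len, layout.n_start_res),
    ):
        for cid, off in zip(cids, params.offsets):
            bulge = (n_radial_bulge if side == "n" else 0.0) + disp.get(cid, 0.0)
            xyz = crick_ca_coords(
                params,
                length,
                chain_offset_deg=off,
                index_offset=g0 - g_mid,  # z = 0 at the junction midpoint
                r0_override=params.r0 + bulge if bulge else None,
            )
            if side == "n":
                xyz = xyz @ transform.T
            if jitter_sd > 0:
                xyz = xyz + rng.normal(0.0, jitter_sd, size=xyz.shape)
            coords[cid] = xyz
            starts[cid] = start
    # hard-sphere sanity between the two dimers
    c_all = np.concatenate([coords[c] for c in layout.c_chain_ids])
    n_all = np.concatenate([coords[c] for c in layout.n_chain_ids])
    dmin = np.sqrt(
        np.min(np.sum((c_all[:, None, :] - n_all[None, :, :]) ** 2, axis=2))
    )
    if dmin < clash_cutoff:
        raise ClashError(f"inter-dimer CA clash: min distance {dmin:.2f} A < {clash_cutoff} A")

    order = list(layout.n_chain_ids) + list(layout.c_chain_ids)
    st = _structure_from_chain_coords({c: coords[c] for c in order}, starts)
    truth = {
        "kind": "overlap_bundle",
        "seed": seed,
        "theta_deg": theta,
        "omega_deg": omega,
        "radial_displacement": dict(disp),
        "params": params,
        "layout": layout,
        "n_radial_bulge": n_radial_bulge,
        "jitter_sd": jitter_sd,
    }
    return st, truth


def gen_trajectory(
    seed: int = 0,
    n_frames: int = 35,
    theta_start: float = 0.0,
    theta_target: float = 15.0,
    omega_start: float = 0.0,
    omega_target: float = 8.0,
    convergence_frame: int = 10,
    angle_noise_sd: float = 2.0,
    jitter_sd: float = 0.0,
    **bundle_kwargs,
) -> tuple[Structure, dict]:
    """Multi-frame bundle whose angles drift to a target and then fluctuate.

    Frames f < ``convergence_frame`` interpolate linearly from the start to
    the target angles; later frames sit at the target.  Gaussian noise of SD
    ``angle_noise_sd`` (degrees) is added to both angles in every frame;
    the default of 2 degrees reflects the few-degree frame-to-frame
    fluctuation typical of junction-angle traces from production runs.  One frame per "ns" is the intended reading of the
    default 35 frames.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if convergence_frame < 0:
        raise ParameterError("convergence_frame must be >= 0")
    rng = np.random.default_rng(seed)
    frac = np.minimum(np.arange(n_frames) / max(convergence_frame, 1), 1.0)
    theta_f = theta_start + (theta_target - theta_start) * frac
    omega_f = omega_start + (omega_target - omega_start) * frac
    theta_f = theta_f + rng.normal(0.0, angle_noise_sd, n_frames)
    omega_f = np.abs(omega_f + rng.normal(0.0, angle_noise_sd, n_frames))

    models = []
    for f in range(n_frames):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        frame_st, _ = gen_overlap_bundle(
            seed=sub_seed,
            theta=float(theta_f[f]),
            omega=float(omega_f[f]),
            jitter_sd=jitter_sd,
            **bundle_kwargs,
        )
        models.append(frame_st.models[0])
    st = Structure(models=models)
    truth = {
        "kind": "trajectory",
        "seed": seed,
        "n_frames": n_frames,
        "theta_target": theta_target,
        "omega_target": omega_target,
        "theta_per_frame": theta_f,
        "omega_per_frame": omega_f,
        "convergence_frame": convergence_frame,
        "angle_noise_sd": angle_noise_sd,
        "jitter_sd": jitter_sd,
        "layout": bundle_kwargs.get("layout") or BundleLayout(),
    }
    return st, truth


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------


def gen_melt_curve(
    seed: int = 0,
    tms: Sequence[float] = (44.4,),
    widths: Sequence[float] = (2.0,),
    weights: Sequence[float] | None = None,
    t_min: float = 20.0,
    t_max: float = 65.0,
    step: float = 0.5,
    amplitude: float = 22.0,
    baseline_folded: tuple[float, float] = (-30.0, 0.05),
    baseline_unfolded_slope: float = 0.02,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Two-state (or multi-transition) CD melt curves in mdeg.

    ``widths`` are the widths of the unfolding transitions expressed as the
    standard deviation (degC) of the derivative peak, i.e. directly
    comparable to the sigma of a fitted Gaussian component; internally each
    is converted to the logistic scale s = width * sqrt(3) / pi.

    The fraction unfolded is a mixture of logistic transitions,
    f(T) = sum_k w_k / (1 + exp(-(T - Tm_k)/s_k)), and the signal is the
    canonical two-state mixture (1 - f) * folded(T) + f * unfolded(T) with
    linear baselines.  The unfolded baseline starts ``amplitude`` mdeg above
    the folded one (CD at 222 nm is strongly negative when helical) with its
    own slope.  ``noise_sd`` is Gaussian noise expressed as a fraction of
    ``amplitude`` (so 0.02 means 2% of the transition height).
    ``amplitude=0`` yields a flat, featureless curve.
    """
    tms, widths = list(tms), list(widths)
    if len(tms) != len(widths):
        raise ParameterError("need one width per transition")
    if weights is None:
        weights = [1.0 / len(tms)] * len(tms)
    if len(weights) != len(tms) or abs(sum(weights) - 1.0) > 1e-9:
        raise ParameterError("weights must match transitions and sum to 1")
    for tm in tms:
        if not t_min < tm < t_max:
            raise ParameterError(f"Tm {tm} outside the temperature grid {t_min}-{t_max}")
    rng = np.random.default_rng(seed)
    temp = np.arange(t_min, t_max + step / 2, step)
    b0, b_slope = baseline_folded
    folded = b0 + b_slope * (temp - t_min)
    unfolded = b0 + amplitude + baseline_unfolded_slope * (temp - t_min)
    frac = np.zeros_like(temp)
    scales = [w * np.sqrt(3.0) / np.pi for w in widths]
    for tm, s_k, wt in zip(tms, scales, weights):
        frac = frac + wt / (1.0 + np.exp(-(temp - tm) / s_k))
    base = (1.0 - frac) * folded + frac * unfolded
    rows = []
    for rep in range(n_replicates):
        sig = base + rng.normal(0.0, noise_sd * amplitude if amplitude else noise_sd, temp.shape)
        rows.append(
            pd.DataFrame(
                {"temperature_C": temp, "signal": sig, "replicate": rep}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    truth = {
        "kind": "melt_curve",
        "seed": seed,
        "tm_C": tms,
        "width_sigma_C": widths,
        "logistic_scale_C": scales,
        "weights": list(weights),
        "amplitude": amplitude,
        "noise_sd_fraction": noise_sd,
        "grid": [t_min, t_max, step],
        "n_replicates": n_replicates,
    }
    return df, truth


# ---------------------------------------------------------------------------
# binding isotherms
# ---------------------------------------------------------------------------


def serial_dilutions(top: float = 64.0, n: int = 9, factor: float = 2.0) -> np.ndarray:
    """Descending serial-dilution series, e.g. 64, 32, ..., 0.25 uM."""
    return top / factor ** np.arange(n)


def gen_isotherm(
    seed: int = 0,
    kd: float = 2.0,
    bmax_uM: float = 5.0,
    tpm_dimer_uM: float = 5.0,
    concentrations: Sequence[float] | None = None,
    n_replicates: int = 4,
    specific_activity: float = 125.0,
    volume_l: float = 25e-6,
    efficiency: float = 1.0,
    counting_noise: bool = True,
    background_dpm: float = 30.0,
    post_fraction: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One-site saturation isotherm read out as scintillation counts.

    bound(L) = Bmax * L / (Kd + L) with L the free ligand concentration.
    The bound amount is converted to expected dpm through the specific
    activity (mCi/mmol) and sample volume, Poisson-sampled when
    ``counting_noise``, and a constant ``background_dpm`` is added.  The
    table carries both raw counts and the background-subtracted ``bound_uM``
    an analyst would compute.  ``post_fraction`` adds a second condition
    whose binding is that fraction of the pre-incubation curve (the
    preformed-filament control where incorporation stays near background).
    """
    if kd <= 0 or bmax_uM <= 0:
        raise ParameterError("kd and bmax must be positive")
    conc = np.asarray(
        concentrations if concentrations is not None else serial_dilutions(), dtype=float
    )
    if conc.ndim != 1 or len(conc) < 4 or np.any(conc < 0):
        raise ParameterError("need >=4 non-negative concentrations")
    rng = np.random.default_rng(seed)
    scale = dpm_per_uM(specific_activity, volume_l)

    def sample(bound_expected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dpm_expected = bound_expected * scale + background_dpm
        if counting_noise:
            dpm_obs = rng.poisson(dpm_expected).astype(float)
        else:
            dpm_obs = dpm_expected
        counts = dpm_obs * efficiency
        bound_uM = (dpm_obs - background_dpm) / scale
        return counts, bound_uM

    rows = []
    conditions = [("pre_incubation", 1.0)]
    if post_fraction is not None:
        conditions.append(("post_incubation", post_fraction))
    for cond, frac in conditions:
        expected = frac * bmax_uM * conc / (kd + conc)
        for rep in range(n_replicates):
            counts, bound = sample(expected)
            rows.append(
                pd.DataFrame(
                    {
                        "concentration_uM": conc,
                        "counts_cpm": counts,
                        "bound_uM": bound,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    truth = {
        "kind": "isotherm",
        "seed": seed,
        "kd_uM": kd,
        "bmax_uM": bmax_uM,
        "tpm_dimer_uM": tpm_dimer_uM,
        "stoichiometry": bmax_uM / tpm_dimer_uM,
        "concentrations_uM": conc,
        "n_replicates": n_replicates,
        "specific_activity_mCi_per_mmol": specific_activity,
        "volume_l": volume_l,
        "efficiency": efficiency,
        "counting_noise": counting_noise,
        "background_dpm": background_dpm,
        "post_fraction": post_fraction,
    }
    return df, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_structure_with_truth(st: Structure, truth: dict, out_dir: str | Path, stem: str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"{stem}.pdb"
    write_pdb(st, pdb)
    tj = write_truth(truth, out_dir / f"{stem}.truth.json")
    return {"data": str(pdb), "truth": str(tj)}


def write_table_with_truth(df: pd.DataFrame, truth: dict, out_dir: str | Path, stem: str) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv = out_dir / f"{stem}.csv"
    df.to_csv(csv, index=False, float_format="%.6g")
    tj = write_truth(truth, out_dir / f"{stem}.truth.json")
    return {"data": str(csv), "truth": str(tj)}
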