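"""Coiled-coil geometry measurements.

Implements the measurement side of the pipeline:

* per-residue local helix-axis points from CA coordinates (three-point
  bisector construction, the same family of constructions used by Twister-
  style coiled-coil analysis),
* central axis of a helix pair/bundle and per-residue coiled-coil radius,
* overlap-junction bend (omega) and twist (theta) angles, per frame and as
  trajectory summaries,
* Kabsch least-squares superposition with range-restricted RMSD,
* ligand heavy-atom contact maps.

Angle conventions
-----------------
For a head-to-tail overlap junction the two C-terminal chains approach the
junction from one side and the two N-terminal chains leave it on the other;
residue numbering increases in the same spatial direction on both sides.
``omega`` is the unsigned angle in degrees between straight axes fitted to
the two flanking coiled coils (0 for a straight junction).  ``theta`` is the
signed rotation, right-hand rule about the junction axis oriented from the
C-flank toward the N-flank, of the N-flank's inter-helix vector relative to
the C-flank's.  Because the inter-helix vector precesses with the
superhelical phase, each flank's vector azimuth is fit linearly against the
axial coordinate and extrapolated to the junction midpoint before the two
flanks are differenced; this removes the trivial phase advance along the
coil so a continuous, undisturbed coiled coil measures theta = 0.  The
literal single-residue variant (``reference="nearest"``) is also provided.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    InsufficientInputError,
    ParameterError,
    SelectionError,
    TrajectoryError,
    WindowError,
)
from .structure import Chain, Selection, Structure, select_atoms

# ---------------------------------------------------------------------------
# local helix axes
# ---------------------------------------------------------------------------


@dataclass
class AxisTrace:
    """Per-residue local helix-axis points for one helix.

    ``residue_ids[i]`` is the author residue number whose axis point is
    ``points[i]``.  Terminal residues carry no axis point.
    """

    residue_ids: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.residue_ids) != len(self.points):
            raise AlignmentError("residue ids and axis points differ in length")


def local_axis_points(ca: np.ndarray) -> np.ndarray:
    """Axis points for the interior residues of a run of consecutive CAs.

    For residue i the unit bisector A_i of the angle CA(i-1)-CA(i)-CA(i+1)
    points toward the local helix axis.  Consecutive bisectors A_i, A_(i+1)
    define the local axis direction; the local helix radius r1 follows from
    requiring the axis segment between the two axis points to be
    perpendicular to both bisectors.  Input of n CAs yields n-2 axis points
    (residues 1..n-2, 0-based).
    """
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    if n < 4:
        raise InsufficientInputError(f"need >=4 consecutive CA atoms, got {n}")
    prev = ca[:-2] - ca[1:-1]
    nxt = ca[2:] - ca[1:-1]
    prev /= np.linalg.norm(prev, axis=1, keepdims=True)
    nxt /= np.linalg.norm(nxt, axis=1, keepdims=True)
    bis = prev + nxt
    norms = np.linalg.norm(bis, axis=1, keepdims=True)
    if np.any(norms < 1e-8):
        raise DegenerateGeometryError("collinear CA triple: local axis undefined")
    bis /= norms  # bis[k] is the bisector at residue k+1 (0-based)

    pts = np.empty((n - 2, 3))
    d = ca[2:-1] - ca[1:-2]           # CA(i+1) - CA(i) for interior pairs
    a0 = bis[:-1]                      # bisector at i
    a1 = bis[1:]                       # bisector at i+1
    diff = a1 - a0
    # least-squares r from [(d + r*diff).a0 = 0, (d + r*diff).a1 = 0]
    m0 = np.einsum("ij,ij->i", diff, a0)
    m1 = np.einsum("ij,ij->i", diff, a1)
    b0 = -np.einsum("ij,ij->i", d, a0)
    b1 = -np.einsum("ij,ij->i", d, a1)
    denom = m0 * m0 + m1 * m1
    if np.any(denom < 1e-12):
        raise DegenerateGeometryError("parallel bisectors: straight-segment input")
    r = (m0 * b0 + m1 * b1) / denom
    pts[:-1] = ca[1:-2] + r[:, None] * a0
    pts[-1] = ca[-2] + r[-1] * bis[-1]
    return pts


def fit_local_axes(
    chain: Chain,
    residue_range: tuple[int, int] | None = None,
    atom_name: str = "CA",
) -> AxisTrace:
    """Local axis points for (a residue range of) one chain.

    The range must be a run of consecutively numbered residues each carrying
    the requested atom.
    """
    resids, coords = [], []
    for r in chain.residues:
        if residue_range is not None and not residue_range[0] <= r.seq_id <= residue_range[1]:
            continue
        a = r.atom(atom_name)
        if a is None:
            raise SelectionError(f"chain {chain.chain_id} residue {r.seq_id}: no atom {atom_name}")
        resids.append(r.seq_id)
        coords.append(a.coords)
    if len(resids) < 4:
        raise InsufficientInputError(
            f"chain {chain.chain_id}: {len(resids)} {atom_name} atoms in range, need >=4"
        )
    resids = np.asarray(resids)
    if np.any(np.diff(resids) != 1):
        raise AlignmentError(f"chain {chain.chain_id}: residue numbering has gaps in range")
    pts = local_axis_points(np.asarray(coords))
    return AxisTrace(residue_ids=resids[1:-1], points=pts)


def central_axis(
    traces: Sequence[AxisTrace],
    offsets: Sequence[int] | None = None,
) -> AxisTrace:
    """Mean of the member helices' axis points at aligned residues.

    ``offsets[k]`` is subtracted from trace k's residue ids before aligning,
    so helices with different author numbering (e.g. an N-terminal chain
    starting at 1 against a C-terminal chain starting at 169) can be paired.
    The returned trace carries the common (offset-corrected) ids.
    """
    if len(traces) < 2:
        raise AlignmentError("central axis needs >=2 helices")
    if offsets is None:
        offsets = [0] * len(traces)
    if len(offsets) != len(traces):
        raise AlignmentError("one offset per trace required")
    shifted = [t.residue_ids - o for t, o in zip(traces, offsets)]
    common = shifted[0]
    for ids in shifted[1:]:
        common = np.intersect1d(common, ids)
    if len(common) == 0:
        raise AlignmentError("helix axis traces share no aligned residues")
    stacked = []
    for t, ids in zip(traces, shifted):
        idx = np.searchsorted(ids, common)
        stacked.append(t.points[idx])
    return AxisTrace(residue_ids=common, points=np.mean(stacked, axis=0))


# ---------------------------------------------------------------------------
# radius profiles
# ---------------------------------------------------------------------------


@dataclass
class RadiusProfile:
    """Per-residue coiled-coil radius, per chain and per frame.

    ``radii`` has shape (n_frames, n_chains, n_residues).  ``mean``/``sd``
    are over frames (sd is None for a single frame).
    """

    residue_ids: np.ndarray
    chain_ids: list[str]
    frames: list[int]
    radii: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.radii.mean(axis=0)

    @property
    def sd(self) -> np.ndarray | None:
        if len(self.frames) < 2:
            return None
        return self.radii.std(axis=0, ddof=1)

    @property
    def helix_averaged(self) -> np.ndarray:
        """Radius averaged over member helices, then over frames."""
        return self.radii.mean(axis=(0, 1))

    def to_frame(self):
        """Long-form pandas DataFrame (frame, chain, residue, radius)."""
        import pandas as pd

        rows = []
        for fi, f in enumerate(self.frames):
            for ci, cid in enumerate(self.chain_ids):
                for ri, rid in enumerate(self.residue_ids):
                    rows.append((f, cid, int(rid), self.radii[fi, ci, ri]))
        return pd.DataFrame(rows, columns=["frame", "chain", "residue", "radius_A"])


def last_third(n_frames: int) -> range:
    """Frame window covering the final third of a trajectory (>=1 frame)."""
    return range(n_frames - max(1, n_frames // 3), n_frames)


def _resolve_frames(structure: Structure, frames: Iterable[int] | None) -> list[int]:
    if frames is None:
        return list(range(structure.n_models))
    frames = list(frames)
    if not frames:
        raise WindowError("empty frame window")
    bad = [f for f in frames if not 0 <= f < structure.n_models]
    if bad:
        raise WindowError(f"frame indices {bad} outside 0..{structure.n_models - 1}")
    return frames


def radius_profile(
    structure: Structure,
    pairing: Sequence[str],
    residue_range: tuple[int, int] | None = None,
    frames: Iterable[int] | None = None,
    offsets: Sequence[int] | None = None,
) -> RadiusProfile:
    """Per-residue distance of each helix's local axis from the central axis.

    ``pairing`` lists the chains forming the coiled coil (2 for a dimer, 4
    for the overlap bundle); ``offsets`` aligns their numbering as in
    :func:`central_axis`.  Multi-frame structures yield per-frame radii with
    mean and SD available on the result.
    """
    if len(pairing) < 2:
        raise AlignmentError("pairing requires >=2 chains")
    frame_list = _resolve_frames(structure, frames)
    if structure.n_models > 1:
        structure.assert_consistent_topology()
    all_radii = []
    common_ids = None
    for f in frame_list:
        traces = [
            fit_local_axes(structure.chain(cid, f), residue_range=residue_range)
            for cid in pairing
        ]
        center = central_axis(traces, offsets=offsets)
        ids = center.residue_ids
        if common_ids is None:
            common_ids = ids
        per_chain = []
        offs = offsets or [0] * len(traces)
        for t, o in zip(traces, offs):
            idx = np.searchsorted(t.residue_ids - o, ids)
            per_chain.append(np.linalg.norm(t.points[idx] - center.points, axis=1))
        all_radii.append(per_chain)
    return RadiusProfile(
        residue_ids=common_ids,
        chain_ids=list(pairing),
        frames=frame_list,
        radii=np.asarray(all_radii),
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Kabsch least-squares rigid-body fit of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation superposition (Kabsch, SVD form).

    Returns the rotation/translation mapping ``mobile`` onto ``reference``
    and the post-fit RMSD over the paired atoms.
    """
    mob = np.asarray(mobile, float).reshape(-1, 3)
    ref = np.asarray(reference, float).reshape(-1, 3)
    if len(mob) != len(ref):
        raise AlignmentError(f"point sets differ in length: {len(mob)} vs {len(ref)}")
    if len(mob) < 3:
        raise InsufficientInputError("superposition needs >=3 paired points")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(mob))


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    selection: Selection,
    mobile_selection: Selection | None = None,
    model_index: int = 0,
    skip_missing_atoms: bool = False,
) -> SuperpositionResult:
    """Range-restricted superposition of two structures.

    The same selection is applied to both unless ``mobile_selection`` is
    given (different chain labels / numbering between the two entries).
    """
    from .structure import select_coords

    ref = select_coords(reference, selection, model_index, skip_missing_atoms)
    mob = select_coords(mobile, mobile_selection or selection, model_index, skip_missing_atoms)
    return superpose(mob, ref)


# ---------------------------------------------------------------------------
# overlap-junction angles
# ---------------------------------------------------------------------------


@dataclass
class JunctionSpec:
    """Names the four junction chains and the flanking windows.

    ``c_chains``/``n_chains`` are the chain-id pairs of the C-terminal and
    N-terminal coiled coils; ``c_flank``/``n_flank`` are inclusive residue
    windows on those chains, outside the interdigitated overlap itself.
    Flank windows must span at least :data:`MIN_FLANK` residues for the
    straight-axis fit to be meaningful.
    """

    MIN_FLANK = 5

    n_chains: tuple[str, str]
    c_chains: tuple[str, str]
    n_flank: tuple[int, int]
    c_flank: tuple[int, int]
    reference: Literal["extrapolate", "nearest"] = "extrapolate"

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("n_flank", self.n_flank), ("c_flank", self.c_flank)):
            if hi - lo + 1 < self.MIN_FLANK:
                raise WindowError(f"{name} {lo}-{hi} spans {hi - lo + 1} residues; need >={self.MIN_FLANK}")

    def swapped_roles(self) -> "JunctionSpec":
        """The same junction with the N/C roles exchanged (theta negates)."""
        return JunctionSpec(
            n_chains=self.c_chains,
            c_chains=self.n_chains,
            n_flank=self.c_flank,
            c_flank=self.n_flank,
            reference=self.reference,
        )


@dataclass
class OverlapGeometry:
    """Twist/bend of one frame; theta in (-180, 180], omega in [0, 180]."""

    theta: float
    omega: float
    frame_index: int = 0


@dataclass
class AngleSeries:
    frames: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    window: np.ndarray
    summary: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frame": self.frames, "theta_deg": self.theta, "omega_deg": self.omega})


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points; direction oriented along the
    point order (first -> last)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    direction = vt[0]
    if direction @ (points[-1] - points[0]) < 0:
        direction = -direction
    return centroid, direction


def _minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rodrigues rotation taking unit vector v_from onto v_to."""
    c = float(np.clip(v_from @ v_to, -1.0, 1.0))
    axis = np.cross(v_from, v_to)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)  # antiparallel is degenerate
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _wrap_angle(deg: float) -> float:
    """Map to (-180, 180]."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def _flank_data(structure, chains, flank, model_index):
    traces = [
        fit_local_axes(structure.chain(cid, model_index), residue_range=flank)
        for cid in chains
    ]
    center = central_axis(traces)
    ids = center.residue_ids
    idx = [np.searchsorted(t.residue_ids, ids) for t in traces]
    inter = traces[0].points[idx[0]] - traces[1].points[idx[1]]
    return center, inter


def overlap_angles(
    structure: Structure,
    spec: JunctionSpec,
    model_index: int = 0,
) -> OverlapGeometry:
    """Bend (omega) and signed twist (theta) of an overlap junction frame.

    See the module docstring for the exact conventions.  Flank axes are
    total-least-squares lines through the flank's central-axis points; the
    junction axis is the bisector of the two flank directions, oriented
    C-flank -> N-flank.
    """
    c_center, c_inter = _flank_data(structure, spec.c_chains, spec.c_flank, model_index)
    n_center, n_inter = _flank_data(structure, spec.n_chains, spec.n_flank, model_index)

    c0, d_c = _tls_line(c_center.points)
    n0, d_n = _tls_line(n_center.points)
    omega = float(np.degrees(np.arccos(np.clip(d_c @ d_n, -1.0, 1.0))))

    axis = d_c + d_n
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError("flank axes are antiparallel; junction axis undefined")
    axis /= norm
    # deterministic basis perpendicular to the junction axis
    seed = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    # junction pivot: mutual closest-approach point of the two flank axes,
    # expressed per flank along its own axis.  For (nearly) parallel flanks
    # the closest approach is degenerate; project the gap midpoint instead.
    b = float(d_c @ d_n)
    w0 = n0 - c0
    denom = 1.0 - b * b
    if denom > 1e-6:
        rhs = np.array([d_c @ w0, d_n @ w0])
        s_c, s_n = np.linalg.solve(np.array([[1.0, -b], [b, -1.0]]), rhs)
        p_c = c0 + s_c * d_c
        p_n = n0 + s_n * d_n
    else:
        mid = 0.5 * (c_center.points[-1] + n_center.points[0])
        p_c = c0 + ((mid - c0) @ d_c) * d_c
        p_n = n0 + ((mid - n0) @ d_n) * d_n

    thetas = {}
    for label, center, inter, d, pivot in (
        ("c", c_center, c_inter, d_c, p_c),
        ("n", n_center, n_inter, d_n, p_n),
    ):
        rot = _minimal_rotation(d, axis)
        w = inter @ rot.T
        s = (center.points - pivot) @ d
        alpha = np.unwrap(np.arctan2(w @ e2, w @ e1))
        if spec.reference == "nearest":
            # flank residue nearest the junction pivot
            k = int(np.argmin(np.abs(s)))
            thetas[label] = alpha[k]
        else:
            coef = np.polyfit(s, alpha, 1)
            thetas[label] = float(np.polyval(coef, 0.0))
    theta = _wrap_angle(float(np.degrees(thetas["n"] - thetas["c"])))
    return OverlapGeometry(theta=theta, omega=omega, frame_index=model_index)


def angle_time_series(
    structure: Structure,
    spec: JunctionSpec,
    frame_window: Iterable[int] | None = None,
) -> AngleSeries:
    """Per-frame theta/omega plus mean and SD over a frame window.

    The default window is the last third of frames, the package's analogue
    of averaging the tail of a production run once the geometry has
    converged.
    """
    if structure.n_models < 2:
        raise TrajectoryError("angle time series needs >=2 frames")
    structure.assert_consistent_topology()
    frames = np.arange(structure.n_models)
    geos = [overlap_angles(structure, spec, model_index=f) for f in frames]
    theta = np.array([g.theta for g in geos])
    omega = np.array([g.omega for g in geos])
    window = np.asarray(
        list(frame_window) if frame_window is not None else list(last_third(structure.n_models))
    )
    if window.size == 0:
        raise WindowError("empty frame window")
    if np.any((window < 0) | (window >= structure.n_models)):
        raise WindowError("frame window outside trajectory")
    summary = {
        "n_frames": int(window.size),
        "window": [int(window.min()), int(window.max())],
        "theta_mean": float(theta[window].mean()),
        "theta_sd": float(theta[window].std(ddof=1)) if window.size > 1 else 0.0,
        "omega_mean": float(omega[window].mean()),
        "omega_sd": float(omega[window].std(ddof=1)) if window.size > 1 else 0.0,
    }
    return AngleSeries(frames=frames, theta=theta, omega=omega, window=window, summary=summary)


# ---------------------------------------------------------------------------
# ligand contacts
# ---------------------------------------------------------------------------

_APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
_TYR_RING = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Contact:
    ligand_atom: str
    chain_id: str
    residue_id: int
    residue_name: str
    distance: float
    contact_class: Literal["hydrophobic", "polar"]


@dataclass
class ContactMap:
    cutoff: float
    contacts: list[Contact]

    def chains(self) -> set[str]:
        return {c.chain_id for c in self.contacts}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (c.ligand_atom, c.chain_id, c.residue_id, c.residue_name, c.distance, c.contact_class)
                for c in self.contacts
            ],
            columns=["ligand_atom", "chain", "residue", "residue_name", "min_distance_A", "class"],
        )


def _classify(atom_name: str, element: str, res_name: str) -> str:
    if element.upper() in {"N", "O"}:
        return "polar"
    side_chain = atom_name not in _BACKBONE
    if side_chain and element.upper() in {"C", "S"}:
        if res_name in _APOLAR_RESIDUES:
            return "hydrophobic"
        if res_name == "TYR" and atom_name in _TYR_RING:
            return "hydrophobic"
        if res_name == "MET":  # SD is sulfur but hydrophobic in context
            return "hydrophobic"
    return "polar"


def contact_map(
    structure: Structure,
    ligand: Selection | str,
    cutoff: float = 4.0,
    model_index: int = 0,
) -> ContactMap:
    """Protein residues with a heavy atom within ``cutoff`` of the ligand.

    ``ligand`` may be a residue name (matched against HETATM residues) or an
    explicit :class:`Selection`.  Each (ligand atom, residue) pair is
    reported once, at its minimum heavy-atom distance, classified as
    hydrophobic when the nearest protein atom is a side-chain C/S of an
    apolar residue (Tyr ring carbons included) and polar otherwise.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    model = structure.model(model_index)
    if isinstance(ligand, str):
        lig_atoms = [
            (ch.chain_id, r, a)
            for ch in model
            for r in ch.residues
            if r.name == ligand
            for a in r.atoms
        ]
    else:
        lig_atoms = select_atoms(structure, ligand, model_index)
    lig_atoms = [(cid, r, a) for cid, r, a in lig_atoms if a.is_heavy]
    if not lig_atoms:
        raise SelectionError("ligand selection resolved to zero heavy atoms")
    lig_keys = {(cid, r.seq_id) for cid, r, _ in lig_atoms}

    contacts: list[Contact] = []
    for cid, res, la in lig_atoms:
        for ch in model:
            for r in ch.residues:
                if (ch.chain_id, r.seq_id) in lig_keys:
                    continue
                best = None
                for a in r.atoms:
                    if not a.is_heavy:
                        continue
                    dist = float(np.linalg.norm(a.coords - la.coords))
                    if dist <= cutoff and (best is None or dist < best[0]):
                        best = (dist, a)
                if best is not None:
                    dist, a = best
                    contacts.append(
                        Contact(
                            ligand_atom=la.name,
                            chain_id=ch.chain_id,
                            residue_id=r.seq_id,
                            residue_name=r.name,
                            distance=dist,
                            contact_class=_classify(a.name, a.element, r.name),
                        )
                    )
    return ContactMap(cutoff=cutoff, contacts=contacts)
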