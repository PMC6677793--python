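"""Ideal coiled-coil construction and overlap-model assembly.

The builder places CA atoms on the Crick parametric curve: a minor
(alpha-helical) winding of radius R1 superposed on a superhelical path of
radius R0 and a stated pitch.  Default parameters are canonical
parallel-dimer values (R1 = 2.26 A, 1.495 A rise per residue, 3.62 residues
per minor turn, R0 = 4.9 A, left-handed superhelix of ~140 A pitch); they
are design defaults of this package, overridable per call.

Model assembly mirrors the homology-modeling recipe used for head-to-tail
overlap models of tropomyosin: superpose a fragment onto a scaffold over an
equal-length residue window (CA atoms), splice the fragment in from the
window outward, thread a target sequence onto the backbone, and extend
termini with ideal coiled-coil segments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .coilgeom import superpose
from .errors import (
    AlignmentError,
    ClashError,
    GeometryError,
    InsufficientInputError,
    LengthError,
    ParameterError,
)
from .structure import Atom, Chain, Residue, Selection, Structure, select_coords

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class CrickParameters:
    """Geometry of an ideal coiled coil.

    r0/r1 in Angstrom; rise in Angstrom per residue along the superhelical
    axis; pitch is the superhelical pitch in Angstrom; phi1 the minor-helix
    starting phase in degrees.  A left-handed superhelix and right-handed
    minor helix are the canonical choice for an alpha-helical coiled coil.
    chain_offsets (degrees, about the superhelical axis) default to an even
    spread: {0, 180} for a dimer.
    """

    r0: float = 4.9
    r1: float = 2.26
    rise: float = 1.495
    residues_per_turn: float = 3.62
    pitch: float = 140.0
    phi1: float = 0.0
    superhelix_handedness: Literal["left", "right"] = "left"
    minor_handedness: Literal["left", "right"] = "right"
    n_chains: int = 2
    chain_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.r1, self.rise, self.residues_per_turn, self.pitch) <= 0:
            raise ParameterError("r1, rise, residues_per_turn and pitch must be positive")
        if self.r0 < 0:
            raise ParameterError("r0 must be >= 0")
        if self.n_chains < 1:
            raise ParameterError("n_chains must be >= 1")
        if self.chain_offsets is not None and len(self.chain_offsets) != self.n_chains:
            raise ParameterError("need one chain offset per chain")

    @property
    def offsets(self) -> tuple[float, ...]:
        if self.chain_offsets is not None:
            return tuple(self.chain_offsets)
        return tuple(360.0 * k / self.n_chains for k in range(self.n_chains))


def crick_ca_coords(
    params: CrickParameters,
    n_residues: int,
    chain_offset_deg: float = 0.0,
    index_offset: float = 0.0,
    z0: float = 0.0,
    r0_override: float | None = None,
) -> np.ndarray:
    """CA coordinates of one chain on the Crick curve.

    ``index_offset`` shifts both the axial position and the winding phases,
    so two chains built with contiguous index ranges continue each other
    seamlessly.  ``r0_override`` substitutes the superhelical radius while
    keeping all phases (used to displace a chain radially outward).
    """
    r0 = params.r0 if r0_override is None else r0_override
    sig0 = -1.0 if params.superhelix_handedness == "left" else 1.0
    sig1 = 1.0 if params.minor_handedness == "right" else -1.0
    n = np.arange(n_residues, dtype=float) + index_offset
    z = params.rise * n + z0
    phi0 = sig0 * 2.0 * math.pi * z / params.pitch + math.radians(chain_offset_deg)
    # minor phase: residues_per_turn is the apparent (lab-frame) helical
    # periodicity, so subtract the rotation of the local frame that comes
    # with the superhelical phase advance
    psi = (
        sig1 * 2.0 * math.pi * n / params.residues_per_turn
        + math.radians(params.phi1)
        - sig0 * 2.0 * math.pi * z / params.pitch
    )

    cos0, sin0 = np.cos(phi0), np.sin(phi0)
    curve = np.stack([r0 * cos0, r0 * sin0, z], axis=1)
    # local frame: radial u, tangent t, binormal b = t x u
    u = np.stack([cos0, sin0, np.zeros_like(z)], axis=1)
    dphi_dn = sig0 * 2.0 * math.pi * params.rise / params.pitch
    t = np.stack([-r0 * dphi_dn * sin0, r0 * dphi_dn * cos0, np.full_like(z, params.rise)], axis=1)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    b = np.cross(t, u)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return curve + params.r1 * (np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * b)


def build_ideal_coiled_coil(
    params: CrickParameters,
    n_residues: int,
    chain_ids: Sequence[str] | None = None,
    start_res: int = 1,
    res_name: str = "ALA",
) -> Structure:
    """Deterministic CA-trace coiled coil with ``params.n_chains`` chains.

    Consecutive CA spacing is checked against the physical alpha-helical
    window [3.6, 4.0] A; parameters violating it raise GeometryError.
    """
    if n_residues < 4:
        raise InsufficientInputError("need n_residues >= 4")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + k) for k in range(params.n_chains)]
    if len(chain_ids) != params.n_chains:
        raise ParameterError("need one chain id per chain")
    chains = []
    for cid, off in zip(chain_ids, params.offsets):
        xyz = crick_ca_coords(params, n_residues, chain_offset_deg=off)
        spacing = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        if spacing.min() < 3.6 or spacing.max() > 4.0:
            raise GeometryError(
                f"parameters give CA spacing {spacing.min():.2f}-{spacing.max():.2f} A, "
                "outside [3.6, 4.0]"
            )
        residues = [
            Residue(seq_id=start_res + i, name=res_name, atoms=[Atom("CA", "C", c)])
            for i, c in enumerate(xyz)
        ]
        chains.append(Chain(chain_id=cid, residues=residues))
    return Structure(
        models=[chains],
        metadata={"builder": "crick", "params": params, "n_residues": n_residues},
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class AssemblySpec:
    """Fragment-onto-scaffold splice instructions.

    ``chain_map`` maps fragment chain ids to scaffold chain ids.  The
    fragment window ``source_window`` (fragment numbering) is superposed on
    ``target_window`` (scaffold numbering); both are inclusive and must
    contain the same number of residues.  ``replace_side`` says which side
    of the scaffold, beyond the window, the fragment replaces: "n" for the
    N-terminal side (an incoming N-terminal fragment), "c" for C-terminal.
    """

    fragment: Structure
    scaffold: Structure
    chain_map: dict[str, str]
    source_window: tuple[int, int]
    target_window: tuple[int, int]
    replace_side: Literal["n", "c"] = "n"
    rmsd_warn_threshold: float = 5.0

    def __post_init__(self) -> None:
        ns = self.source_window[1] - self.source_window[0] + 1
        nt = self.target_window[1] - self.target_window[0] + 1
        if ns != nt:
            raise AlignmentError(
                f"mapped windows differ in length: {ns} vs {nt} residues "
                f"({self.source_window} -> {self.target_window})"
            )
        if ns < 3:
            raise AlignmentError("mapped window must span >=3 residues")


def assemble_overlap(spec: AssemblySpec) -> Structure:
    """Superpose the fragment onto the scaffold over the mapped window and
    splice it in.

    The fit uses CA atoms of all mapped chains jointly.  Fragment residues
    are renumbered into the scaffold frame (offset = target start - source
    start).  The window-fit RMSD is recorded in the output metadata; a fit
    above ``rmsd_warn_threshold`` adds a warning entry instead of failing.
    """
    frag_chains = list(spec.chain_map)
    scaf_chains = [spec.chain_map[c] for c in frag_chains]
    frag_sel = Selection(chain_ids=frag_chains, residue_range=spec.source_window, atom_names=("CA",))
    scaf_sel = Selection(chain_ids=scaf_chains, residue_range=spec.target_window, atom_names=("CA",))
    fit = superpose(
        select_coords(spec.fragment, frag_sel),
        select_coords(spec.scaffold, scaf_sel),
    )
    offset = spec.target_window[0] - spec.source_window[0]
    out = spec.scaffold.copy()
    for frag_cid, scaf_cid in spec.chain_map.items():
        frag_ch = spec.fragment.chain(frag_cid)
        new_residues: list[Residue] = []
        for r in frag_ch.residues:
            mapped_id = r.seq_id + offset
            inside = spec.source_window[0] <= r.seq_id <= spec.source_window[1]
            beyond = (
                r.seq_id < spec.source_window[0]
                if spec.replace_side == "n"
                else r.seq_id > spec.source_window[1]
            )
            if not (inside or beyond):
                continue
            new_residues.append(
                Residue(
                    seq_id=mapped_id,
                    name=r.name,
                    atoms=[
                        Atom(a.name, a.element, fit.apply(a.coords), a.occupancy, a.b_factor)
                        for a in r.atoms
                    ],
                    het=r.het,
                )
            )
        scaf_ch = out.chain(scaf_cid)
        if spec.replace_side == "n":
            kept = [r for r in scaf_ch.residues if r.seq_id > spec.target_window[1]]
            merged = new_residues + kept
        else:
            kept = [r for r in scaf_ch.residues if r.seq_id < spec.target_window[0]]
            merged = kept + new_residues
        scaf_ch.residues[:] = merged
    out.metadata = dict(out.metadata)
    out.metadata["assembly"] = {
        "window_rmsd_A": fit.rmsd,
        "chain_map": dict(spec.chain_map),
        "source_window": spec.source_window,
        "target_window": spec.target_window,
    }
    if fit.rmsd > spec.rmsd_warn_threshold:
        out.metadata["assembly"]["warning"] = (
            f"window fit rmsd {fit.rmsd:.2f} A exceeds {spec.rmsd_warn_threshold} A"
        )
    return out


# ---------------------------------------------------------------------------
# sequence threading
# ---------------------------------------------------------------------------


def thread_sequence(
    structure: Structure,
    sequence: str,
    register: int = 0,
    chain_ids: Sequence[str] | None = None,
    keep_cb: bool = False,
) -> Structure:
    """Rename residues to a target sequence without moving any atom.

    ``sequence`` is one-letter; residue k (in chain order) takes
    ``sequence[register + k]``.  Side-chain atoms beyond CB are dropped;
    CB itself is kept only when ``keep_cb`` is set (and never appears on
    glycine).  The source -> target mapping is recorded in metadata.
    """
    sequence = sequence.strip().upper()
    bad = sorted(set(sequence) - set(ONE_TO_THREE))
    if bad:
        raise ParameterError(f"non-standard residue letter(s): {''.join(bad)}")
    if register < 0:
        raise ParameterError("register must be >= 0")
    out = structure.copy()
    mapping = {}
    for ch in out.model(0):
        if chain_ids is not None and ch.chain_id not in chain_ids:
            continue
        span = len(ch.residues)
        if register + span > len(sequence):
            raise LengthError(
                f"chain {ch.chain_id}: sequence of {len(sequence)} residues cannot cover "
                f"{span} backbone residues at register {register}"
            )
        for k, res in enumerate(ch.residues):
            new_name = ONE_TO_THREE[sequence[register + k]]
            mapping[f"{ch.chain_id}:{res.seq_id}"] = f"{res.name}->{new_name}"
            res.name = new_name
            keep = set(("N", "CA", "C", "O", "OXT"))
            if keep_cb and new_name != "GLY":
                keep.add("CB")
            res.atoms[:] = [a for a in res.atoms if a.name in keep]
    # threading applies to every model identically (names/atom pruning only)
    for model in out.models[1:]:
        for ch in model:
            if chain_ids is not None and ch.chain_id not in chain_ids:
                continue
            for k, res in enumerate(ch.residues):
                res.name = ONE_TO_THREE[sequence[register + k]]
                keep = set(("N", "CA", "C", "O", "OXT"))
                if keep_cb and res.name != "GLY":
                    keep.add("CB")
                res.atoms[:] = [a for a in res.atoms if a.name in keep]
    out.metadata = dict(out.metadata)
    out.metadata["threading"] = {"register": register, "mapping": mapping}
    return out


# ---------------------------------------------------------------------------
# terminal extension
# ---------------------------------------------------------------------------


def extend_termini(
    structure: Structure,
    params: CrickParameters,
    n_extra: int,
    end: Literal["n", "c"] = "c",
    chain_ids: Sequence[str] | None = None,
    overlap: int = 5,
    clash_cutoff: float = 2.5,
) -> Structure:
    """Extend chain termini with an ideal coiled-coil segment.

    A fresh segment of ``n_extra + overlap`` residues is built with
    ``params`` for the selected chains jointly, superposed by its first (for
    a C-terminal extension) or last (N-terminal) ``overlap`` CA atoms onto
    the corresponding terminal CAs, and the residues beyond the overlap are
    spliced on with continuous numbering.  Any CA pair closer than
    ``clash_cutoff`` between new and pre-existing residues raises
    ClashError.
    """
    if n_extra < 0:
        raise ParameterError("n_extra must be >= 0")
    out = structure.copy()
    if n_extra == 0:
        return out
    model = out.model(0)
    cids = list(chain_ids) if chain_ids is not None else [ch.chain_id for ch in model]
    if len(cids) != params.n_chains:
        raise ParameterError(
            f"params describe {params.n_chains} chains but {len(cids)} chains selected"
        )
    seg = build_ideal_coiled_coil(params, n_extra + overlap, chain_ids=cids)

    mob, ref = [], []
    for cid in cids:
        old = out.chain(cid)
        if len(old.residues) < overlap:
            raise InsufficientInputError(
                f"chain {cid}: needs >={overlap} terminal residues to establish a frame"
            )
        term = old.residues[-overlap:] if end == "c" else old.residues[:overlap]
        for r in term:
            ca = r.atom("CA")
            if ca is None:
                raise InsufficientInputError(f"chain {cid} residue {r.seq_id}: no CA")
            ref.append(ca.coords)
        seg_ch = seg.chain(cid)
        seg_term = seg_ch.residues[:overlap] if end == "c" else seg_ch.residues[-overlap:]
        mob.extend(r.atom("CA").coords for r in seg_term)
    fit = superpose(np.asarray(mob), np.asarray(ref))

    for cid in cids:
        old = out.chain(cid)
        seg_ch = seg.chain(cid)
        fresh = seg_ch.residues[overlap:] if end == "c" else seg_ch.residues[:-overlap]
        moved = [
            Residue(
                seq_id=0,
                name=r.name,
                atoms=[Atom(a.name, a.element, fit.apply(a.coords)) for a in r.atoms],
            )
            for r in fresh
        ]
        body = [r for r in old.residues if r.atom("CA") is not None]
        body_excl = body[:-overlap] if end == "c" else body[overlap:]
        if body_excl:
            body_ca = np.array([r.atom("CA").coords for r in body_excl])
            new_ca = np.array([r.atoms[0].coords for r in moved])
            d = np.linalg.norm(body_ca[:, None, :] - new_ca[None, :, :], axis=2)
            if d.min() < clash_cutoff:
                raise ClashError(
                    f"chain {cid}: extension clashes with body (min CA-CA {d.min():.2f} A)"
                )
        if end == "c":
            last = old.residues[-1].seq_id
            for k, r in enumerate(moved, start=1):
                r.seq_id = last + k
            splice = float(
                np.linalg.norm(old.residues[-1].atom("CA").coords - moved[0].atoms[0].coords)
            ) if moved else 0.0
            old.residues.extend(moved)
        else:
            first = old.residues[0].seq_id
            for k, r in enumerate(reversed(moved), start=1):
                r.seq_id = first - k
            splice = float(
                np.linalg.norm(old.residues[0].atom("CA").coords - moved[-1].atoms[0].coords)
            ) if moved else 0.0
            old.residues[:0] = moved
        out.metadata.setdefault("extension", {})[cid] = {
            "n_extra": n_extra,
            "end": end,
            "fit_rmsd_A": fit.rmsd,
            "splice_ca_ca_A": splice,
        }
    return out
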