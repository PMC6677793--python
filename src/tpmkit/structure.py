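"""PDB-backed structure container and selections.

A :class:`Structure` is a list of models (trajectory frames), each a list of
:class:`Chain` objects holding author-numbered residues.  Reading and writing
go through :mod:`gemmi`; this module only adds the light in-memory types the
geometry code works on, plus range/atom selections in the author numbering
used throughout ("residues 12-74" means both ends inclusive).

Insertion codes are not supported (tropomyosin fragments do not need them)
and are rejected on read.  Alternate locations are collapsed to the highest
occupancy conformer (ties broken alphabetically by altloc).
"""
from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    CoordinateOverflowError,
    FormatError,
    SelectionError,
    TrajectoryError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_HYDROGEN = {"H", "D"}


@dataclass
class Atom:
    """A single atom with coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FormatError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise FormatError("atom name must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass
class Residue:
    """Author-numbered residue; atom names are unique within the residue."""

    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise FormatError(f"residue {self.name} {self.seq_id}: duplicate atom names")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if ids != sorted(ids) or len(ids) != len(set(ids)):
            raise FormatError(f"chain {self.chain_id}: residues must be unique and ascending")

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    def ca_coords(self, residue_range: tuple[int, int] | None = None) -> np.ndarray:
        """CA coordinates, optionally restricted to an inclusive residue range."""
        out = []
        for r in self.residues:
            if residue_range is not None and not residue_range[0] <= r.seq_id <= residue_range[1]:
                continue
            ca = r.atom("CA")
            if ca is not None:
                out.append(ca.coords)
        return np.array(out, dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    """One or more models (frames) sharing chain/residue/atom topology."""

    models: list[list[Chain]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise FormatError("a Structure needs at least one model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model(self, index: int = 0) -> list[Chain]:
        return self.models[index]

    def chain(self, chain_id: str, model_index: int = 0) -> Chain:
        for ch in self.models[model_index]:
            if ch.chain_id == chain_id:
                return ch
        raise SelectionError(f"chain {chain_id!r} not present in model {model_index}")

    def chain_ids(self, model_index: int = 0) -> list[str]:
        return [ch.chain_id for ch in self.models[model_index]]

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def assert_consistent_topology(self) -> None:
        """Raise TrajectoryError unless every model has identical topology."""
        ref = _topology(self.models[0])
        for i, m in enumerate(self.models[1:], start=1):
            if _topology(m) != ref:
                raise TrajectoryError(f"model {i} topology differs from model 0")


def _topology(model: list[Chain]):
    return tuple(
        (ch.chain_id, tuple((r.seq_id, r.name, tuple(a.name for a in r.atoms)) for r in ch.residues))
        for ch in model
    )


@dataclass
class Selection:
    """Chains x inclusive author-numbered residue range x atom names.

    ``atom_names=None`` keeps every atom; ``residue_range=None`` keeps every
    residue.  ``chain_ids=None`` means all chains in model order.
    """

    chain_ids: Sequence[str] | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise SelectionError(f"residue range {lo}-{hi}: start must be <= end")


def read_pdb(path: str | Path) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0 or all(len(list(m)) == 0 for m in st):
        raise FormatError(f"{path}: no ATOM/HETATM records")
    models: list[list[Chain]] = []
    for m in st:
        chains: list[Chain] = []
        for ch in m:
            residues: list[Residue] = []
            for res in ch:
                if res.seqid.icode not in (" ", "\0", ""):
                    raise FormatError(
                        f"{path}: insertion code {res.seqid.icode!r} at {ch.name} "
                        f"{res.seqid.num} is not supported"
                    )
                atoms: dict[str, Atom] = {}
                best: dict[str, tuple[float, str]] = {}
                for a in res:
                    cand = Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                    )
                    # keep the dominant altloc: occupancy first, then altloc letter
                    key = (-cand.occupancy, _altloc_key(a))
                    if a.name not in best or key < best[a.name]:
                        best[a.name] = key
                        atoms[a.name] = cand
                residues.append(Residue(seq_id=res.seqid.num, name=res.name, atoms=list(atoms.values()), het=res.het_flag == "H"))
            chains.append(Chain(chain_id=ch.name, residues=residues))
        models.append(chains)
    return Structure(models=models, metadata={"source": str(path)})


def _altloc_key(a) -> str:
    return a.altloc or " "


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write fixed-column PDB; MODEL/ENDMDL only for multi-frame input."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = str(structure.metadata.get("name", "tpmkit"))
    for mi, model in enumerate(structure.models, start=1):
        gm = gemmi.Model(mi)
        for ch in model:
            gch = gemmi.Chain(ch.chain_id)
            for res in ch.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seq_id, " ")
                gres.het_flag = "H" if res.het else "A"
                for a in res.atoms:
                    if np.any(np.abs(a.coords) >= 10000) or np.any(a.coords <= -1000):
                        raise CoordinateOverflowError(
                            f"{ch.chain_id} {res.seq_id} {a.name}: coordinate "
                            f"{a.coords} exceeds the PDB %8.3f field"
                        )
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    gres.add_atom(ga)
                gch.add_residue(gres)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    # setup_entities may reclassify; restore our het flags
    for gm, model in zip(st, structure.models):
        for gch, ch in zip(gm, model):
            for gres, res in zip(gch, ch.residues):
                gres.het_flag = "H" if res.het else "A"
    st.write_pdb(str(path))
    return path


def select_coords(
    structure: Structure,
    selection: Selection,
    model_index: int = 0,
    skip_missing_atoms: bool = False,
) -> np.ndarray:
    """Ordered coordinates for a selection.

    Order is (chain order as given, residue seq_id ascending, atom names in
    the order listed by the selection).  A residue in the requested range
    that lacks a requested atom raises :class:`SelectionError` unless
    ``skip_missing_atoms`` is set, in which case the whole residue is
    skipped (terminal residues are often unresolved in crystal structures).
    """
    triples = select_atoms(structure, selection, model_index, skip_missing_atoms)
    return np.array([a.coords for _, _, a in triples], dtype=float).reshape(-1, 3)


def select_atoms(
    structure: Structure,
    selection: Selection,
    model_index: int = 0,
    skip_missing_atoms: bool = False,
) -> list[tuple[str, Residue, Atom]]:
    """Like :func:`select_coords` but keeps (chain_id, residue, atom) context."""
    model = structure.model(model_index)
    chain_ids = selection.chain_ids or [ch.chain_id for ch in model]
    out: list[tuple[str, Residue, Atom]] = []
    for cid in chain_ids:
        ch = structure.chain(cid, model_index)
        in_range = [
            r
            for r in ch.residues
            if selection.residue_range is None
            or selection.residue_range[0] <= r.seq_id <= selection.residue_range[1]
        ]
        if selection.residue_range is not None and not in_range:
            lo, hi = selection.residue_range
            raise SelectionError(f"chain {cid}: no residues in range {lo}-{hi}")
        for r in in_range:
            if selection.atom_names is None:
                out.extend((cid, r, a) for a in r.atoms)
                continue
            picked = []
            missing = []
            for name in selection.atom_names:
                a = r.atom(name)
                (picked.append(a) if a is not None else missing.append(name))
            if missing:
                if skip_missing_atoms:
                    continue
                raise SelectionError(
                    f"chain {cid} residue {r.seq_id}: missing atom(s) {','.join(missing)}"
                )
            out.extend((cid, r, a) for a in picked)
    if not out:
        raise SelectionError("selection resolved to zero atoms")
    return out


def structure_from_coords(
    chain_coords: dict[str, np.ndarray],
    chain_start: dict[str, int] | int = 1,
    atom_name: str = "CA",
    element: str = "C",
    res_name: str = "ALA",
    metadata: dict | None = None,
) -> Structure:
    """Build a single-model, one-atom-per-residue structure from raw arrays."""
    chains = []
    for cid, xyz in chain_coords.items():
        xyz = np.asarray(xyz, float)
        start = chain_start if isinstance(chain_start, int) else chain_start[cid]
        residues = [
            Residue(seq_id=start + i, name=res_name, atoms=[Atom(atom_name, element, c)])
            for i, c in enumerate(xyz)
        ]
        chains.append(Chain(chain_id=cid, residues=residues))
    return Structure(models=[chains], metadata=metadata or {})
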