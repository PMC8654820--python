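"""Coordinate model types (Atom/Residue/Structure), file I/O and editing.

PDB and mmCIF parsing/writing is delegated to gemmi; the in-memory model is
a small set of plain dataclasses holding orthogonal-Angstrom coordinates,
which keeps the density code free of reader-specific types.
"""
from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

from .cell import UnitCell
from .errors import FormatError, MissingCellError

__all__ = [
    "Atom", "Residue", "Structure", "STANDARD_AA", "WATER_NAMES",
    "read_structure", "write_structure", "set_uniform_bfactor", "strip",
    "split_by_element",
]

STANDARD_AA = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])
WATER_NAMES = frozenset(["HOH", "WAT", "H2O", "DOD"])


@dataclass
class Atom:
    """One atom: element symbol, orthogonal position (A), occupancy, B_iso (A^2)."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float).reshape(3)
        if self.b_iso < 0:
            raise ValueError("b_iso must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue: chain id, author sequence number, 3-letter name, atoms."""

    chain: str
    seqnum: int
    name: str
    atoms: list = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> tuple:
        return (self.chain, self.seqnum, self.name)

    @property
    def is_water(self) -> bool:
        return self.name.upper() in WATER_NAMES

    @property
    def is_standard_aa(self) -> bool:
        return self.name.upper() in STANDARD_AA

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def find_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Unit cell + residues grouped by chain. Space group P1 for synthesis;
    other space-group names are carried as metadata only."""

    cell: UnitCell
    residues: list = field(default_factory=list)
    spacegroup: str = "P 1"
    id: str = ""

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.pos for r in self.residues for a in r.atoms
               if not (heavy_only and a.is_hydrogen)]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def get_residue(self, chain: str, seqnum: int) -> Optional[Residue]:
        for r in self.residues:
            if r.chain == chain and r.seqnum == seqnum:
                return r
        return None

    def electron_count(self, table) -> float:
        """Total occupancy-weighted electron count under a scattering table."""
        return float(sum(a.occupancy * table.coefficients(a.element).f0
                         for a in self.atoms()))


# ---------------------------------------------------------------------------
# file I/O

_DIALECTS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _is_placeholder_cell(c: gemmi.UnitCell) -> bool:
    return abs(c.a - 1.0) < 1e-6 and abs(c.b - 1.0) < 1e-6 and abs(c.c - 1.0) < 1e-6


def read_structure(path, dialect: str = None, cell: UnitCell = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path : file path
    dialect : "pdb" | "mmcif" | None
        None auto-detects from the file contents/extension.
    cell : UnitCell, optional
        Supplied cell for files lacking CRYST1/cell records; otherwise a
        missing cell raises :class:`MissingCellError`.
    """
    path = str(path)
    try:
        if dialect is None:
            st = gemmi.read_structure(path)
        else:
            try:
                fmt = _DIALECTS[dialect]
            except KeyError:
                raise FormatError(f"unknown dialect {dialect!r}; use 'pdb' or 'mmcif'")
            st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {dialect or 'coordinates'}: {exc}") from exc

    if _is_placeholder_cell(st.cell):
        if cell is None:
            raise MissingCellError(
                f"{path} carries no unit cell; pass cell=UnitCell(...) to supply one")
        ucell = cell
    else:
        ucell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                         st.cell.alpha, st.cell.beta, st.cell.gamma)

    residues = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                atoms = []
                for at in res:
                    elem = at.element.name if at.element.name != "X" else at.name[:1]
                    atoms.append(Atom(
                        name=at.name, element=elem,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ), b_iso=float(at.b_iso),
                        altloc=at.altloc if at.altloc != "\x00" else ""))
                residues.append(Residue(
                    chain=chain.name, seqnum=res.seqid.num, name=res.name,
                    atoms=atoms, het=(res.het_flag == "H")))
    sg = st.spacegroup_hm or "P 1"
    return Structure(cell=ucell, residues=residues, spacegroup=sg,
                     id=st.name or Path(path).stem)


def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "boxcc"
    st.cell = structure.cell.to_gemmi()
    st.spacegroup_hm = structure.spacegroup
    model = gemmi.Model("1")
    chains: dict = {}
    for res in structure.residues:
        ch = chains.get(res.chain)
        if ch is None:
            ch = gemmi.Chain(res.chain)
            chains[res.chain] = ch
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seqnum, " ")
        gres.het_flag = "H" if res.het else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.b_iso = a.b_iso
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path, dialect: str = None) -> None:
    """Write a structure as PDB or mmCIF (dialect inferred from extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    st = to_gemmi(structure)
    try:
        if dialect == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# editing primitives

def set_uniform_bfactor(structure: Structure, value: float) -> Structure:
    """Return a copy with every atom's B_iso set to `value` (A^2).

    The toolkit's calculated-density convention fixes B_iso = 2.0 so that
    coordinates are scored independently of refined displacement parameters.
    """
    if value < 0:
        raise ValueError("B-factor must be >= 0")
    out = structure.copy()
    for atom in out.atoms():
        atom.b_iso = float(value)
    return out


def strip(structure: Structure, drop_waters: bool = True, drop_hetero: bool = False,
          drop_hydrogens: bool = True, altloc_policy: str = "highest_occupancy") -> Structure:
    """Remove waters/heteros/hydrogens and collapse alternate conformers.

    ``altloc_policy="highest_occupancy"`` keeps exactly one conformer per
    atom name (ties broken by the alphabetically first altloc code) and
    resets its occupancy to 1.0, since density comparisons assume a single
    model. May return an empty structure.
    """
    if altloc_policy not in ("highest_occupancy", "keep"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    out = Structure(cell=structure.cell, spacegroup=structure.spacegroup,
                    id=structure.id)
    for res in structure.residues:
        if drop_waters and res.is_water:
            continue
        if drop_hetero and res.het and not res.is_standard_aa:
            continue
        atoms = [a for a in res.atoms if not (drop_hydrogens and a.is_hydrogen)]
        if altloc_policy == "highest_occupancy":
            by_name: dict = {}
            for a in atoms:
                prev = by_name.get(a.name)
                if prev is None or (a.occupancy, _alt_rank(a)) > (prev.occupancy, _alt_rank(prev)):
                    by_name[a.name] = a
            picked = []
            seen = set()
            for a in atoms:           # preserve original atom order
                if a.name in seen:
                    continue
                seen.add(a.name)
                chosen = _copy.deepcopy(by_name[a.name])
                if chosen.altloc:
                    chosen.altloc = ""
                    chosen.occupancy = 1.0
                picked.append(chosen)
            atoms = picked
        else:
            atoms = [_copy.deepcopy(a) for a in atoms]
        if atoms:
            out.residues.append(Residue(res.chain, res.seqnum, res.name, atoms, res.het))
    return out


def _alt_rank(atom: Atom):
    # higher rank wins ties: alphabetically first altloc ("" counts first)
    return -ord(atom.altloc) if atom.altloc else 0


def split_by_element(structure: Structure, elements) -> dict:
    """Partition a structure's atoms by element symbol.

    Returns a mapping ``element -> Structure`` for each requested element
    (possibly empty). Atoms of unlisted elements are not silently dropped:
    a warning reports their element counts.
    """
    elements = [e.upper() for e in elements]
    if not elements:
        raise ValueError("elements list must be non-empty")
    out = {e: Structure(cell=structure.cell, spacegroup=structure.spacegroup,
                        id=f"{structure.id}:{e}") for e in elements}
    leftover: dict = {}
    for res in structure.residues:
        buckets: dict = {e: [] for e in elements}
        for a in res.atoms:
            e = a.element.upper()
            if e in buckets:
                buckets[e].append(_copy.deepcopy(a))
            else:
                leftover[e] = leftover.get(e, 0) + 1
        for e, atoms in buckets.items():
            if atoms:
                out[e].residues.append(Residue(res.chain, res.seqnum, res.name,
                                               atoms, res.het))
    if leftover:
        warnings.warn(f"split_by_element: atoms of unlisted elements skipped: {leftover}",
                      stacklevel=2)
    return out
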