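"""Self-contained synthetic crystallographic fixtures.

Generates ground-truth helical polypeptides in padded P1 cells, simulated
"observed" maps at chosen resolutions (structure factors -> resolution
truncation -> reflection noise -> FFT synthesis), parametrically perturbed
"incorrect" models, and ligand-pocket scenarios — everything reproducible
from (config, seed) alone, with no downloads and no external refinement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cell import UnitCell
from .errors import ClashError
from .maps import DensityMap
from .reflections import (add_reflection_noise, default_fft_grid,
                          map_from_reflections, structure_factors,
                          truncate_resolution)
from .structure import Atom, Residue, Structure
from .templates import (BACKBONE_GEOMETRY as BB, DEFAULT_CHI, TEMPLATES,
                        place_atom, resolve_dihedral)

__all__ = ["generate_structure", "generate_bundle", "PerturbationSpec",
           "perturb_structure", "BFactorProfile", "simulate_observed_map",
           "add_ligand_pocket", "add_water_near", "most_buried_residue",
           "DEFAULT_COMPOSITION"]

DEFAULT_COMPOSITION = ("GLY", "ALA", "SER", "CYS", "THR", "VAL", "LEU",
                       "ASP", "MET", "LYS", "PHE")


# ---------------------------------------------------------------------------
# ground-truth structures

def _build_chain(sequence, rng, chi_jitter_deg, torsion_jitter_deg):
    """Backbone + side chains along an alpha-helical curve via NeRF."""
    residues = []
    # seed the first three backbone atoms
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([BB["n_ca"], 0.0, 0.0])
    c_pos = place_atom(np.array([-1.0, 1.0, 0.0]), n_pos, ca_pos,
                       BB["ca_c"], BB["angle_n_ca_c"], 45.0)
    prev = None
    for i, name in enumerate(sequence):
        tpl = TEMPLATES[name]
        if i > 0:
            psi = BB["psi"] + rng.normal(0, torsion_jitter_deg)
            phi = BB["phi"] + rng.normal(0, torsion_jitter_deg)
            pn, pca, pc = prev
            n_pos = place_atom(pn, pca, pc, BB["c_n"], BB["angle_ca_c_n"], psi)
            ca_pos = place_atom(pca, pc, n_pos, BB["n_ca"], BB["angle_c_n_ca"], BB["omega"])
            c_pos = place_atom(pc, n_pos, ca_pos, BB["ca_c"], BB["angle_n_ca_c"], phi)
        coords = {"N": n_pos, "CA": ca_pos, "C": c_pos}
        atoms = [Atom("N", "N", n_pos), Atom("CA", "C", ca_pos), Atom("C", "C", c_pos)]
        chi = {k: v + rng.normal(0, chi_jitter_deg) for k, v in DEFAULT_CHI.items()}
        for row in tpl.sidechain:
            aname, elem, refs, bond, angle, dih = row
            pos = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                             bond, angle, resolve_dihedral(dih, chi))
            coords[aname] = pos
            atoms.append(Atom(aname, elem, pos))
        # carbonyl O after phi of the NEXT residue would be ideal; the
        # improper against N keeps it planar enough for density purposes
        o_pos = place_atom(n_pos, ca_pos, c_pos, BB["c_o"], BB["angle_ca_c_o"], 135.0)
        coords["O"] = o_pos
        atoms.insert(3, Atom("O", "O", o_pos))
        residues.append(Residue("A", i + 1, name, atoms))
        prev = (n_pos, ca_pos, c_pos)
    return residues


def _has_clash(residues, min_dist: float = 1.0) -> bool:
    """Any pair of atoms from non-adjacent residues closer than min_dist."""
    pos, rid = [], []
    for i, r in enumerate(residues):
        for a in r.atoms:
            pos.append(a.pos)
            rid.append(i)
    pos = np.array(pos)
    rid = np.array(rid)
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(min_dist):
        if abs(rid[i] - rid[j]) >= 2:
            return True
    return False


def generate_structure(n_residues: int, composition: Optional[Sequence[str]] = None,
                       cell_padding: float = 6.0, seed: int = 0,
                       chi_jitter_deg: float = 10.0,
                       torsion_jitter_deg: float = 6.0,
                       max_retries: int = 20) -> Structure:
    """Random idealized helical polypeptide in a padded orthorhombic P1 cell.

    Residue types are drawn (seeded) from ``composition`` (default: all
    shipped templates). The cell pads the model's bounding box by
    ``cell_padding`` A on every side so that boxes of edge residues stay
    meaningful under periodicity. Raises :class:`ClashError` if clashes
    cannot be resolved within ``max_retries`` re-draws.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    composition = tuple(composition or DEFAULT_COMPOSITION)
    unknown = set(composition) - set(TEMPLATES)
    if unknown:
        raise ValueError(f"no template for residue types {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    sequence = [composition[i] for i in rng.integers(0, len(composition), n_residues)]
    for _ in range(max_retries):
        residues = _build_chain(sequence, rng, chi_jitter_deg, torsion_jitter_deg)
        if not _has_clash(residues):
            break
    else:
        raise ClashError(f"could not build clash-free chain after {max_retries} tries")
    pos = np.array([a.pos for r in residues for a in r.atoms])
    lo = pos.min(axis=0)
    shift = cell_padding - lo
    for r in residues:
        for a in r.atoms:
            a.pos = a.pos + shift
    extent = pos.max(axis=0) - lo + 2 * cell_padding
    cell = UnitCell(*np.round(extent, 3))
    return Structure(cell=cell, residues=residues, spacegroup="P 1",
                     id=f"synth-n{n_residues}-s{seed}")


def generate_bundle(n_residues: int, n_chains: int = 3,
                    chain_offset: float = 8.5,
                    composition: Optional[Sequence[str]] = None,
                    cell_padding: float = 6.0, seed: int = 0) -> Structure:
    """Several parallel helices packed side by side in one P1 cell.

    A single helix leaves a residue-centered 12 A box half empty; packing
    ``n_chains`` copies ``chain_offset`` A apart reproduces the atom
    density of a protein interior, which matters for environment-dependent
    quantities (e.g. how little one atom contributes to a box score).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(24):
        base = generate_structure(n_residues, composition, cell_padding, seed=int(
            rng.integers(0, 2 ** 31)))
        # keep the packing tight: only widen the gap after several
        # fresh-helix attempts at the current one
        gap = chain_offset + 0.5 * (attempt // 6)
        offsets = []
        for i in range(n_chains):
            # 2-wide square grid in the y-z plane perpendicular to the axis
            row, col = divmod(i, 2)
            offsets.append(np.array([0.0,
                                     gap * (col - 0.5),
                                     gap * 0.9 * (row - (n_chains - 1) // 4)]))
        residues = []
        for i, off in enumerate(offsets):
            chain_id = chr(ord("A") + i)
            jitter = rng.normal(0.0, 0.3, 3)
            for res in base.residues:
                atoms = [Atom(a.name, a.element, a.pos + off + jitter,
                              a.occupancy, a.b_iso) for a in res.atoms]
                residues.append(Residue(chain_id, res.seqnum, res.name, atoms))
        if not _has_clash(residues):
            break
    else:
        raise ClashError("bundle chains clash; increase chain_offset")
    pos = np.array([a.pos for r in residues for a in r.atoms])
    lo = pos.min(axis=0)
    shift = cell_padding - lo
    for r in residues:
        for a in r.atoms:
            a.pos = a.pos + shift
    extent = pos.max(axis=0) - lo + 2 * cell_padding
    cell = UnitCell(*np.round(extent, 3))
    return Structure(cell=cell, residues=residues, spacegroup="P 1",
                     id=f"bundle-n{n_residues}x{n_chains}-s{seed}")


# ---------------------------------------------------------------------------
# perturbations ("incorrect" models)

@dataclass(frozen=True)
class PerturbationSpec:
    """How to damage a structure: mode, magnitude (A or degrees), range, seed."""

    mode: str                       # jitter | sidechain_rotate | segment_shift | rigid_body
    magnitude: float                # A for jitter/segment_shift, degrees for rotations
    residue_range: Optional[tuple] = None   # (first_seqnum, last_seqnum) inclusive; None = all
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.mode not in ("jitter", "sidechain_rotate", "segment_shift", "rigid_body"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")


_BACKBONE_NAMES = ("N", "CA", "C", "O")


def perturb_structure(structure: Structure, spec: PerturbationSpec) -> Structure:
    """Seeded copy of a structure with only the targeted residues moved.

    jitter: i.i.d. Gaussian displacement with sigma = magnitude/sqrt(3)
    per component, so the expected all-atom RMSD equals the magnitude.
    sidechain_rotate: rotate atoms beyond CB about the CA-CB axis by
    magnitude degrees; backbone exactly fixed. segment_shift: rigid
    translation of the range by magnitude A in a random direction.
    rigid_body: rotation of the range about its centroid by magnitude
    degrees around a random axis.
    """
    out = structure.copy()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.residue_range if spec.residue_range else (None, None)
    targets = [r for r in out.residues
               if (lo is None or lo <= r.seqnum) and (hi is None or r.seqnum <= hi)]
    if not targets:
        raise ValueError(f"residue range {spec.residue_range} selects no residues")
    if spec.magnitude == 0:
        return out
    if spec.mode == "jitter":
        sigma = spec.magnitude / np.sqrt(3.0)
        for r in targets:
            for a in r.atoms:
                a.pos = a.pos + rng.normal(0.0, sigma, 3)
    elif spec.mode == "sidechain_rotate":
        for r in targets:
            ca, cb = r.find_atom("CA"), r.find_atom("CB")
            if ca is None or cb is None:
                continue
            axis = cb.pos - ca.pos
            axis = axis / np.linalg.norm(axis)
            rot = _axis_rotation(axis, np.deg2rad(spec.magnitude))
            for a in r.atoms:
                if a.name in _BACKBONE_NAMES or a.name == "CB":
                    continue
                a.pos = ca.pos + rot @ (a.pos - ca.pos)
    elif spec.mode == "segment_shift":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for r in targets:
            for a in r.atoms:
                a.pos = a.pos + spec.magnitude * direction
    else:  # rigid_body
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = _axis_rotation(axis, np.deg2rad(spec.magnitude))
        pivot = np.mean([a.pos for r in targets for a in r.atoms], axis=0)
        for r in targets:
            for a in r.atoms:
                a.pos = pivot + rot @ (a.pos - pivot)
    return out


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# observed-map simulation

@dataclass(frozen=True)
class BFactorProfile:
    """Per-atom B assignment for simulated observed maps.

    base B plus a ramp up to ``exposure_scale`` for atoms far from the
    molecular centroid — a cheap proxy for the blurring of solvent-exposed
    regions, without any solvent model.
    """

    base: float = 15.0
    exposure_scale: float = 25.0

    def assign(self, structure: Structure) -> Structure:
        out = structure.copy()
        pos = out.coords()
        centroid = pos.mean(axis=0)
        dist = np.linalg.norm(pos - centroid, axis=1)
        dmax = dist.max() if dist.max() > 0 else 1.0
        for a, d in zip(out.atoms(), dist):
            a.b_iso = self.base + self.exposure_scale * (d / dmax)
        return out


def simulate_observed_map(structure: Structure, d_min: float,
                          noise_sigma: float = 0.05,
                          b_profile: Optional[BFactorProfile] = None,
                          seed: int = 0, grid_dims=None) -> DensityMap:
    """Simulated "observed" 2mFo-DFc-like map at resolution d_min.

    Pipeline: assign per-atom B from the profile -> direct-summation
    structure factors to d_min -> resolution truncation -> complex
    Gaussian reflection noise -> FFT synthesis on a 1.5x-Nyquist grid.
    No refinement step is involved, so the map carries no model bias by
    construction.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    b_profile = b_profile or BFactorProfile()
    bstruct = b_profile.assign(structure)
    rs = structure_factors(bstruct, d_min)
    rs = truncate_resolution(rs, d_min)
    rs = add_reflection_noise(rs, noise_sigma, seed)
    dims = grid_dims or default_fft_grid(structure.cell, d_min)
    m = map_from_reflections(rs, dims, label=(
        f"synthetic-observed d_min={d_min} noise={noise_sigma} seed={seed}"))
    return m


def most_buried_residue(structure: Structure, edge: float = 12.0,
                        seqnum_window: Optional[tuple] = None) -> Residue:
    """The residue whose box contains the most heavy atoms.

    A proxy for "interior" in synthetic bundles; optionally restricted to
    a seqnum range (e.g. the middle of each chain) to avoid termini.
    """
    from .boxes import residue_centroid
    pts = structure.coords(heavy_only=True)
    best, best_n = None, -1
    for res in structure.residues:
        if not res.is_standard_aa:
            continue
        if seqnum_window and not seqnum_window[0] <= res.seqnum <= seqnum_window[1]:
            continue
        c = residue_centroid(res)
        n = int(np.sum(np.all(np.abs(pts - c) <= edge / 2.0, axis=1)))
        if n > best_n:
            best, best_n = res, n
    return best


def add_water_near(structure: Structure, residue: Residue,
                   max_offset: float = 1.2, seed: int = 0,
                   n_candidates: int = 8000) -> Structure:
    """Place one water oxygen near a residue's centroid, as far from the
    protein as possible.

    The oxygen lands within ``max_offset`` A of the centroid along every
    axis (so it stays inside even a small residue-centered box) at the
    candidate position maximizing the distance to the nearest protein
    atom. Appended as a hetero HOH residue on chain S.
    """
    from .boxes import residue_centroid
    rng = np.random.default_rng(seed)
    center = residue_centroid(residue)
    tree = cKDTree(structure.coords(heavy_only=True))
    offsets = rng.uniform(-max_offset, max_offset, size=(n_candidates, 3))
    dists, _ = tree.query(center + offsets)
    pos = center + offsets[np.argmax(dists)]
    out = structure.copy()
    seq = max((r.seqnum for r in out.residues), default=0) + 900
    out.residues.append(Residue("S", seq, "HOH", [Atom("O", "O", pos)], het=True))
    return out


# ---------------------------------------------------------------------------
# ligand pockets

DEFAULT_LIGAND_COMPOSITION = {"C": 14, "N": 6, "O": 5, "S": 1}   # SAH-like heavy atoms


def add_ligand_pocket(structure: Structure, ligand_atom_spec: Optional[dict] = None,
                      pocket_residue: Optional[tuple] = None, seed: int = 0,
                      max_retries: int = 50) -> Structure:
    """Place a small-molecule atom cluster next to a pocket residue.

    The ligand is a self-avoiding random walk (1.5 A steps) with the given
    heavy-atom composition (default: a 26-atom SAH-like C/N/O/S mix),
    started 3.5-5 A from the pocket residue's centroid, kept within the
    residue's 12 A box and clash-free (>= 2.6 A to protein atoms, >= 1.2 A
    between non-bonded ligand atoms). Returned flagged as hetero, chain L.
    """
    from .boxes import residue_centroid
    spec = dict(ligand_atom_spec or DEFAULT_LIGAND_COMPOSITION)
    elements = [el for el, cnt in spec.items() for _ in range(cnt)]
    if pocket_residue is None:
        mid = structure.residues[len(structure.residues) // 2]
        pocket = mid
    else:
        pocket = structure.get_residue(*pocket_residue)
        if pocket is None:
            raise ValueError(f"pocket residue {pocket_residue} not found")
    rng = np.random.default_rng(seed)
    center = residue_centroid(pocket)
    prot = structure.coords(heavy_only=True)
    tree = cKDTree(prot)
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]
    for _ in range(max_retries):
        pts = _grow_ligand(rng, center, tree, n_atoms=len(elements))
        if pts is not None:
            break
    else:
        raise ClashError("could not place ligand without clashes")
    atoms = [Atom(f"{el}{i + 1}", el, p) for i, (el, p) in enumerate(zip(elements, pts))]
    out = structure.copy()
    out.residues.append(Residue("L", 1, "LIG", atoms, het=True))
    return out


def _grow_ligand(rng, center, prot_tree, n_atoms, step: float = 1.5,
                 box_radius: float = 5.5, min_prot: float = 2.6,
                 min_self: float = 1.2):
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for _ in range(20):
        start = center + direction * rng.uniform(3.5, 5.0)
        if prot_tree.query(start)[0] >= min_prot and np.all(np.abs(start - center) <= box_radius):
            break
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
    else:
        return None
    pts = [start]
    for _ in range(n_atoms - 1):
        placed = False
        for _ in range(60):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pts[rng.integers(0, len(pts))] + step * d
            if np.any(np.abs(cand - center) > box_radius):
                continue
            if prot_tree.query(cand)[0] < min_prot:
                continue
            dists = np.linalg.norm(np.array(pts) - cand, axis=1)
            if np.any(dists < min_self):
                continue
            pts.append(cand)
            placed = True
            break
        if not placed:
            return None
    return np.array(pts)
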