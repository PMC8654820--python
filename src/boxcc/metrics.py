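"""Local map-vs-model quality metrics.

The central quantity is the box correlation coefficient (bCC): the Pearson
correlation, over a residue-centered cubic voxel box, between an observed
("correct") density map and the density calculated from the coordinates
under evaluation at B_iso = 2.0. Because it is computed over the whole box
it scores the residue together with its environment, and because it only
ever references the high-resolution correct map it is immune to the model
bias that inflates conventional RSCC at low resolution.
"""
from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from .boxes import Box, extract_box, residue_centroid
from .density import suggest_grid, synthesize_map
from .errors import CellMismatchError, DegenerateBoxError, NoLigandError
from .maps import DensityMap
from .scattering import ScatteringTable, default_table
from .structure import Residue, Structure, set_uniform_bfactor, strip

__all__ = ["bcc", "per_residue_bcc", "rscc", "ligand_delta_bcc",
           "single_atom_contribution", "CALC_B_ISO"]

# the calculated-density displacement convention: score coordinates only
CALC_B_ISO = 2.0
# grid spacing for calculated maps; fine enough to sample B=2 Gaussians
CALC_SPACING = 0.3


def _box_values(b: Union[Box, np.ndarray]) -> np.ndarray:
    return b.values if isinstance(b, Box) else np.asarray(b, dtype=float)


def bcc(box_obs: Union[Box, np.ndarray], box_calc: Union[Box, np.ndarray]) -> float:
    """Pearson correlation between two voxel boxes, in [-1, 1].

    Invariant to affine rescaling of either box and to applying the same
    cube rotation to both. Zero variance in either box raises
    :class:`DegenerateBoxError` rather than silently scoring an empty
    region as 0.
    """
    x = _box_values(box_obs).ravel()
    y = _box_values(box_calc).ravel()
    if x.shape != y.shape:
        raise ValueError(f"box shapes differ: {x.shape} vs {y.shape}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateBoxError("zero-variance box (empty or flat density region)")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise DegenerateBoxError("zero-variance box (empty or flat density region)")
    return float((xc @ yc) / np.sqrt(vx * vy))


def _check_cells(structure: Structure, density_map: DensityMap, rel: float = 1e-3) -> None:
    if not structure.cell.approx_equal(density_map.cell, rel):
        raise CellMismatchError(
            f"structure cell {structure.cell} and map cell {density_map.cell} "
            f"disagree beyond {rel:.1%}")


def calculated_map(structure: Structure, table: ScatteringTable = None,
                   spacing: float = CALC_SPACING,
                   b_iso: float = CALC_B_ISO) -> DensityMap:
    """rho_model,calc over the unit cell: hydrogens dropped, B reset, summed."""
    prep = set_uniform_bfactor(strip(structure, drop_waters=False, drop_hetero=False,
                                     drop_hydrogens=True), b_iso)
    return synthesize_map(prep, suggest_grid(structure.cell, spacing),
                          b_override=b_iso, table=table, label="calculated")


def per_residue_bcc(structure: Structure, obs_map: DensityMap,
                    table: ScatteringTable = None, edge: float = 12.0,
                    spacing: float = 0.5, calc_map: Optional[DensityMap] = None,
                    calc_spacing: float = CALC_SPACING) -> pd.DataFrame:
    """bCC for every standard amino-acid residue of a structure.

    The calculated map is synthesized once over the whole cell (B_iso reset
    to 2.0, hydrogens dropped), then observed and calculated boxes are cut
    at each residue's heavy-atom centroid and correlated. Residues whose
    boxes are degenerate get a null score and a flag instead of aborting.

    Returns a DataFrame with columns chain, resnum, resname, bcc, flag.
    """
    _check_cells(structure, obs_map)
    if calc_map is None:
        calc_map = calculated_map(structure, table, calc_spacing)
    rows = []
    for res in structure.residues:
        if not res.is_standard_aa or res.het:
            continue
        center = residue_centroid(res)
        flag = ""
        try:
            score = bcc(extract_box(obs_map, center, edge, spacing),
                        extract_box(calc_map, center, edge, spacing))
        except DegenerateBoxError:
            score, flag = np.nan, "degenerate"
        rows.append((res.chain, res.seqnum, res.name, score, flag))
    return pd.DataFrame(rows, columns=["chain", "resnum", "resname", "bcc", "flag"])


def rscc(structure: Structure, obs_map: DensityMap, calc_map: DensityMap,
         residue: Residue, mask_radius: float = 1.5) -> float:
    """Real-space correlation restricted to one residue's atomic footprint.

    A mask-radius Pearson approximation of the conventional per-residue
    RSCC: the correlation between observed and calculated maps over the
    grid points within ``mask_radius`` A of any non-hydrogen atom of the
    residue. Both maps must share one grid.
    """
    if obs_map.shape != calc_map.shape:
        raise ValueError("observed and calculated maps must share a grid")
    if not obs_map.cell.approx_equal(calc_map.cell):
        raise CellMismatchError("observed and calculated map cells differ")
    cell = obs_map.cell
    n = np.array(obs_map.shape)
    mask = np.zeros(obs_map.shape, dtype=bool)
    frac_per_ang = np.linalg.norm(cell.frac_matrix, axis=1)
    orth = cell.orth_matrix
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.key} has no non-hydrogen atoms")
    for atom in heavy:
        f0 = cell.frac_matrix @ atom.pos
        half = np.ceil(mask_radius * frac_per_ang * n).astype(int)
        ctr = np.round(f0 * n).astype(int)
        ax = [np.arange(ctr[k] - half[k], ctr[k] + half[k] + 1) for k in range(3)]
        dfr = [ax[k] / n[k] - f0[k] for k in range(3)]
        dx = (orth[0, 0] * dfr[0][:, None, None] + orth[0, 1] * dfr[1][None, :, None]
              + orth[0, 2] * dfr[2][None, None, :])
        dy = (orth[1, 0] * dfr[0][:, None, None] + orth[1, 1] * dfr[1][None, :, None]
              + orth[1, 2] * dfr[2][None, None, :])
        dz = (orth[2, 0] * dfr[0][:, None, None] + orth[2, 1] * dfr[1][None, :, None]
              + orth[2, 2] * dfr[2][None, None, :])
        within = dx * dx + dy * dy + dz * dz <= mask_radius ** 2
        sub = mask[np.ix_(*[a % n[k] for k, a in enumerate(ax)])]
        mask[np.ix_(*[a % n[k] for k, a in enumerate(ax)])] = sub | within
    if not mask.any():
        raise ValueError("empty RSCC mask; increase mask_radius")
    x = obs_map.values[mask]
    y = calc_map.values[mask]
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = float(xc @ xc), float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise DegenerateBoxError("zero variance inside RSCC mask")
    return float((xc @ yc) / np.sqrt(vx * vy))


def single_atom_contribution(structure: Structure, obs_map: DensityMap,
                             residue: Residue, atom_selector,
                             table: ScatteringTable = None, edge: float = 12.0,
                             spacing: float = 0.5,
                             calc_spacing: float = CALC_SPACING) -> float:
    """Fractional bCC change when one atom leaves the calculated density.

    ``atom_selector`` is either ``(chain, resnum, atom_name)`` or a
    predicate ``f(residue, atom) -> bool`` picking exactly one atom. The
    atom is removed from rho_model,calc only — the observed map is left
    untouched. Returns |bCC_with - bCC_without| / bCC_with; an atom whose
    center lies outside the residue's box yields 0 with a warning.
    """
    table = table or default_table()
    sel_res, sel_atom = _find_atom(structure, atom_selector)
    center = residue_centroid(residue)
    if np.any(np.abs(sel_atom.pos - center) > edge / 2.0):
        warnings.warn(f"selected atom {sel_atom.name} of {sel_res.key} lies outside "
                      f"the {edge} A box; contribution is 0", stacklevel=2)
        return 0.0
    cmap = calculated_map(structure, table, calc_spacing)
    solo = Structure(cell=structure.cell,
                     residues=[Residue(sel_res.chain, sel_res.seqnum, sel_res.name,
                                       [sel_atom], sel_res.het)])
    atom_map = calculated_map(solo, table, calc_spacing)
    obs_box = extract_box(obs_map, center, edge, spacing)
    with_box = extract_box(cmap, center, edge, spacing)
    without = Box(values=with_box.values - extract_box(atom_map, center, edge, spacing).values,
                  edge=edge, spacing=spacing, center=center)
    b_with = bcc(obs_box, with_box)
    b_without = bcc(obs_box, without)
    return abs(b_with - b_without) / abs(b_with)


def _find_atom(structure: Structure, atom_selector):
    matches = []
    if isinstance(atom_selector, tuple) and len(atom_selector) == 3:
        chain, resnum, name = atom_selector
        for res in structure.residues:
            if res.chain == chain and res.seqnum == resnum:
                for a in res.atoms:
                    if a.name == name:
                        matches.append((res, a))
    else:
        for res in structure.residues:
            for a in res.atoms:
                if atom_selector(res, a):
                    matches.append((res, a))
    if len(matches) != 1:
        raise ValueError(f"atom selector matched {len(matches)} atoms; need exactly 1")
    return matches[0]


def ligand_delta_bcc(structure_bound: Structure, structure_unbound: Structure,
                     obs_map: DensityMap, contact_radius: float = 5.0,
                     table: ScatteringTable = None, edge: float = 12.0,
                     spacing: float = 0.5,
                     calc_spacing: float = CALC_SPACING) -> pd.DataFrame:
    """Per-residue bCC difference between ligand-bound and unbound models.

    The two structures must be identical apart from the ligand. Rows are
    restricted to residues with any heavy atom within ``contact_radius``
    (default 5 A) of a ligand atom; the same observed map scores both
    models, with ligand atoms contributing to the bound model's calculated
    density. Delta = bCC_bound - bCC_unbound.
    """
    bound_keys = {r.key for r in structure_bound.residues}
    unbound_keys = {r.key for r in structure_unbound.residues}
    ligand_keys = bound_keys - unbound_keys
    if not ligand_keys:
        raise NoLigandError("bound and unbound structures contain the same residues; "
                            "no ligand found")
    ligand_pos = np.array([a.pos for r in structure_bound.residues
                           if r.key in ligand_keys for a in r.atoms if not a.is_hydrogen])
    _check_cells(structure_bound, obs_map)
    calc_bound = calculated_map(structure_bound, table, calc_spacing)
    calc_unbound = calculated_map(structure_unbound, table, calc_spacing)
    rows = []
    for res in structure_bound.residues:
        if res.key in ligand_keys or not res.is_standard_aa:
            continue
        pos = np.array([a.pos for a in res.heavy_atoms()])
        dmin = np.sqrt(((pos[:, None, :] - ligand_pos[None, :, :]) ** 2).sum(-1)).min()
        if dmin > contact_radius:
            continue
        center = residue_centroid(res)
        obs_box = extract_box(obs_map, center, edge, spacing)
        b_bound = bcc(obs_box, extract_box(calc_bound, center, edge, spacing))
        b_unbound = bcc(obs_box, extract_box(calc_unbound, center, edge, spacing))
        rows.append((res.chain, res.seqnum, res.name, dmin,
                     b_bound, b_unbound, b_bound - b_unbound))
    return pd.DataFrame(rows, columns=["chain", "resnum", "resname",
                                       "ligand_distance", "bcc_bound",
                                       "bcc_unbound", "delta"])
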