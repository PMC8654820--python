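"""Residue-centered cubic voxel boxes and the 24 cube rotations.

A box is N = edge/spacing samples per axis along the orthogonal Cartesian
axes (no per-residue orientation frame — rotation augmentation supplies
orientation invariance), placed symmetrically about the center so the
outermost samples span (N-1)*spacing. The default 12 A / 0.5 A geometry
gives 24x24x24 voxels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np

from .maps import DensityMap
from .structure import Residue

__all__ = ["Box", "RotationSet", "residue_centroid", "extract_box",
           "cube_rotations", "rotate_box", "rotate_voxels"]

# atomic masses for the optional mass-weighted centroid
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass
class Box:
    """Cubic voxel array of density values around a center point."""

    values: np.ndarray
    edge: float
    spacing: float
    center: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        n = self.values.shape[0]
        if self.values.shape != (n, n, n):
            raise ValueError("box values must be a cube")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("box values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def residue_centroid(residue: Residue, mass_weighted: bool = False) -> np.ndarray:
    """Center of gravity of a residue's non-hydrogen atoms (orthogonal A).

    By default the unweighted mean of heavy-atom positions; set
    ``mass_weighted=True`` for an atomic-mass-weighted mean.
    """
    heavy = residue.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {residue.key} has no non-hydrogen atoms")
    pos = np.array([a.pos for a in heavy])
    if not mass_weighted:
        return pos.mean(axis=0)
    w = np.array([_MASS.get(a.element.upper(), 12.0) for a in heavy])
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def box_sample_points(center, edge: float, spacing: float) -> np.ndarray:
    """The (N^3, 3) orthogonal sample positions of a box."""
    n = _box_dim(edge, spacing)
    off = (np.arange(n) - (n - 1) / 2.0) * spacing
    gx, gy, gz = np.meshgrid(off, off, off, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    return pts + np.asarray(center, dtype=float)


def _box_dim(edge: float, spacing: float) -> int:
    n = edge / spacing
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"spacing {spacing} does not divide edge {edge}")
    return int(round(n))


def extract_box(density_map: DensityMap, center, edge: float = 12.0,
                spacing: float = 0.5, provenance: str = "") -> Box:
    """Cut a cubic box out of a periodic map by trilinear interpolation.

    Sample i along each orthogonal axis sits at
    center + (i - (N-1)/2) * spacing, i = 0..N-1.
    """
    n = _box_dim(edge, spacing)
    pts = box_sample_points(center, edge, spacing)
    vals = density_map.sample_orthogonal(pts).reshape(n, n, n)
    return Box(values=vals, edge=float(edge), spacing=float(spacing),
               center=np.asarray(center, dtype=float),
               provenance=provenance or density_map.label)


# ---------------------------------------------------------------------------
# the octahedral rotation group

@dataclass
class RotationSet:
    """The 24 proper rotations mapping a cube's axes onto themselves."""

    matrices: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, k: int) -> np.ndarray:
        return self.matrices[k]


_ROTATIONS: RotationSet = None
_INDEX_CACHE: dict = {}


def cube_rotations() -> RotationSet:
    """All signed axis permutations with determinant +1, in a fixed order."""
    global _ROTATIONS
    if _ROTATIONS is None:
        mats = []
        for perm in permutations(range(3)):
            for signs in product((1, -1), repeat=3):
                m = np.zeros((3, 3), dtype=int)
                for row, (col, s) in enumerate(zip(perm, signs)):
                    m[row, col] = s
                if round(np.linalg.det(m)) == 1:
                    mats.append(m)
        assert len(mats) == 24
        _ROTATIONS = RotationSet(mats)
    return _ROTATIONS


def _voxel_index(n: int, k: int) -> np.ndarray:
    """Flat gather indices realizing rotation k on an (n,n,n) array."""
    key = (n, k)
    cached = _INDEX_CACHE.get(key)
    if cached is not None:
        return cached
    rot = cube_rotations()[k]
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n)).reshape(3, -1).T.astype(float)  # target voxels
    src = (idx - c) @ rot + c        # (R^-1 v) since R^-1 = R^T and (v^T R)^T = R^T v
    src = np.rint(src).astype(np.int64)
    flat = (src[:, 0] * n + src[:, 1]) * n + src[:, 2]
    _INDEX_CACHE[key] = flat
    return flat


def rotate_voxels(values: np.ndarray, k: int) -> np.ndarray:
    """Apply cube rotation k to the trailing three (cubic) axes of an array.

    Pure index permutation — no interpolation; the voxel multiset is
    preserved and rotation 0 is the identity.
    """
    if not 0 <= k < 24:
        raise IndexError(f"rotation index {k} out of range 0..23")
    n = values.shape[-1]
    if values.shape[-3:] != (n, n, n):
        raise ValueError("trailing axes must be cubic")
    flat = _voxel_index(n, k)
    lead = values.shape[:-3]
    out = values.reshape(*lead, -1)[..., flat]
    return out.reshape(values.shape)


def rotate_box(box: Box, k: int) -> Box:
    """Rotated copy of a box; out[v] = in[R_k^{-1} v] about the box center."""
    return Box(values=rotate_voxels(box.values, k), edge=box.edge,
               spacing=box.spacing, center=box.center.copy(),
               provenance=f"{box.provenance}|rot{k}")
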