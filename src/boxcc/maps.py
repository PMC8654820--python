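"""Periodic density maps on a unit-cell grid, with CCP4/MRC file I/O.

Internal storage is always a (nx, ny, nz) array along the crystallographic
a/b/c axes with grid point (i, j, k) at fractional (i/nx, j/ny, k/nz) — the
CCP4 convention without half-cell offset. Files with permuted fast/medium/
slow axis order are normalized on read; writes use canonical a-fast order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .cell import UnitCell
from .errors import FormatError

__all__ = ["DensityMap", "read_map", "write_map"]


@dataclass
class DensityMap:
    """Real density samples over a P1 unit cell, periodic along all axes."""

    cell: UnitCell
    values: np.ndarray
    label: str = "synthetic"      # observed | calculated | synthetic (free text)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density values must be a 3-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    @property
    def spacings(self) -> tuple:
        """Approximate grid spacing (A) along each cell edge."""
        n = self.values.shape
        return (self.cell.a / n[0], self.cell.b / n[1], self.cell.c / n[2])

    # -- sampling -------------------------------------------------------

    def sample_fractional(self, frac: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at fractional coordinates, periodic.

        Exact on densities that are affine in position (within one period)
        and exactly periodic: sampling at x and x+1 agree bitwise.
        """
        frac = np.atleast_2d(np.asarray(frac, dtype=float))
        n = np.array(self.values.shape)
        g = (frac % 1.0) * n                      # in [0, n)
        i0 = np.floor(g).astype(np.int64)
        t = g - i0
        i0 %= n
        i1 = (i0 + 1) % n
        v = self.values
        ix0, iy0, iz0 = i0[:, 0], i0[:, 1], i0[:, 2]
        ix1, iy1, iz1 = i1[:, 0], i1[:, 1], i1[:, 2]
        tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
        c000 = v[ix0, iy0, iz0]
        c100 = v[ix1, iy0, iz0]
        c010 = v[ix0, iy1, iz0]
        c110 = v[ix1, iy1, iz0]
        c001 = v[ix0, iy0, iz1]
        c101 = v[ix1, iy0, iz1]
        c011 = v[ix0, iy1, iz1]
        c111 = v[ix1, iy1, iz1]
        c00 = c000 * (1 - tx) + c100 * tx
        c10 = c010 * (1 - tx) + c110 * tx
        c01 = c001 * (1 - tx) + c101 * tx
        c11 = c011 * (1 - tx) + c111 * tx
        c0 = c00 * (1 - ty) + c10 * ty
        c1 = c01 * (1 - ty) + c11 * ty
        return c0 * (1 - tz) + c1 * tz

    def sample_orthogonal(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at orthogonal-A positions."""
        return self.sample_fractional(self.cell.fractionalize(points))


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (mode 2, float32)

def read_map(path) -> DensityMap:
    """Read a CCP4/MRC mode-2 map; axis order is normalized to a,b,c.

    Raises :class:`FormatError` for non-float modes or headers whose grid
    extents do not cover a full (consistent) unit cell.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise FormatError(f"unsupported CCP4/MRC mode {mode} in {path}; only mode 2 (float32)")
    try:
        m.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"inconsistent map header in {path}: {exc}") from exc
    values = np.array(m.grid, copy=True)
    if not np.all(np.isfinite(values)):
        raise FormatError(
            f"map {path} does not cover the full unit cell (header dimensions inconsistent)")
    gc = m.grid.unit_cell
    cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    return DensityMap(cell=cell, values=values, label="observed")


def write_map(density_map: DensityMap, path) -> None:
    """Write as CCP4 mode 2 (float32), canonical a-fast axis order.

    Values round-trip to float32 precision; the header cell equals the
    map's cell to float32 precision.
    """
    grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.values, dtype=np.float32))
    grid.unit_cell = density_map.cell.to_gemmi()
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))
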