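"""Structure factors and Fourier-space map manipulation (P1 only).

F(hkl) = sum_atoms occ * f_el(s) * exp(-B_iso s^2) * exp(2 pi i h.x_frac)
with s = sin(theta)/lambda = 1/(2 d_hkl) and f_el(s) = sum_j a_j exp(-b_j s^2) + c.
The Debye-Waller convention exp(-(B+b_j) s^2) is the exact Fourier pair of
the real-space Gaussian density used by :mod:`boxcc.density`, so direct-sum
and FFT-synthesized maps agree at matched B.

Reflections are stored as the Friedel-unique half set (plus F(000)); full
sets are reconstructed with F(-h) = conj(F(h)) when synthesizing maps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cell import UnitCell
from .errors import GridTooCoarseError
from .maps import DensityMap
from .scattering import ScatteringTable, default_table
from .structure import Structure

__all__ = [
    "ReflectionSet", "structure_factors", "map_from_reflections",
    "truncate_resolution", "add_reflection_noise",
    "write_reflections", "read_reflections",
]


@dataclass
class ReflectionSet:
    """Friedel-unique Miller indices with complex structure factors (e)."""

    cell: UnitCell
    d_min: float
    hkl: np.ndarray       # (M, 3) int
    f: np.ndarray         # (M,) complex

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=complex).reshape(-1)
        if len(self.hkl) != len(self.f):
            raise ValueError("hkl and F lengths differ")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacings(self.hkl)

    def f000(self) -> complex:
        mask = np.all(self.hkl == 0, axis=1)
        return complex(self.f[mask][0]) if mask.any() else 0j

    def expand_friedel(self) -> tuple[np.ndarray, np.ndarray]:
        """Full set (h, -h pairs) with F(-h) = conj(F(h))."""
        nonzero = ~np.all(self.hkl == 0, axis=1)
        hkl_full = np.vstack([self.hkl, -self.hkl[nonzero]])
        f_full = np.concatenate([self.f, np.conj(self.f[nonzero])])
        return hkl_full, f_full

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.cell, self.d_min, self.hkl.copy(), self.f.copy())


def _unique_half_mask(hkl: np.ndarray) -> np.ndarray:
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    return (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l >= 0))


def all_indices_to(cell: UnitCell, d_min: float, unique: bool = True) -> np.ndarray:
    """All Miller indices with d >= d_min (Friedel-unique half if requested)."""
    hmax = [int(np.floor(edge / d_min)) + 1 for edge in (cell.a, cell.b, cell.c)]
    ax = [np.arange(-m, m + 1) for m in hmax]
    hh, kk, ll = np.meshgrid(*ax, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    d = cell.d_spacings(hkl)
    hkl = hkl[d >= d_min - 1e-9]
    if unique:
        hkl = hkl[_unique_half_mask(hkl)]
    # deterministic order
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def structure_factors(structure: Structure, d_min: float,
                      b_override: Optional[float] = None,
                      table: ScatteringTable = None) -> ReflectionSet:
    """Direct-summation structure factors for all unique hkl with d >= d_min.

    F(000) equals the occupancy-weighted total electron count. Per-atom
    B_iso is used unless ``b_override`` is given.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    table = table or default_table()
    cell = structure.cell
    hkl = all_indices_to(cell, d_min, unique=True)
    d = cell.d_spacings(hkl)
    with np.errstate(divide="ignore"):
        s2 = 1.0 / (4.0 * d * d)          # (sin theta / lambda)^2
    s2[~np.isfinite(s2)] = 0.0

    f = np.zeros(len(hkl), dtype=complex)
    frac_mat = cell.frac_matrix
    atoms = [a for a in structure.atoms() if a.occupancy != 0.0]
    # group atoms by (element, B) to share the form-factor profile
    groups: dict = {}
    for a in atoms:
        b = float(b_override) if b_override is not None else a.b_iso
        groups.setdefault((a.element.upper(), b), []).append(a)
    for (element, b), members in groups.items():
        co = table.coefficients(element)
        a_coef = np.array(co.a)
        b_coef = np.array(co.b)
        # f_el(s) * exp(-B s^2) with the constant folded at width B
        ff = (a_coef[None, :] * np.exp(-(b_coef + b)[None, :] * s2[:, None])).sum(axis=1)
        ff = ff + co.c * np.exp(-b * s2)
        frac = np.array([frac_mat @ m.pos for m in members])          # (A, 3)
        occ = np.array([m.occupancy for m in members])
        phase = np.exp(2j * np.pi * (hkl @ frac.T))                   # (M, A)
        f += ff * (phase @ occ)
    return ReflectionSet(cell=cell, d_min=float(d_min), hkl=hkl, f=f)


def map_from_reflections(reflections: ReflectionSet, grid_dims,
                         label: str = "calculated") -> DensityMap:
    """Inverse-FFT map synthesis: rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    The grid must hold every reflection without aliasing: each dimension
    needs at least 2*cell_edge/d_min points (checked against the actual
    index range too). The imaginary residue of the synthesized map is
    verified to be < 1e-8 relative.
    """
    dims = tuple(int(d) for d in grid_dims)
    cell = reflections.cell
    for axis, (edge, nd) in enumerate(zip((cell.a, cell.b, cell.c), dims)):
        if nd < 2.0 * edge / reflections.d_min:
            raise GridTooCoarseError(
                f"grid dim {nd} on axis {axis} below Nyquist 2*{edge:.1f}/{reflections.d_min}")
    hkl_full, f_full = reflections.expand_friedel()
    if len(hkl_full):
        max_idx = np.abs(hkl_full).max(axis=0)
        if np.any(max_idx * 2 >= np.array(dims)):
            raise GridTooCoarseError(
                f"grid dims {dims} cannot index reflections up to {max_idx}")
    fgrid = np.zeros(dims, dtype=complex)
    idx = hkl_full % np.array(dims)
    fgrid[idx[:, 0], idx[:, 1], idx[:, 2]] = f_full
    rho = np.fft.fftn(fgrid) / cell.volume
    scale = np.abs(rho.real).max()
    if scale > 0 and np.abs(rho.imag).max() > 1e-8 * scale:
        raise ValueError("synthesized map has non-negligible imaginary part; "
                         "input reflections violate Friedel symmetry")
    return DensityMap(cell=cell, values=rho.real, label=label)


def default_fft_grid(cell: UnitCell, d_min: float) -> tuple:
    """Smallest even dims with >= 3 samples per d_min (1.5x Nyquist)."""
    dims = []
    for edge in (cell.a, cell.b, cell.c):
        n = int(np.ceil(3.0 * edge / d_min))
        dims.append(n + (n % 2))
    return tuple(dims)


def truncate_resolution(reflections: ReflectionSet, d_min_new: float) -> ReflectionSet:
    """Keep exactly the reflections with d >= d_min_new (F(000) survives).

    Surviving F values are carried over bitwise; deterministic.
    """
    if d_min_new < reflections.d_min - 1e-9:
        raise ValueError(
            f"cannot truncate to finer resolution ({d_min_new} < {reflections.d_min})")
    keep = reflections.d_spacings >= d_min_new - 1e-9
    return ReflectionSet(cell=reflections.cell, d_min=float(d_min_new),
                         hkl=reflections.hkl[keep].copy(), f=reflections.f[keep].copy())


def add_reflection_noise(reflections: ReflectionSet, relative_sigma: float,
                         seed: int) -> ReflectionSet:
    """Perturb each F (except F(000)) with complex Gaussian noise.

    Noise std is ``relative_sigma`` times the RMS |F| over non-origin
    reflections, split evenly between real and imaginary parts; the stored
    half set keeps Friedel symmetry intact by construction. Reproducible
    under a fixed seed; sigma 0 returns an identical copy.
    """
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    out = reflections.copy()
    if relative_sigma == 0 or len(out) == 0:
        return out
    origin = np.all(out.hkl == 0, axis=1)
    work = ~origin
    if not work.any():
        return out
    rms = np.sqrt(np.mean(np.abs(out.f[work]) ** 2))
    rng = np.random.default_rng(seed)
    scale = relative_sigma * rms / np.sqrt(2.0)
    noise = rng.normal(0.0, scale, size=(int(work.sum()), 2))
    out.f[work] += noise[:, 0] + 1j * noise[:, 1]
    return out


# ---------------------------------------------------------------------------
# plain-text serialization (h k l F_re F_im)

_HEADER = "# boxcc reflections v1"


def write_reflections(reflections: ReflectionSet, path) -> None:
    c = reflections.cell
    with open(path, "w") as fh:
        fh.write(f"{_HEADER}\n")
        fh.write(f"# cell {c.a:.6f} {c.b:.6f} {c.c:.6f} {c.alpha:.6f} {c.beta:.6f} {c.gamma:.6f}\n")
        fh.write(f"# d_min {reflections.d_min:.6f}\n")
        fh.write("# h k l F_real F_imag\n")
        for (h, k, l), f in zip(reflections.hkl, reflections.f):
            fh.write(f"{h} {k} {l} {f.real:.10e} {f.imag:.10e}\n")


def read_reflections(path) -> ReflectionSet:
    cell = d_min = None
    hkl, fs = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["cell"]:
                    cell = UnitCell(*map(float, parts[1:7]))
                elif parts[:1] == ["d_min"]:
                    d_min = float(parts[1])
                continue
            h, k, l, fre, fim = line.split()
            hkl.append((int(h), int(k), int(l)))
            fs.append(float(fre) + 1j * float(fim))
    if cell is None or d_min is None:
        raise ValueError(f"{path}: missing cell or d_min header")
    return ReflectionSet(cell=cell, d_min=d_min, hkl=np.array(hkl), f=np.array(fs))
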