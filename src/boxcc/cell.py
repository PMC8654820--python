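"""Crystallographic unit cell with fractional/orthogonal coordinate transforms.

The orthogonalization convention is the PDB one (a along x, b in the x-y
plane), delegated to gemmi and cached as plain 3x3 numpy matrices so that
point transforms vectorize.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["UnitCell"]


@dataclass(frozen=True)
class UnitCell:
    """Unit cell: edge lengths in Angstrom, angles in degrees.

    Fractionalization and orthogonalization are mutual inverses to well
    below 1e-10 relative error for any valid cell.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    _orth: np.ndarray = field(init=False, repr=False, compare=False)
    _frac: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        ca, cb, cg = np.cos(np.deg2rad([self.alpha, self.beta, self.gamma]))
        # squared volume factor; <= 0 means the three angles cannot close
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if not disc > 1e-12:
            raise ValueError(
                f"cell angles ({self.alpha}, {self.beta}, {self.gamma}) do not "
                "define a valid parallelepiped")
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        orth = np.array(g.orth.mat.tolist(), dtype=float)
        object.__setattr__(self, "_orth", orth)
        object.__setattr__(self, "_frac", np.linalg.inv(orth))

    # -- transforms ------------------------------------------------------

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix mapping fractional to orthogonal (A) coordinates."""
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        """3x3 matrix mapping orthogonal (A) to fractional coordinates."""
        return self._frac

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> orthogonal A. Accepts (3,) or (N, 3) arrays."""
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        """Orthogonal A -> fractional. Accepts (3,) or (N, 3) arrays."""
        return np.asarray(orth, dtype=float) @ self._frac.T

    # -- derived quantities ---------------------------------------------

    @property
    def volume(self) -> float:
        """Cell volume in A^3."""
        return float(abs(np.linalg.det(self._orth)))

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Lattice-plane spacing d (A) for Miller indices, (N, 3) -> (N,).

        Uses 1/d^2 = h^T (M^T M)^{-1} h with M the orthogonalization matrix;
        valid for any (including triclinic) cell. d of (0,0,0) is inf.
        """
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self._frac @ self._frac.T
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def approx_equal(self, other: "UnitCell", rel: float = 1e-3) -> bool:
        """True if all six parameters agree within relative tolerance."""
        mine = np.array([self.a, self.b, self.c, self.alpha, self.beta, self.gamma])
        theirs = np.array([other.a, other.b, other.c, other.alpha, other.beta, other.gamma])
        return bool(np.all(np.abs(mine - theirs) <= rel * np.abs(mine)))

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
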