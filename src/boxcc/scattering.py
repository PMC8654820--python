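"""Gaussian atomic scattering-factor tables.

Each element carries five Gaussian terms (a_i, b_i) plus a constant c, with
f(s) = sum_i a_i exp(-b_i s^2) + c  at  s = sin(theta)/lambda = 1/(2d),
so that f(0) = sum(a_i) + c equals the electron count Z. The shipped table
is the standard analytic X-ray fit (Cromer-Mann form); it lives in a
versioned JSON data file and can be swapped for another parameterization.

The constant term has no intrinsic width, so in real space it is folded in
as an extra Gaussian whose width comes from B_iso alone (policy
"fold_as_zero_width_gaussian"); this preserves f(0) = Z exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import UnknownElementError

__all__ = ["ElementCoefficients", "ScatteringTable", "default_table"]


@dataclass(frozen=True)
class ElementCoefficients:
    a: tuple  # electrons, 5 Gaussian amplitudes
    b: tuple  # A^2, 5 Gaussian widths (all > 0)
    c: float  # electrons, constant term
    z: int    # electron count of the neutral atom

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 5:
            raise ValueError("expected 5 Gaussian terms per element")
        if any(b <= 0 for b in self.b):
            raise ValueError("all Gaussian b_i must be > 0")

    @property
    def f0(self) -> float:
        """Forward-scattering amplitude f(0) = sum(a) + c, in electrons."""
        return float(sum(self.a) + self.c)


class ScatteringTable:
    """Per-element Gaussian scattering coefficients with a fold-in policy."""

    def __init__(self, elements: Mapping[str, ElementCoefficients],
                 name: str = "custom", fold_constant: bool = True):
        self.name = name
        self.fold_constant = fold_constant
        self._elements = dict(elements)

    def __contains__(self, element: str) -> bool:
        return element.upper() in self._elements

    @property
    def elements(self) -> tuple:
        return tuple(self._elements)

    def coefficients(self, element: str) -> ElementCoefficients:
        try:
            return self._elements[element.upper()]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} not in scattering table {self.name!r} "
                f"(available: {', '.join(self._elements)})") from None

    def gaussian_terms(self, element: str, b_iso: float) -> tuple[np.ndarray, np.ndarray]:
        """Effective (amplitude, width) term lists for real-space density.

        Returns amplitudes a_j (electrons) and widths B_iso + b_j (A^2),
        with the constant term appended as (c, B_iso) when folding is on.
        Zero-amplitude padding terms are dropped.
        """
        co = self.coefficients(element)
        a = np.array(co.a, dtype=float)
        b = np.array(co.b, dtype=float) + b_iso
        keep = a != 0.0
        a, b = a[keep], b[keep]
        if self.fold_constant:
            a = np.append(a, co.c)
            b = np.append(b, b_iso)
        if np.any(b <= 0):
            raise ValueError(
                f"effective Gaussian width <= 0 for {element} at B_iso={b_iso}; "
                "B_iso=0 requires all effective b terms > 0")
        return a, b

    def form_factor(self, element: str, s: np.ndarray) -> np.ndarray:
        """f(s) in electrons at s = sin(theta)/lambda = 1/(2d), vectorized."""
        co = self.coefficients(element)
        s2 = np.asarray(s, dtype=float) ** 2
        a = np.array(co.a)[:, None]
        b = np.array(co.b)[:, None]
        return (a * np.exp(-b * s2.ravel()[None, :])).sum(axis=0).reshape(np.shape(s2)) + co.c

    @classmethod
    def from_json(cls, path_or_dict) -> "ScatteringTable":
        if isinstance(path_or_dict, dict):
            doc = path_or_dict
        else:
            with open(path_or_dict) as fh:
                doc = json.load(fh)
        elements = {
            sym: ElementCoefficients(tuple(rec["a"]), tuple(rec["b"]), rec["c"], rec["z"])
            for sym, rec in doc["elements"].items()
        }
        fold = doc.get("constant_policy", "fold_as_zero_width_gaussian") == "fold_as_zero_width_gaussian"
        return cls(elements, name=f"{doc.get('name', 'table')}-v{doc.get('version', 0)}",
                   fold_constant=fold)


_DEFAULT = None


def default_table() -> ScatteringTable:
    """The shipped X-ray table (H, C, N, O, S), loaded once."""
    global _DEFAULT
    if _DEFAULT is None:
        doc = json.loads(resources.files("boxcc.data").joinpath("scattering_xray.json").read_text())
        _DEFAULT = ScatteringTable.from_json(doc)
    return _DEFAULT
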