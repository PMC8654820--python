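"""Idealized amino-acid templates built from internal coordinates.

Each template lists its side-chain atoms as z-matrix rows (bond length,
bond angle, dihedral) relative to already-placed atoms; backbone atoms
N/CA/C/O come from standard peptide geometry. Placement uses the standard
NeRF construction. Eleven residue types are shipped — enough compositional
variety (including one- and two-ring-free S carriers CYS/MET and the
aromatic PHE) for synthetic training corpora; they are idealized
stand-ins, not rotamer-library conformers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidueTemplate", "TEMPLATES", "place_atom", "BACKBONE_GEOMETRY"]


def place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position a new atom bonded to p3 with angle p2-p3-new and dihedral
    p1-p2-p3-new (NeRF construction)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        # colinear reference atoms: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(ang),
                  bond * np.sin(ang) * np.cos(dih),
                  bond * np.sin(ang) * np.sin(dih)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


# peptide backbone ideal values (lengths A, angles deg)
BACKBONE_GEOMETRY = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "angle_n_ca_c": 111.0, "angle_ca_c_n": 116.6, "angle_c_n_ca": 121.7,
    "angle_ca_c_o": 120.8,
    # alpha-helical torsions
    "phi": -57.0, "psi": -47.0, "omega": 180.0,
}


@dataclass(frozen=True)
class ResidueTemplate:
    """One residue type: side-chain z-matrix rows over the N/CA/C frame.

    Each row is (atom_name, element, (ref1, ref2, ref3), bond, angle,
    dihedral) where the dihedral may be a number (degrees) or a chi label
    ("chi1".."chi4", optionally "+<offset>") resolved at build time.
    """

    name: str
    sidechain: tuple
    n_chi: int = 0

    @property
    def heavy_atom_names(self) -> tuple:
        return ("N", "CA", "C", "O") + tuple(row[0] for row in self.sidechain)


def _t(name, sidechain, n_chi=0):
    return ResidueTemplate(name=name, sidechain=tuple(sidechain), n_chi=n_chi)


# CB placement: improper dihedral C-N-CA-CB ~ +122.6 deg gives the
# conventional L chirality under this frame ordering.
_CB = ("CB", "C", ("C", "N", "CA"), 1.530, 110.5, 122.6)

TEMPLATES = {
    "GLY": _t("GLY", []),
    "ALA": _t("ALA", [_CB]),
    "SER": _t("SER", [_CB, ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, "chi1")], 1),
    "CYS": _t("CYS", [_CB, ("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, "chi1")], 1),
    "THR": _t("THR", [_CB,
                      ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, "chi1"),
                      ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, "chi1+120")], 1),
    "VAL": _t("VAL", [_CB,
                      ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, "chi1"),
                      ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, "chi1+122")], 1),
    "LEU": _t("LEU", [_CB,
                      ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, "chi1"),
                      ("CD1", "C", ("CA", "CB", "CG"), 1.524, 110.7, "chi2"),
                      ("CD2", "C", ("CA", "CB", "CG"), 1.525, 110.7, "chi2+122")], 2),
    "ASP": _t("ASP", [_CB,
                      ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
                      ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, "chi2"),
                      ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, "chi2+180")], 2),
    "MET": _t("MET", [_CB,
                      ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
                      ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, "chi2"),
                      ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, "chi3")], 3),
    "LYS": _t("LYS", [_CB,
                      ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, "chi1"),
                      ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, "chi2"),
                      ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, "chi3"),
                      ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, "chi4")], 4),
    "PHE": _t("PHE", [_CB,
                      ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, "chi1"),
                      ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, "chi2"),
                      ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, "chi2+180"),
                      ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
                      ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
                      ("CZ", "C", ("CG", "CD1", "CE1"), 1.372, 120.0, 0.0)], 2),
}

# ideal chi defaults (deg): roughly the most common rotamer
DEFAULT_CHI = {"chi1": -65.0, "chi2": 175.0, "chi3": 175.0, "chi4": 175.0}


def resolve_dihedral(spec, chi: dict) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if "+" in spec:
        base, off = spec.split("+")
        return chi[base] + float(off)
    return chi[spec]
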