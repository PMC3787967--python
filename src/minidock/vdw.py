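"""Van der Waals parameter table in the geometric-combination convention.

For a 12-6 potential E = A/r^12 - B/r^6 between an atom pair, geometric
combination lets the receptor grids store sums of sqrt(A_k)/r^12 and
sqrt(B_k)/r^6 while each ligand atom contributes its own sqrt(A), sqrt(B)
multipliers.  Coefficients here derive from generic single-atom Lennard-Jones
well depths/radii (A = eps * rmin^12, B = 2 * eps * rmin^6), keyed by TRIPOS
atom type; they are conventional values adequate for grid scoring, not a
fitted force field.
"""

from __future__ import annotations

import math

__all__ = ["VDW_TABLE", "lookup_vdw", "lj_to_sqrt_ab"]


def lj_to_sqrt_ab(epsilon: float, rmin: float) -> tuple[float, float]:
    """(sqrt A, sqrt B) from a well depth (kcal/mol) and minimum distance (A)."""
    a = epsilon * rmin**12
    b = 2.0 * epsilon * rmin**6
    return math.sqrt(a), math.sqrt(b)


# element/type -> (epsilon kcal/mol, rmin A); generic AMBER-like magnitudes
_LJ = {
    "C.3": (0.11, 3.90), "C.2": (0.09, 3.85), "C.ar": (0.09, 3.85), "C.1": (0.09, 3.80),
    "N.3": (0.17, 3.65), "N.2": (0.17, 3.65), "N.ar": (0.17, 3.65), "N.am": (0.17, 3.65),
    "N.4": (0.17, 3.65), "N.pl3": (0.17, 3.65),
    "O.3": (0.21, 3.35), "O.2": (0.21, 3.30), "O.co2": (0.21, 3.30),
    "S.3": (0.25, 4.00), "S.2": (0.25, 4.00),
    "P.3": (0.20, 4.20),
    "F": (0.061, 3.50), "Cl": (0.27, 3.90), "Br": (0.32, 4.10), "I": (0.40, 4.40),
    "H": (0.015, 1.50),
}

VDW_TABLE: dict[str, tuple[float, float]] = {
    key: lj_to_sqrt_ab(eps, rmin) for key, (eps, rmin) in _LJ.items()
}


def lookup_vdw(vdw_class: str) -> tuple[float, float]:
    """(sqrt A, sqrt B) for a vdW class; falls back to the element prefix."""
    if vdw_class in VDW_TABLE:
        return VDW_TABLE[vdw_class]
    prefix = vdw_class.split(".")[0]
    for key, val in VDW_TABLE.items():
        if key.split(".")[0] == prefix:
            return val
    return VDW_TABLE["C.3"]
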