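"""Shared parameter tables: van der Waals radii and Lennard-Jones constants.

Bondi-type vdW radii (Å) and generic per-element 12-6 parameters. Both are
deliberately coarse — they parameterize a reduced-representation energy
stand-in, not a transferable force field — and both can be overridden from a
YAML config.
"""

from __future__ import annotations

import math

# Bondi-type vdW radii, Å
VDW_RADII_A: dict[str, float] = {
    "H": 1.1,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "X": 2.0,   # unified side-chain / methyl pseudo-atom
    "D": 2.2,   # dye-marker pseudo-atom
    "CU": 1.4,
}

# Per-element LJ well depth (kcal/mol); sigma derived from the vdW radius
LJ_EPSILON_KCAL: dict[str, float] = {
    "H": 0.02,
    "C": 0.10,
    "N": 0.16,
    "O": 0.20,
    "S": 0.25,
    "P": 0.20,
    "X": 0.12,
    "D": 0.12,
    "CU": 0.05,
}

COULOMB_KCAL_A = 332.0637  # kcal mol^-1 Å e^-2

# 2^(-1/6): converts an LJ r_min (sum of vdW radii) to sigma
_RMIN_TO_SIGMA = 2.0 ** (-1.0 / 6.0)


def vdw_radius(element: str) -> float:
    return VDW_RADII_A.get(element.upper(), VDW_RADII_A["X"])


def lj_epsilon(element: str) -> float:
    return LJ_EPSILON_KCAL.get(element.upper(), 0.1)


def lj_sigma_pair(r_i: float, r_j: float) -> float:
    """Pair sigma from vdW radii: r_min = r_i + r_j, sigma = r_min * 2^(-1/6)."""
    return (r_i + r_j) * _RMIN_TO_SIGMA


def lj_epsilon_pair(eps_i: float, eps_j: float) -> float:
    return math.sqrt(eps_i * eps_j)
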