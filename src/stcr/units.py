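"""Nutrient unit-basis handling.

Phosphorus and potassium quantities circulate in two conventions: as the
elements (P, K) or as the oxides (P2O5, K2O) that fertilizer labels and many
soil-test reports use.  Mixing the two silently is the single most common
source of arithmetic error in soil-test crop response work, so every quantity
in this package carries an explicit basis and conversions go through the
functions here.

The canonical internal basis is ELEMENTAL; oxide values appear only at I/O
and metric boundaries.
"""

from __future__ import annotations

import math

__all__ = [
    "ELEMENTAL",
    "OXIDE",
    "P_TO_P2O5",
    "K_TO_K2O",
    "check_basis",
    "convert_value",
]

ELEMENTAL = "elemental"
OXIDE = "oxide"
_BASES = (ELEMENTAL, OXIDE)

# Stoichiometric mass ratios P2O5/2P and K2O/2K, rounded to the conventional
# agronomic constants.  The extra digits of the exact ratios (2.2914, 1.2046)
# change downstream results by <0.1%.
P_TO_P2O5 = 2.29
K_TO_K2O = 1.205


def check_basis(basis: str) -> str:
    """Validate a basis token, returning it normalised to lower case."""
    b = str(basis).lower()
    if b not in _BASES:
        raise ValueError(f"unknown nutrient basis {basis!r}; expected one of {_BASES}")
    return b


def convert_value(
    value: float,
    nutrient: str,
    from_basis: str,
    to_basis: str,
    *,
    p_factor: float = P_TO_P2O5,
    k_factor: float = K_TO_K2O,
) -> float:
    """Convert one quantity between elemental and oxide bases.

    Nitrogen is identical under both bases; P is multiplied by ``p_factor``
    (elemental -> oxide) or divided (oxide -> elemental), K likewise with
    ``k_factor``.  Converting to the current basis is the identity.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r} for nutrient {nutrient!r}")
    from_basis = check_basis(from_basis)
    to_basis = check_basis(to_basis)
    nutrient = nutrient.lower()
    if nutrient not in ("n", "p", "k"):
        raise ValueError(f"unknown nutrient {nutrient!r}")
    if from_basis == to_basis or nutrient == "n":
        return value
    factor = {"p": p_factor, "k": k_factor}[nutrient]
    if from_basis == ELEMENTAL:  # -> oxide
        return value * factor
    return value / factor
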