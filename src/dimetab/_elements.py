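"""Monoisotopic atomic masses used throughout the package.

Values are IUPAC/CODATA monoisotopic masses in Da (unified atomic mass
units), quoted to >= 6 decimal places. All neutral-molecule masses in the
package are computed from these constants; nothing is rounded before
mass-difference matching.
"""

from __future__ import annotations

# IUPAC 2021 monoisotopic masses (most abundant isotope), Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,           # definition of the unified atomic mass unit
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

ELEMENTS = ("C", "H", "O", "N", "S", "P")


def formula_mass(composition: dict[str, int]) -> float:
    """Neutral monoisotopic mass of an elemental composition.

    Parameters
    ----------
    composition : mapping of element symbol -> integer count (e.g.
        ``{"C": 6, "H": 12, "O": 6}`` for glucose).
    """
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in composition.items())
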