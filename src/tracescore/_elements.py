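"""Natural isotopic-abundance constants.

Each element maps to an ordered tuple of ``(mass_shift, probability)`` pairs,
where the mass shift is the nominal mass difference from the most abundant
(lightest listed) isotope. Values are IUPAC representative isotopic
compositions; probabilities sum to 1 per element.
"""

from __future__ import annotations

# IUPAC 2021 representative isotopic composition, by nominal mass shift.
NATURAL_ABUNDANCE: dict[str, tuple[tuple[int, float], ...]] = {
    "H": ((0, 0.999885), (1, 0.000115)),
    "C": ((0, 0.9893), (1, 0.0107)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "P": ((0, 1.0),),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
    "Si": ((0, 0.92223), (1, 0.04685), (2, 0.03092)),
    "Cl": ((0, 0.7576), (2, 0.2424)),
}

RECOGNIZED_ELEMENTS = frozenset(NATURAL_ABUNDANCE)
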