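"""Physical constants shared across the package.

Monoisotopic atomic masses and isotopic abundances are pinned to fixed
values (IUPAC representative abundances) so that every mass printed by
this package is bit-reproducible across platforms and library versions.
"""

from __future__ import annotations

# Monoisotopic masses of the lightest isotope, Da.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON_MASS: float = 1.00727646

# Per-element isotope tables: list of (mass Da, abundance fraction),
# ordered by mass. IUPAC 2013 representative values.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088989, 0.00364)],
    "O": [
        (15.9949146221, 0.99757),
        (16.9991315, 0.00038),
        (17.9991604, 0.00205),
    ],
    "S": [
        (31.97207069, 0.9499),
        (32.9714585, 0.0075),
        (33.9678668, 0.0425),
        (35.9670809, 0.0001),
    ],
}

#: Mass difference between 18O and 16O, Da.
O18_SHIFT: float = ISOTOPES["O"][2][0] - ISOTOPES["O"][0][0]

#: MALDI-TOF reflector centroid grid: peaks closer than this are merged.
MERGE_TOLERANCE: float = 0.2

WATER_MONO_MASS: float = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]
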