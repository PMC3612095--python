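"""Published DNA geometry parameter sets used by the curvature/bendability profiles.

Two scales are embedded:

* ``WEDGE_ANGLES`` — the dinucleotide wedge model (twist, wedge magnitude and
  wedge direction, all in degrees) derived from gel-mobility data. Roll and
  tilt components are obtained as ``wedge * cos(direction)`` and
  ``wedge * sin(direction)``. The table is reverse-complement symmetric:
  complementary steps share twist and wedge and have opposite directions.

* ``BENDABILITY`` — the trinucleotide DNase I sensitivity scale
  (dimensionless), defined on 32 complement classes; each trinucleotide and
  its reverse complement share a value. Higher values mean a more flexible
  (bendable) step.

Both are plain dicts so that alternative parameter sets can be swapped in.
"""

from __future__ import annotations

import math

from .genome import reverse_complement

# dinucleotide -> (twist, wedge, direction), degrees
WEDGE_ANGLES: dict[str, tuple[float, float, float]] = {
    "AA": (35.62, 7.2, -154.0),
    "AC": (34.40, 1.1, 143.0),
    "AG": (27.70, 8.4, 2.0),
    "AT": (31.50, 2.6, 0.0),
    "CA": (34.50, 3.5, -64.0),
    "CC": (33.67, 2.1, -57.0),
    "CG": (29.80, 6.7, 0.0),
    "CT": (27.70, 8.4, -2.0),
    "GA": (36.90, 5.3, 120.0),
    "GC": (40.00, 5.0, 180.0),
    "GG": (33.67, 2.1, 57.0),
    "GT": (34.40, 1.1, -143.0),
    "TA": (36.00, 0.9, 0.0),
    "TC": (36.90, 5.3, -120.0),
    "TG": (34.50, 3.5, 64.0),
    "TT": (35.62, 7.2, 154.0),
}

# 32 complement classes of the trinucleotide DNase I bendability scale.
_BENDABILITY_CLASSES: dict[str, float] = {
    "AAT": -0.280, "AAA": -0.274, "CCA": -0.246, "AAC": -0.205,
    "ACT": -0.183, "CCG": -0.136, "ATC": -0.110, "AAG": -0.081,
    "CGC": -0.077, "AGG": -0.057, "GAA": -0.037, "ACG": -0.033,
    "ACC": -0.032, "GAC": -0.013, "CCC": -0.012, "ACA": -0.006,
    "CGA": -0.003, "GGA": 0.013, "CAA": 0.015, "AGC": 0.017,
    "GTA": 0.025, "AGA": 0.027, "CTC": 0.031, "CAC": 0.040,
    "TAA": 0.068, "GCA": 0.076, "CTA": 0.090, "GCC": 0.107,
    "ATG": 0.134, "CAG": 0.175, "ATA": 0.182, "TCA": 0.194,
}

BENDABILITY: dict[str, float] = {}
for _tri, _v in _BENDABILITY_CLASSES.items():
    BENDABILITY[_tri] = _v
    BENDABILITY[reverse_complement(_tri)] = _v


def roll_tilt_twist(dinucleotide: str) -> tuple[float, float, float]:
    """Roll, tilt and twist angles (degrees) for a dinucleotide step."""
    twist, wedge, direction = WEDGE_ANGLES[dinucleotide]
    rad = math.radians(direction)
    return wedge * math.cos(rad), wedge * math.sin(rad), twist
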