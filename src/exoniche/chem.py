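"""Exact-mass bookkeeping for small-molecule ions.

Monoisotopic element masses, adduct (ion-type) rules, and elemental-formula
helpers shared by ion grouping, formula assignment and the synthetic
generator. Electron mass is carried implicitly by using cation/anion masses
(e.g. the proton, not atomic H) in adduct shifts; the residual error is far
below the m/z tolerances used anywhere in the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

# Monoisotopic masses of the principal isotope, Da (CODATA / AME2020).
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Contribution of each element to the M+1/M intensity ratio
#: (minor-isotope / major-isotope natural abundance: 13C, 2H, 15N, 17O, 33S).
ISOTOPE_M1_RATIO: dict[str, float] = {
    "C": 0.0107 / 0.9893,
    "H": 0.000115 / 0.999885,
    "N": 0.003640 / 0.996360,
    "O": 0.000380 / 0.997570,
    "S": 0.007500 / 0.949900,
}

PROTON_MASS = 1.00727646688
#: NH4+, Na+ and CH3COO- ion masses (electron accounted for).
AMMONIUM_MASS = 18.03382553
SODIUM_ION_MASS = 22.98922070
ACETATE_MASS = 59.01385292

ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class AdductRule:
    """One ion type: how a neutral molecule M maps to an observed m/z.

    m/z = (multiplicity * M + mass_shift) / charge.  ``characteristic``
    marks the ion species eligible to quantify a metabolite (protonated,
    deprotonated or ammoniated molecule).
    """

    name: str
    polarity: str  # "positive" | "negative"
    multiplicity: int = 1
    mass_shift: float = 0.0
    charge: int = 1
    characteristic: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if self.multiplicity < 1 or self.charge < 1:
            raise ValueError("multiplicity and charge must be >= 1")

    def mz_from_neutral(self, neutral_mass: float) -> float:
        return (self.multiplicity * neutral_mass + self.mass_shift) / self.charge

    def neutral_from_mz(self, mz: float) -> float:
        return (mz * self.charge - self.mass_shift) / self.multiplicity


#: Default rule set, in priority order.  [M+H]+, [M-H]- and [M+NH4]+ are the
#: usual quantifier ions; sodium adducts, acetate adducts (ammonium-acetate
#: mobile phase) and proton-bound/deprotonated dimers are common companions.
DEFAULT_ADDUCT_RULES: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", "positive", 1, PROTON_MASS, 1, characteristic=True),
    AdductRule("[M+NH4]+", "positive", 1, AMMONIUM_MASS, 1, characteristic=True),
    AdductRule("[M+Na]+", "positive", 1, SODIUM_ION_MASS, 1),
    AdductRule("[2M+H]+", "positive", 2, PROTON_MASS, 1),
    AdductRule("[M-H]-", "negative", 1, -PROTON_MASS, 1, characteristic=True),
    AdductRule("[M+CH3COO]-", "negative", 1, ACETATE_MASS, 1),
    AdductRule("[2M-H]-", "negative", 2, -PROTON_MASS, 1),
)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse 'C6H12O6' into element counts. Only CHNOPS are accepted."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, digits = m.group(1), m.group(2)
        if elem not in ELEMENT_MASS:
            raise ValueError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill-notation string (C first, H second, then alphabetical)."""
    parts = []
    for elem in ELEMENT_ORDER:
        n = counts.get(elem, 0)
        if n == 1:
            parts.append(elem)
        elif n > 1:
            parts.append(f"{elem}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    return sum(ELEMENT_MASS[e] * n for e, n in counts.items())


def rdbe(counts: Mapping[str, int]) -> float:
    """Ring-plus-double-bond equivalents: C + 1 + (N+P)/2 - H/2."""
    return (
        counts.get("C", 0)
        + 1
        + 0.5 * (counts.get("N", 0) + counts.get("P", 0))
        - 0.5 * counts.get("H", 0)
    )


def m1_ratio(counts: Mapping[str, int]) -> float:
    """Predicted M+1/M intensity ratio from natural isotope abundances."""
    return sum(ISOTOPE_M1_RATIO[e] * n for e, n in counts.items() if e in ISOTOPE_M1_RATIO)
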