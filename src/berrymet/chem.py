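"""Small-molecule mass arithmetic for electrospray annotation.

Monoisotopic masses, molecular-formula parsing, first-order isotopologue
(A+1)/A abundance ratios, and the default positive/negative-mode adduct
tables used to infer neutral masses from observed m/z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# IUPAC 2021 monoisotopic masses of the most abundant isotope (Da).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.968852682,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.000549
# 13C - 12C spacing; the dominant contributor to the A+1 isotopologue.
C13_SPACING = 1.003355

# Natural (A+1)/A abundance contribution per atom, first order.
_A1_CONTRIBUTION = {"C": 0.0107, "H": 0.000115, "N": 0.00364, "O": 0.00038}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for element symbols outside the supported CHNOPS+Na/K/Cl set."""


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula string into element counts.

    Accepts an already-parsed dict unchanged. Empty string -> empty dict.
    """
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        s = formula.strip()
        while pos < len(s):
            m = _FORMULA_TOKEN.match(s, pos)
            if m is None or m.group(0) == "":
                raise FormulaError(f"cannot parse formula at {s[pos:]!r}")
            elem, count = m.group(1), int(m.group(2) or 1)
            counts[elem] = counts.get(elem, 0) + count
            pos = m.end()
    for elem in counts:
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {elem!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses).

    >>> round(monoisotopic_mass("C15H10O7"), 4)   # morin
    302.0427
    """
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())


def expected_a1_ratio(formula: str | dict[str, int]) -> float:
    """Expected (A+1)/A isotopologue intensity ratio, first-order.

    ratio = nC*0.0107 + nH*0.000115 + nN*0.00364 + nO*0.00038.
    Used to validate a proposed molecular formula against the observed
    intensity of the +1.0034 Da co-eluting isotope peak.
    """
    counts = parse_formula(formula)
    return sum(_A1_CONTRIBUTION.get(e, 0.0) * n for e, n in counts.items())


@dataclass(frozen=True)
class Adduct:
    """One electrospray ion species: m/z = (n_mer * M + shift) / |z|."""

    label: str
    polarity: str  # "positive" | "negative"
    shift: float  # Da, signed
    n_mer: int = 1

    def mz(self, neutral_mass: float) -> float:
        return self.n_mer * neutral_mass + self.shift

    def neutral_mass(self, mz: float) -> float:
        return (mz - self.shift) / self.n_mer


# Standard singly-charged small-molecule ESI species. The intrinsic-cation
# entry covers flavylium ions (anthocyanins), detected as M+ with only the
# electron mass removed.
DEFAULT_ADDUCTS: tuple[Adduct, ...] = (
    Adduct("[M+H]+", "positive", +PROTON_MASS),
    Adduct("[M+Na]+", "positive", +22.989218),
    Adduct("[M+K]+", "positive", +38.963158),
    Adduct("[M+NH4]+", "positive", +18.033823),
    Adduct("[2M+H]+", "positive", +PROTON_MASS, n_mer=2),
    Adduct("[M]+", "positive", -ELECTRON_MASS),
    Adduct("[M-H]-", "negative", -PROTON_MASS),
    Adduct("[M+Cl]-", "negative", +34.969402),
    Adduct("[M+HCOO]-", "negative", +44.998201),
    Adduct("[2M-H]-", "negative", -PROTON_MASS, n_mer=2),
)


def adducts_for(polarity: str, table: tuple[Adduct, ...] = DEFAULT_ADDUCTS) -> list[Adduct]:
    return [a for a in table if a.polarity == polarity]


def default_adduct(polarity: str) -> Adduct:
    """Protonation/deprotonation species assumed for unpaired base ions."""
    label = "[M+H]+" if polarity == "positive" else "[M-H]-"
    return next(a for a in DEFAULT_ADDUCTS if a.label == label)


def ppm_error(observed: float, reference: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed - reference) / reference * 1e6
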