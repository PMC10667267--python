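"""Monoisotopic masses and adduct m/z for HR-ESI-MS "calcd" values.

Natural-product structure assignments quote a theoretical ("calcd") m/z for
the observed ion, computed from the molecular formula and the adduct species.
This module parses Hill-style elemental formulas, sums monoisotopic atomic
masses, and applies adduct deltas for the negative-mode ions commonly seen in
phytochemical work: the deprotonated molecule [M-H]- and the formate adduct
after in-source water loss, written here as "[M+HCOO]-[H2O]".

By the prevailing reporting convention the electron mass is neglected, i.e.
the ion mass is the plain atom-sum after the adduct delta; pass
``electron_correction=True`` to subtract/add electron masses per charge
(a shift of ~0.00055 Da per charge).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "ElementalFormula",
    "AdductSpec",
    "FormulaError",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ADDUCT_REGISTRY",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
]

# Monoisotopic masses of the lightest stable isotope, Da (CODATA/IUPAC).
# Hard-coded so results cannot drift with library versions.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 0.000548579909  # Da


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition: element symbol -> positive atom count."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element {el!r}: no monoisotopic mass available")
            if not isinstance(n, int) or n <= 0:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def apply_delta(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Add/remove atoms; negative resulting counts are an error."""
        counts = dict(self.element_counts)
        for el, d in delta.items():
            new = counts.get(el, 0) + d
            if new < 0:
                raise FormulaError(
                    f"delta removes {-d} {el} atoms but formula has only {counts.get(el, 0)}"
                )
            if new == 0:
                counts.pop(el, None)
            else:
                counts[el] = new
        return ElementalFormula(counts)

    def hill_string(self) -> str:
        """Serialize in Hill order: C, H, then remaining elements alphabetically."""
        counts = self.element_counts
        order = [el for el in ("C", "H") if el in counts]
        order += sorted(el for el in counts if el not in ("C", "H"))
        return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.hill_string()


@dataclass(frozen=True)
class AdductSpec:
    """An ion species relative to the neutral molecule M.

    ``formula_delta`` is the net atom change (e.g. {H: -1} for [M-H]-),
    ``charge`` the signed ion charge.
    """

    name: str
    formula_delta: Mapping[str, int] = field(default_factory=dict)
    charge: int = -1

    def __post_init__(self) -> None:
        if self.charge == 0 and self.formula_delta:
            raise ValueError(f"adduct {self.name!r}: ionic adducts must have charge != 0")
        object.__setattr__(self, "formula_delta", dict(self.formula_delta))


# Negative-mode adducts used in the HR-ESI-MS assignments. The composite
# "[M+HCOO]-[H2O]" (formate adduct that has lost water) is one species with
# the net delta +CHO2 - H2O = {C:+1, H:-1, O:+1}.
ADDUCT_REGISTRY: Dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
    "[M+HCOO]-": AdductSpec("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1),
    "[M+HCOO]-[H2O]": AdductSpec("[M+HCOO]-[H2O]", {"C": 1, "H": -1, "O": 1}, -1),
    "[M+Cl]-": AdductSpec("[M+Cl]-", {"Cl": 1}, -1),
    "[M-H2O-H]-": AdductSpec("[M-H2O-H]-", {"H": -3, "O": -1}, -1),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C24H20O7"``.

    Repeated element symbols accumulate. Raises :class:`FormulaError` for
    unknown elements (naming the symbol) or malformed input (with position).
    """
    text = text.strip()
    if not text:
        raise FormulaError("empty formula string")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of monoisotopic atomic masses over the formula, in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.element_counts.items())


def adduct_mz(
    f: ElementalFormula,
    adduct: AdductSpec | str,
    electron_correction: bool = False,
) -> float:
    """Theoretical m/z of the adduct ion of ``f``.

    ``adduct`` may be an :class:`AdductSpec` or a registry name. m/z is the
    monoisotopic mass after the adduct's atom delta, divided by |charge|.
    With ``electron_correction`` the electron mass is added per negative
    charge and subtracted per positive charge.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCT_REGISTRY[adduct]
        except KeyError:
            known = ", ".join(sorted(ADDUCT_REGISTRY))
            raise KeyError(f"unknown adduct {adduct!r}; registered: {known}") from None
    if adduct.charge == 0:
        raise ValueError(f"adduct {adduct.name!r} has zero charge; m/z undefined")
    mass = monoisotopic_mass(f.apply_delta(adduct.formula_delta))
    if electron_correction:
        mass -= adduct.charge * ELECTRON_MASS
    return mass / abs(adduct.charge)


def calcd(f: ElementalFormula | str, adduct: AdductSpec | str, **kw) -> float:
    """The 4-decimal "calcd" presentation of :func:`adduct_mz` (round-half-even)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return round(adduct_mz(f, adduct, **kw), 4)
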