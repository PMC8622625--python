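"""Elemental molecular formula (EMF) utilities.

Formulas are element->count mappings rendered in Hill notation (C first,
H second, remaining elements alphabetical).  An isotope-resolved molecular
formula (IMF) is identified here by an EMF plus an isotopologue index k,
whose m/z is shifted by k times the 13C-12C mass difference.  All adducts
are singly charged positive-mode species.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

#: 13C - 12C mass difference (Da), the per-isotopologue m/z step.
C13_C12 = 1.0033548378

_ELECTRON = 0.00054857990946

#: Ion mass added to the neutral monoisotopic mass for each positive adduct.
ADDUCT_MASS = {
    "H": 1.00782503207 - _ELECTRON,
    "Na": 22.9897692809 - _ELECTRON,
    "K": 38.96370668 - _ELECTRON,
    "NH4": 14.0030740048 + 4 * 1.00782503207 - _ELECTRON,
}

#: Element caps used when enumerating candidate formulas.
ELEMENT_CAPS = {"C": 130, "N": 7, "O": 28, "P": 3, "H": 230}

#: Upper m/z limit for any assigned formula.
MZ_LIMIT = 1605.0

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def hill_formula(counts: dict[str, int]) -> str:
    """Render element counts as a Hill-notation string."""
    items = {el: n for el, n in counts.items() if n}
    parts = []
    for el in ("C", "H"):
        if el in items:
            n = items.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(items):
        n = items[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


_MASS_CACHE: dict[str, float] = {}


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass of an EMF (Da)."""
    if isinstance(formula, str):
        cached = _MASS_CACHE.get(formula)
        if cached is not None:
            return cached
        mass = _pmass.calculate_mass(composition=_pmass.Composition(parse_formula(formula)))
        _MASS_CACHE[formula] = mass
        return mass
    return _pmass.calculate_mass(composition=_pmass.Composition(formula))


def peak_mz(emf: str | dict[str, int], imf_index: int, adduct: str) -> float:
    """m/z of the singly charged ``adduct`` ion of isotopologue ``imf_index``."""
    if adduct not in ADDUCT_MASS:
        raise ValueError(f"unknown adduct {adduct!r}")
    if imf_index < 0:
        raise ValueError("isotopologue index must be >= 0")
    return monoisotopic_mass(emf) + imf_index * C13_C12 + ADDUCT_MASS[adduct]


def within_caps(counts: dict[str, int]) -> bool:
    """True if every element count is within the enumeration caps."""
    return all(el in ELEMENT_CAPS and 0 <= n <= ELEMENT_CAPS[el] for el, n in counts.items())
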