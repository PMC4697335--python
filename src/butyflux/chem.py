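"""Molecular formulas and metabolites over the element set {C, H, O, N}.

The fermentation equations of the lysine/fructoselysine pathways are written
over free acids, so carbon skeletons of CoA thioesters and phosphorylated
intermediates are represented without the cofactor moiety (no P or S).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormulaError

#: Elements supported in formulas and balances. The proposed fermentation
#: equations involve no other elements.
ELEMENTS: tuple[str, ...] = ("C", "H", "O", "N")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string such as ``"C6H14O2N2"``.

    Returns a dict with an integer count for every element in
    :data:`ELEMENTS`; absent elements map to 0. Repeated element symbols
    accumulate.

    Raises
    ------
    FormulaError
        If the string is empty, contains an unsupported element, or has
        characters that do not form ``symbol[count]`` tokens.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty or non-string formula")
    s = formula.strip()
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {formula!r} at {s[pos:]!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in counts:
            raise FormulaError(f"unsupported element {symbol!r} in {formula!r}")
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(f"non-positive count for {symbol!r} in {formula!r}")
        counts[symbol] += n
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render an element->count map back to a Hill-ish formula string."""
    parts = []
    for el in ELEMENTS:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


@dataclass(frozen=True)
class Metabolite:
    """A named chemical species with a {C,H,O,N} formula.

    ``n_carbons`` is derived from the formula and is the length of the
    positional-isotopomer pattern for this species.
    """

    name: str
    formula: dict[str, int] = field(compare=False)

    def __post_init__(self):
        if not self.name:
            raise ValueError("metabolite name must be non-empty")
        clean = dict.fromkeys(ELEMENTS, 0)
        for el, n in self.formula.items():
            if el not in clean:
                raise FormulaError(f"unsupported element {el!r} in metabolite {self.name!r}")
            if int(n) < 0:
                raise FormulaError(f"negative count for {el!r} in metabolite {self.name!r}")
            clean[el] = int(n)
        object.__setattr__(self, "formula", clean)

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "Metabolite":
        return cls(name=name, formula=parse_formula(formula))

    @property
    def n_carbons(self) -> int:
        return self.formula["C"]

    def count(self, element: str) -> int:
        return self.formula.get(element, 0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({format_formula(self.formula)})"
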