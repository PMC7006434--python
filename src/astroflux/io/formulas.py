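"""Parsing and printing of reaction formula strings.

The dialect is the one used by reaction tables such as
``"1 cys_L[e] + 1 glu_L[c] + 1 gly[c] → 1 gthrd[e]"``: coefficients default
to 1, the left side is consumed (negative), the right side produced
(positive).  Unicode and ASCII arrows are both accepted; output is always
ASCII (``->`` / ``<=>``).  One-sided formulas (``"Tibolone[e] ↔"``) denote
single-metabolite exchange stoichiometries.
"""

from __future__ import annotations

import re

from ..errors import FormulaParseError

__all__ = ["parse_reaction_formula", "format_reaction_formula"]

# Longest-match first so "<->" is not split by "->".
_REVERSIBLE_ARROWS = ("<==>", "<=>", "<->", "↔", "⇌")
_IRREVERSIBLE_ARROWS = ("-->", "->", "→", "=>")

_COEF = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _find_arrow(text: str) -> tuple[int, int, bool]:
    for arrow in _REVERSIBLE_ARROWS + _IRREVERSIBLE_ARROWS:
        idx = text.find(arrow)
        if idx >= 0:
            return idx, idx + len(arrow), arrow in _REVERSIBLE_ARROWS
    raise FormulaParseError(f"no reaction arrow found in {text!r}")


def parse_reaction_formula(text: str) -> tuple[dict[str, float], bool]:
    """Parse a formula string into ``(stoichiometry, reversible)``.

    Raises :class:`FormulaParseError` (with a character position where
    possible) for malformed terms, duplicated metabolites on one side, zero
    coefficients, or net-zero stoichiometry.
    """
    if not text or not text.strip():
        raise FormulaParseError("empty reaction formula")
    a0, a1, reversible = _find_arrow(text)
    stoich: dict[str, float] = {}
    _parse_side(text, 0, a0, sign=-1.0, stoich=stoich)
    _parse_side(text, a1, len(text), sign=+1.0, stoich=stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0.0} if stoich else stoich
    if not stoich:
        raise FormulaParseError(f"net-zero stoichiometry in {text!r}")
    return stoich, reversible


def _parse_side(text: str, start: int, end: int, sign: float, stoich: dict[str, float]) -> None:
    segment = text[start:end]
    if not segment.strip():
        return
    seen: set[str] = set()
    offset = start
    for term in segment.split("+"):
        pos = offset + (len(term) - len(term.lstrip()))
        offset += len(term) + 1
        tokens = term.split()
        if not tokens:
            raise FormulaParseError("empty term in reaction formula", position=pos)
        if len(tokens) == 1:
            coef, met_id = 1.0, tokens[0]
        elif len(tokens) == 2 and _COEF.match(tokens[0]):
            coef, met_id = float(tokens[0]), tokens[1]
        else:
            raise FormulaParseError(f"malformed term {term.strip()!r}", position=pos)
        if coef == 0.0:
            raise FormulaParseError(f"zero coefficient for {met_id!r}", position=pos)
        if coef < 0.0:
            raise FormulaParseError(f"negative coefficient for {met_id!r}", position=pos)
        if met_id in seen:
            raise FormulaParseError(f"duplicate metabolite {met_id!r} on one side", position=pos)
        seen.add(met_id)
        stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef
    # A metabolite appearing on both sides with equal coefficients nets to
    # zero, which silently deletes it: reject.
    for met_id in seen:
        if met_id in stoich and stoich[met_id] == 0.0:
            raise FormulaParseError(f"net-zero stoichiometry for {met_id!r} in {text!r}")


def _fmt_coef(value: float) -> str:
    return f"{value:g}"


def format_reaction_formula(stoichiometry: dict[str, float], reversible: bool) -> str:
    """Render a stoichiometry map back to an ASCII formula string.

    Metabolites are sorted alphabetically within each side, and every
    coefficient is printed explicitly, so ``parse ∘ format`` is the identity
    on (stoichiometry, reversible) pairs.
    """
    if not stoichiometry:
        raise FormulaParseError("cannot format empty stoichiometry")
    left = sorted((m, -c) for m, c in stoichiometry.items() if c < 0)
    right = sorted((m, c) for m, c in stoichiometry.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    lhs = " + ".join(f"{_fmt_coef(c)} {m}" for m, c in left)
    rhs = " + ".join(f"{_fmt_coef(c)} {m}" for m, c in right)
    if lhs and rhs:
        return f"{lhs} {arrow} {rhs}"
    if lhs:
        return f"{lhs} {arrow}"
    return f"{arrow} {rhs}"
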