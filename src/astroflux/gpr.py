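"""Gene-protein-reaction (GPR) boolean trees.

A GPR is a boolean expression over gene identifiers: internal nodes are
AND/OR, leaves are genes.  An empty GPR means "no gene association" and is
distinct from a GPR that evaluates to zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import FormulaParseError

__all__ = ["GPR", "parse_gpr"]


@dataclass(frozen=True)
class GPR:
    """Immutable GPR tree node.

    ``kind`` is one of ``"empty"``, ``"leaf"``, ``"and"``, ``"or"``.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPR", ...] = field(default_factory=tuple)

    # -- constructors -------------------------------------------------
    @staticmethod
    def empty() -> "GPR":
        return GPR("empty")

    @staticmethod
    def leaf(gene: str) -> "GPR":
        if not gene:
            raise ValueError("GPR leaf requires a nonempty gene identifier")
        return GPR("leaf", gene=gene)

    @staticmethod
    def and_(*children: "GPR") -> "GPR":
        return _nary("and", children)

    @staticmethod
    def or_(*children: "GPR") -> "GPR":
        return _nary("or", children)

    # -- queries ------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> set[str]:
        if self.kind == "empty":
            return set()
        if self.kind == "leaf":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        if self.kind == "empty":
            return ""
        if self.kind == "leaf":
            return self.gene  # type: ignore[return-value]
        op = f" {self.kind} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.kind in ("and", "or") and c.kind != self.kind:
                s = f"({s})"
            elif c.kind in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return op.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _nary(kind: str, children) -> GPR:
    kids = tuple(c for c in children if not c.is_empty)
    if not kids:
        return GPR.empty()
    if len(kids) == 1:
        return kids[0]
    return GPR(kind, children=kids)


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def parse_gpr(text: str) -> GPR:
    """Parse strings like ``"(A and B) or C"`` into a :class:`GPR` tree.

    ``and``/``or`` are case-insensitive keywords; anything else is a gene.
    An empty or whitespace-only string yields the empty GPR.
    """
    if text is None or not text.strip():
        return GPR.empty()
    tokens = _tokenize(text)
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise FormulaParseError(f"trailing tokens in GPR: {tokens[pos:]!r}")
    return node


def _tokenize(text: str) -> list[str]:
    tokens, i = [], 0
    while i < len(text):
        m = _TOKEN.match(text, i)
        if m is None:
            break
        tokens.append(m.group(1))
        i = m.end()
    return tokens


def _parse_or(tokens: list[str], pos: int) -> tuple[GPR, int]:
    node, pos = _parse_and(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    return (GPR.or_(*children) if len(children) > 1 else node), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[GPR, int]:
    node, pos = _parse_atom(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    return (GPR.and_(*children) if len(children) > 1 else node), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GPR, int]:
    if pos >= len(tokens):
        raise FormulaParseError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise FormulaParseError("unbalanced parenthesis in GPR")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise FormulaParseError(f"unexpected token {tok!r} in GPR")
    return GPR.leaf(tok), pos + 1
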