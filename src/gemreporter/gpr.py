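"""Gene–reaction (GPR) rule parsing and evaluation.

Rules are boolean expressions over gene identifiers with ``and`` / ``or``
(case-insensitive) and parentheses, the convention used by the HMR family of
human metabolic reconstructions.  ``or`` joins isozymes, ``and`` joins
subunits of a complex.  An empty rule means the reaction is spontaneous or
has no known enzyme.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable

__all__ = ["GprParseError", "parse_gpr", "gpr_genes", "evaluate_gpr"]

# node = gene-id string, or ("and"|"or", [nodes])
GprNode = object

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_IDENT_RE = re.compile(r"^[A-Za-z0-9_.:\-@]+$")


class GprParseError(ValueError):
    """Raised when a gene rule cannot be parsed."""


def _tokenize(rule: str) -> list[str]:
    tokens = _TOKEN_RE.findall(rule)
    out = []
    for t in tokens:
        low = t.lower()
        if low in ("and", "or"):
            out.append(low)
        elif t in ("(", ")"):
            out.append(t)
        elif _IDENT_RE.match(t):
            out.append(t)
        else:
            raise GprParseError(f"bad token {t!r} in gene rule {rule!r}")
    return out


def parse_gpr(rule: str) -> GprNode | None:
    """Parse a rule into a tree; ``None`` for an empty rule.

    Grammar (``or`` binds loosest)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := IDENT | "(" expr ")"
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def factor() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of gene rule {rule!r}")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok in ("and", "or", ")"):
            raise GprParseError(f"unexpected {tok!r} in gene rule {rule!r}")
        return take()

    def term() -> GprNode:
        parts = [factor()]
        while peek() == "and":
            take()
            parts.append(factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def expr() -> GprNode:
        parts = [term()]
        while peek() == "or":
            take()
            parts.append(term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    node = expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in gene rule {rule!r}")
    return node


def gpr_genes(rule: str) -> set[str]:
    """Flattened set of gene ids in a rule, ignoring AND/OR structure."""
    node = parse_gpr(rule)
    out: set[str] = set()

    def walk(n: GprNode) -> None:
        if isinstance(n, str):
            out.add(n)
        elif n is not None:
            for child in n[1]:
                walk(child)

    walk(node)
    return out


def evaluate_gpr(rule: str, score: Callable[[str], float],
                 empty_value: float = 0.0) -> float:
    """Evaluate a rule over per-gene scores: OR -> max, AND -> min.

    The max/min semantics treat OR'd isozymes as redundant (best evidence
    wins) and AND'd complex subunits as limited by their weakest member.
    """
    node = parse_gpr(rule)
    if node is None:
        return empty_value

    def walk(n: GprNode) -> float:
        if isinstance(n, str):
            return score(n)
        op, children = n
        vals = [walk(c) for c in children]
        return max(vals) if op == "or" else min(vals)

    return walk(node)
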