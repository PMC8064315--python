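"""Gene-protein-reaction (GPR) rules: parsing and quantitative evaluation.

A GPR rule is a Boolean expression over gene symbols in which ``and``
joins subunits of an enzyme complex and ``or`` joins isozymes (or
alternative complex configurations).  For expression integration the
Boolean rule is read quantitatively: isozymes contribute additively to a
reaction's capacity, while a complex is only as abundant as its scarcest
subunit.  Hence the reaction activity score (RAS) of a rule is computed
recursively with ``or`` -> sum and ``and`` -> min over per-gene
expression values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence, Union


class GPRParseError(ValueError):
    """Raised when a GPR rule string is malformed."""


@dataclass(frozen=True)
class GeneLeaf:
    """A single gene symbol."""

    gene: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise GPRParseError("gene symbol must be non-empty")


@dataclass(frozen=True)
class AndNode:
    """Subunits of a complex: quantitatively the minimum of the children."""

    children: tuple["GPRNode", ...]


@dataclass(frozen=True)
class OrNode:
    """Isozymes: quantitatively the sum of the children."""

    children: tuple["GPRNode", ...]


@dataclass(frozen=True)
class EmptyGPR:
    """No gene association (exchange, spontaneous or pseudo reactions)."""


GPRNode = Union[GeneLeaf, AndNode, OrNode]
GPRExpression = Union[GPRNode, EmptyGPR]

EMPTY_GPR = EmptyGPR()

# One token per match: parenthesis, keyword synonym, or a gene symbol.
_TOKEN_RE = re.compile(r"\(|\)|&&|\|\||[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    tokens = []
    for tok in _TOKEN_RE.findall(rule):
        low = tok.lower()
        if low in ("and", "&", "&&"):
            tokens.append("and")
        elif low in ("or", "|", "||"):
            tokens.append("or")
        else:
            tokens.append(tok)
    return tokens


def parse_gpr(rule: str) -> GPRExpression:
    """Parse a GPR rule string into an expression tree.

    Grammar (case-insensitive keywords; ``&&``/``||`` accepted as
    synonyms):  ``or_expr := and_expr ('or' and_expr)*``,
    ``and_expr := atom ('and' atom)*``, ``atom := gene | '(' or_expr ')'``.
    Parentheses bind tightest, then ``and``, then ``or``.  An empty or
    all-whitespace string denotes no gene association.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or dangling operators.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return EMPTY_GPR
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        children = [parse_and()]
        while peek() == "or":
            take()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return OrNode(tuple(children))

    def parse_and() -> GPRNode:
        children = [parse_atom()]
        while peek() == "and":
            take()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return AndNode(tuple(children))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"dangling operator in GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in GPR rule {rule!r}")
            take()
            return node
        if tok in (")", "and", "or"):
            raise GPRParseError(f"unexpected {tok!r} in GPR rule {rule!r}")
        return GeneLeaf(take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def gpr_genes(expr: GPRExpression) -> set[str]:
    """All gene symbols appearing in the expression."""
    return set(_iter_genes(expr))


def _iter_genes(expr: GPRExpression) -> Iterator[str]:
    if isinstance(expr, GeneLeaf):
        yield expr.gene
    elif isinstance(expr, (AndNode, OrNode)):
        for child in expr.children:
            yield from _iter_genes(child)


def evaluate_gpr(expr: GPRExpression, values: Mapping[str, float]) -> float:
    """Quantitative GPR evaluation: leaf -> expression value, or -> sum,
    and -> min.

    Raises
    ------
    KeyError
        If a gene symbol is missing from ``values``.
    ValueError
        If ``expr`` is empty (an empty rule has no activity score).
    """
    if isinstance(expr, EmptyGPR):
        raise ValueError("cannot evaluate an empty GPR expression")
    if isinstance(expr, GeneLeaf):
        return float(values[expr.gene])
    if isinstance(expr, OrNode):
        return sum(evaluate_gpr(c, values) for c in expr.children)
    if isinstance(expr, AndNode):
        return min(evaluate_gpr(c, values) for c in expr.children)
    raise TypeError(f"not a GPR expression: {expr!r}")


def format_gpr(expr: GPRExpression) -> str:
    """Render an expression tree back to a normalized rule string."""
    if isinstance(expr, EmptyGPR):
        return ""
    if isinstance(expr, GeneLeaf):
        return expr.gene
    if isinstance(expr, AndNode):
        parts = [
            f"({format_gpr(c)})" if isinstance(c, OrNode) else format_gpr(c)
            for c in expr.children
        ]
        return " and ".join(parts)
    if isinstance(expr, OrNode):
        return " or ".join(format_gpr(c) for c in expr.children)
    raise TypeError(f"not a GPR expression: {expr!r}")
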