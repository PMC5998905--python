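"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers with ``and``/``or``
and parentheses, e.g. ``"(g1 and g2) or g3"``.  Isozymes are joined by
``or``, enzyme complexes by ``and``.  For expression integration the
expression is evaluated over trilean gene states (-1 low, 0 moderate,
+1 high) with the usual convention AND = min, OR = max: a complex is only
as expressed as its least-expressed subunit, while one highly expressed
isozyme suffices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "GprError",
    "GprExpression",
    "Gene",
    "BoolOp",
    "EMPTY_GPR",
    "parse_gpr",
    "evaluate_gpr",
]


class GprError(ValueError):
    """Raised for malformed GPR text."""


class GprExpression:
    """Base class for nodes of a parsed GPR tree."""

    def evaluate(self, gene_states: Mapping[str, int]) -> int:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_text(self) -> str:
        raise NotImplementedError

    @property
    def is_empty(self) -> bool:
        return False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


@dataclass(frozen=True)
class Gene(GprExpression):
    """Leaf node: a single gene id.

    Genes missing from the state map evaluate to 0 (moderate): absence of
    expression evidence never asserts activity or inactivity.
    """

    name: str

    def evaluate(self, gene_states: Mapping[str, int]) -> int:
        return int(gene_states.get(self.name, 0))

    def genes(self) -> frozenset[str]:
        return frozenset((self.name,))

    def to_text(self) -> str:
        return self.name


@dataclass(frozen=True)
class BoolOp(GprExpression):
    """Internal node: ``and`` (min) or ``or`` (max) over two or more operands."""

    op: str  # "and" | "or"
    operands: tuple[GprExpression, ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise GprError(f"unknown operator {self.op!r}")
        if len(self.operands) < 2:
            raise GprError("BoolOp needs at least two operands")

    def evaluate(self, gene_states: Mapping[str, int]) -> int:
        values = [child.evaluate(gene_states) for child in self.operands]
        return min(values) if self.op == "and" else max(values)

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for child in self.operands:
            out |= child.genes()
        return out

    def to_text(self) -> str:
        parts = []
        for child in self.operands:
            text = child.to_text()
            # OR binds looser than AND: parenthesize an OR child inside an AND
            if self.op == "and" and isinstance(child, BoolOp) and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


class _Empty(GprExpression):
    """The empty rule: no gene evidence, always moderate (0)."""

    def evaluate(self, gene_states: Mapping[str, int]) -> int:
        return 0

    def genes(self) -> frozenset[str]:
        return frozenset()

    def to_text(self) -> str:
        return ""

    @property
    def is_empty(self) -> bool:
        return True

    def __repr__(self) -> str:
        return "EMPTY_GPR"


EMPTY_GPR = _Empty()

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> Iterator[str]:
    return iter(_TOKEN_RE.findall(text))


class _Parser:
    """Recursive-descent parser; precedence AND > OR."""

    def __init__(self, text: str) -> None:
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.parse_or()
        if self.peek() is not None:
            raise GprError(f"unexpected token {self.peek()!r} in GPR")
        return expr

    def parse_or(self) -> GprExpression:
        operands = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            operands.append(self.parse_and())
        if len(operands) == 1:
            return operands[0]
        return BoolOp("or", tuple(operands))

    def parse_and(self) -> GprExpression:
        operands = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            operands.append(self.parse_atom())
        if len(operands) == 1:
            return operands[0]
        return BoolOp("and", tuple(operands))

    def parse_atom(self) -> GprExpression:
        tok = self.next()
        if tok == "(":
            expr = self.parse_or()
            if self.peek() != ")":
                raise GprError("unbalanced parentheses in GPR")
            self.next()
            return expr
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"dangling operator or parenthesis near {tok!r}")
        return Gene(tok)


def parse_gpr(text: str | None) -> GprExpression:
    """Parse GPR text into an expression tree.

    Empty or whitespace-only text yields :data:`EMPTY_GPR`.  The grammar
    accepts gene ids (any run of non-space, non-parenthesis characters that
    is not ``and``/``or``), the case-insensitive operators, and parentheses.
    """
    if text is None or not text.strip():
        return EMPTY_GPR
    return _Parser(text).parse()


def evaluate_gpr(expr: GprExpression, gene_states: Mapping[str, int]) -> int:
    """Evaluate a GPR over trilean gene states; total (missing genes -> 0)."""
    return expr.evaluate(gene_states)
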