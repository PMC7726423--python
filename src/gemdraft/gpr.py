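"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule states which gene products enable a reaction: AND joins
subunits of a complex, OR joins isoenzymes.  Rules are modelled as a
rooted tree whose internal nodes are ``and``/``or`` operators with at
least two children and whose leaves are gene identifiers.  The empty
expression (``GprExpression.empty()``) is the distinguished "no gene
association" value carried by spontaneous, transport and exchange
reactions.

The grammar accepted by :func:`parse_gpr` is the one used by COBRA-style
model files: case-insensitive ``and``/``or`` keywords, parentheses, and
gene identifiers that are maximal runs of non-whitespace,
non-parenthesis characters.  ``and`` binds tighter than ``or``.  There
is no negation, which does not occur in GEM practice.

Expressions are always kept in normal form: nested nodes of the same
operator are flattened and single-child nodes are collapsed, so
``(g1 or g2) or g3`` and ``g1 or (g2 or g3)`` parse to the same tree.
Serialization orders children lexicographically, making the string form
canonical and diff-friendly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "GprExpression",
    "GprParseError",
    "parse_gpr",
    "serialize_gpr",
    "gpr_genes",
]


class GprParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed.

    Carries the character ``position`` at which parsing failed.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprExpression:
    """A normalized Boolean AND/OR tree over gene identifiers.

    ``op`` is ``"gene"`` for a leaf (``children`` holds the id),
    ``"and"``/``"or"`` for internal nodes, or ``"empty"`` for the
    distinguished no-association value.  Instances are immutable and
    hashable; construct them through :meth:`gene`, :meth:`and_`,
    :meth:`or_` or :func:`parse_gpr`, which normalize on the way in.
    """

    op: str
    children: tuple = field(default=())

    # -- constructors -------------------------------------------------

    @classmethod
    def empty(cls) -> "GprExpression":
        return cls("empty")

    @classmethod
    def gene(cls, gene_id: str) -> "GprExpression":
        if not gene_id:
            raise ValueError("gene id must be non-empty")
        return cls("gene", (gene_id,))

    @classmethod
    def and_(cls, *children: "GprExpression") -> "GprExpression":
        return _make_node("and", children)

    @classmethod
    def or_(cls, *children: "GprExpression") -> "GprExpression":
        return _make_node("or", children)

    # -- queries ------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    @property
    def gene_id(self) -> str:
        if self.op != "gene":
            raise ValueError("not a leaf node")
        return self.children[0]

    def genes(self) -> set[str]:
        """Set of gene ids appearing as leaves (empty set for empty)."""
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.op == "gene":
            yield self.children[0]
        elif self.op in ("and", "or"):
            for child in self.children:
                yield from child._iter_genes()

    def evaluate(self, present: set[str]) -> bool:
        """Truth value of the rule given the set of present genes.

        The empty expression evaluates to False (no gene evidence).
        """
        if self.op == "empty":
            return False
        if self.op == "gene":
            return self.children[0] in present
        results = (c.evaluate(present) for c in self.children)
        return all(results) if self.op == "and" else any(results)

    def __str__(self) -> str:
        return serialize_gpr(self)


def _make_node(op: str, children) -> GprExpression:
    """Build an AND/OR node, flattening same-op children and collapsing
    trivial cases; empty children are dropped."""
    flat: list[GprExpression] = []
    for child in children:
        if not isinstance(child, GprExpression):
            raise TypeError(f"child is not a GprExpression: {child!r}")
        if child.is_empty:
            continue
        if child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    # idempotence: drop duplicate subtrees (g1 or g1 == g1)
    seen: set[GprExpression] = set()
    unique = [c for c in flat if not (c in seen or seen.add(c))]
    if not unique:
        return GprExpression.empty()
    if len(unique) == 1:
        return unique[0]
    # canonical child order so structurally-equal rules compare equal
    unique.sort(key=serialize_gpr)
    return GprExpression(op, tuple(unique))


# -- parsing ----------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    """Recursive-descent parser; 'and' binds tighter than 'or'."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.text))

    def advance(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        expr = self.parse_or()
        tok, at = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok!r}", at)
        return expr

    def parse_or(self) -> GprExpression:
        children = [self.parse_and()]
        while True:
            tok, _ = self.peek()
            if tok is not None and tok.lower() == "or":
                self.advance()
                children.append(self.parse_and())
            else:
                break
        return _make_node("or", children)

    def parse_and(self) -> GprExpression:
        children = [self.parse_atom()]
        while True:
            tok, _ = self.peek()
            if tok is not None and tok.lower() == "and":
                self.advance()
                children.append(self.parse_atom())
            else:
                break
        return _make_node("and", children)

    def parse_atom(self) -> GprExpression:
        tok, at = self.peek()
        if tok is None:
            raise GprParseError("dangling operator: expected gene id or '('", at)
        if tok == "(":
            self.advance()
            expr = self.parse_or()
            tok2, at2 = self.peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parentheses: expected ')'", at2)
            self.advance()
            return expr
        if tok == ")":
            raise GprParseError("unbalanced parentheses: unexpected ')'", at)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"dangling operator {tok!r}", at)
        self.advance()
        return GprExpression.gene(tok)


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string into a normalized :class:`GprExpression`.

    Empty or whitespace-only input yields the empty expression.

    Raises
    ------
    GprParseError
        On unbalanced parentheses or dangling operators, naming the
        character position of the problem.
    """
    if text is None or not text.strip():
        return GprExpression.empty()
    return _Parser(text).parse()


def serialize_gpr(expr: GprExpression) -> str:
    """Canonical string form of an expression.

    Children are emitted in lexicographic order of their own serialized
    form; compound children are parenthesized.  ``parse_gpr`` of the
    result is structurally equal to the input, and the empty expression
    serializes to ``""``.
    """
    if expr.is_empty:
        return ""
    if expr.op == "gene":
        return expr.children[0]
    parts = []
    for child in expr.children:  # children are already in canonical order
        s = serialize_gpr(child)
        if child.op in ("and", "or"):
            s = f"({s})"
        parts.append(s)
    return f" {expr.op} ".join(parts)


def gpr_genes(expr: GprExpression) -> set[str]:
    """The set of gene ids appearing in the expression."""
    return expr.genes()
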