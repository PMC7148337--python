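"""Boolean gene–protein–reaction (GPR) rule algebra.

A GPR rule is a Boolean tree over gene identifiers: AND nodes model enzyme
complexes (every subunit required), OR nodes model isozymes (any one
suffices).  An empty rule means the reaction is not gene-associated and is
always considered catalysable.

Trees are kept in a canonical form: nested nodes of the same operator are
flattened, duplicate children are collapsed (Boolean idempotence), children
are sorted deterministically, and single-child nodes reduce to that child.
Canonicalisation makes structural equality a sound test of syntactic
equivalence-up-to-commutativity and makes printed output reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

__all__ = [
    "Gpr",
    "Leaf",
    "FalseLeaf",
    "And",
    "Or",
    "EMPTY",
    "GprParseError",
    "parse_gpr",
    "gpr_to_string",
    "eval_gpr",
    "gpr_genes",
    "make_and",
    "make_or",
]


@dataclass(frozen=True)
class Leaf:
    gene: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene id must be a non-empty string")


@dataclass(frozen=True)
class FalseLeaf:
    """Placeholder for a gene with no orthologue, kept in translated trees.

    Evaluates to False.  Retaining the failed source gene (rather than
    silently deleting the leaf) keeps the orthology triage auditable; markers
    are pruned only when curation decisions are applied.
    """

    source_gene: str


@dataclass(frozen=True)
class _Node:
    children: tuple["Gpr", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND/OR nodes need at least two children")


@dataclass(frozen=True)
class And(_Node):
    pass


@dataclass(frozen=True)
class Or(_Node):
    pass


class _Empty:
    """Singleton marker for a reaction without gene association; survives
    copy/deepcopy/pickle as the same object so ``is EMPTY`` stays valid."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EMPTY"

    def __copy__(self):
        return self

    def __deepcopy__(self, memo):
        return self

    def __reduce__(self):
        return (_Empty, ())


EMPTY = _Empty()

Gpr = Union[Leaf, FalseLeaf, And, Or, _Empty]


def _sort_key(node: Gpr) -> tuple[int, str]:
    if isinstance(node, Leaf):
        return (0, node.gene)
    if isinstance(node, FalseLeaf):
        return (1, node.source_gene)
    return (2, gpr_to_string(node))


def _canonical(op: type, children: Iterable[Gpr]) -> Gpr:
    flat: list[Gpr] = []
    for child in children:
        if isinstance(child, _Empty):
            raise ValueError("EMPTY cannot be a child of AND/OR")
        if isinstance(child, op):
            flat.extend(child.children)
        else:
            flat.append(child)
    seen: set[tuple[int, str]] = set()
    unique: list[Gpr] = []
    for child in sorted(flat, key=_sort_key):
        key = _sort_key(child)
        if key not in seen:
            seen.add(key)
            unique.append(child)
    if len(unique) == 1:
        return unique[0]
    return op(tuple(unique))


def make_and(children: Iterable[Gpr]) -> Gpr:
    """Canonical AND over ``children`` (flattened, deduplicated, sorted)."""
    return _canonical(And, children)


def make_or(children: Iterable[Gpr]) -> Gpr:
    """Canonical OR over ``children`` (flattened, deduplicated, sorted)."""
    return _canonical(Or, children)


class GprParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append(("paren", c, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        if word.lower() in _KEYWORDS:
            tokens.append(("op", word.lower(), i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> Gpr:
        if not self.tokens:
            return EMPTY
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def parse_or(self) -> Gpr:
        children = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok is not None and tok[:2] == ("op", "or"):
                self.next()
                children.append(self.parse_and())
            else:
                break
        return make_or(children) if len(children) > 1 else children[0]

    def parse_and(self) -> Gpr:
        children = [self.parse_atom()]
        while True:
            tok = self.peek()
            if tok is not None and tok[:2] == ("op", "and"):
                self.next()
                children.append(self.parse_atom())
            else:
                break
        return make_and(children) if len(children) > 1 else children[0]

    def parse_atom(self) -> Gpr:
        kind, value, position = self.next()
        if kind == "gene":
            return Leaf(value)
        if (kind, value) == ("paren", "("):
            node = self.parse_or()
            tok = self.peek()
            if tok is None or tok[:2] != ("paren", ")"):
                raise GprParseError("unbalanced parenthesis", position)
            self.next()
            return node
        raise GprParseError(f"empty operand before {value!r}", position)


def parse_gpr(text: str) -> Gpr:
    """Parse an infix ``and``/``or`` GPR string into a canonical tree.

    Whitespace-insensitive; keywords are case-insensitive; ``and`` binds
    tighter than ``or``.  The empty string parses to :data:`EMPTY`.
    """
    return _Parser(text).parse()


def gpr_to_string(rule: Gpr) -> str:
    """Render a rule with minimal parentheses (inverse of :func:`parse_gpr`)."""
    if isinstance(rule, _Empty):
        return ""
    if isinstance(rule, Leaf):
        return rule.gene
    if isinstance(rule, FalseLeaf):
        return f"__false__{rule.source_gene}"
    if isinstance(rule, And):
        parts = []
        for child in rule.children:
            s = gpr_to_string(child)
            if isinstance(child, Or):
                s = f"({s})"
            parts.append(s)
        return " and ".join(parts)
    parts = [gpr_to_string(child) for child in rule.children]
    return " or ".join(parts)


def eval_gpr(rule: Gpr, present: set[str] | frozenset[str]) -> bool:
    """Evaluate a rule with the given set of present genes.

    An empty rule is True: reactions without gene association are never
    switched off by gene-level evidence.
    """
    if isinstance(rule, _Empty):
        return True
    if isinstance(rule, Leaf):
        return rule.gene in present
    if isinstance(rule, FalseLeaf):
        return False
    if isinstance(rule, And):
        return all(eval_gpr(c, present) for c in rule.children)
    if isinstance(rule, Or):
        return any(eval_gpr(c, present) for c in rule.children)
    raise TypeError(f"not a GPR node: {rule!r}")


def gpr_genes(rule: Gpr) -> frozenset[str]:
    """All gene ids appearing as (true) leaves; FALSE markers are excluded."""
    if isinstance(rule, Leaf):
        return frozenset({rule.gene})
    if isinstance(rule, (And, Or)):
        out: set[str] = set()
        for child in rule.children:
            out |= gpr_genes(child)
        return frozenset(out)
    return frozenset()
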