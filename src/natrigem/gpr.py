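"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule is a boolean expression over gene identifiers with ``and``/``or``
connectives. A reaction is available iff its rule evaluates to True given the
set of present (non-deleted) genes. ``and`` models multi-subunit complexes
(all subunits required), ``or`` models isoenzymes (any one suffices).

The string dialect is the conventional one used in SBML-FBC exports:
``and``/``or`` case-insensitive, parentheses honoured, ``and`` binding tighter
than ``or``. An empty rule means the reaction is spontaneous / orphan and is
always available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable


class GprSyntaxError(ValueError):
    """Raised when a gene-rule string cannot be parsed."""


@dataclass(frozen=True)
class _Leaf:
    gene: str

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return self.gene not in deleted

    def genes(self) -> set[str]:
        return {self.gene}

    def to_string(self) -> str:
        return self.gene

    def minimal_gene_sets(self) -> list[frozenset[str]]:
        return [frozenset([self.gene])]


@dataclass(frozen=True)
class _And:
    children: tuple

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, _Or):
                s = f"({s})"
            parts.append(s)
        return " and ".join(parts)

    def minimal_gene_sets(self) -> list[frozenset[str]]:
        sets: list[frozenset[str]] = [frozenset()]
        for c in self.children:
            sets = [s | t for s in sets for t in c.minimal_gene_sets()]
        return _minimize(sets)


@dataclass(frozen=True)
class _Or:
    children: tuple

    def evaluate(self, deleted: frozenset[str]) -> bool:
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)

    def minimal_gene_sets(self) -> list[frozenset[str]]:
        sets: list[frozenset[str]] = []
        for c in self.children:
            sets.extend(c.minimal_gene_sets())
        return _minimize(sets)


def _minimize(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    """Drop supersets so only minimal satisfying gene sets remain."""
    uniq = sorted(set(sets), key=lambda s: (len(s), sorted(s)))
    out: list[frozenset[str]] = []
    for s in uniq:
        if not any(t < s or t == s for t in out):
            out.append(s)
    return out


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GeneRule:
    """Boolean gene-association rule; ``root is None`` means 'no rule'."""

    root: object | None = field(default=None)

    @classmethod
    def empty(cls) -> "GeneRule":
        return cls(None)

    @classmethod
    def from_string(cls, text: str) -> "GeneRule":
        text = (text or "").strip()
        if not text:
            return cls.empty()
        tokens = _TOKEN.findall(text)
        node, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GprSyntaxError(f"trailing tokens in gene rule: {text!r}")
        return cls(node)

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True iff the rule is satisfied with the given genes deleted.

        An empty rule is always active (spontaneous reaction).
        """
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(deleted))

    def genes(self) -> set[str]:
        return set() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def minimal_gene_sets(self) -> list[frozenset[str]]:
        """Minimal gene sets whose joint presence satisfies the rule.

        Each set is one complete isoenzyme/complex from the OR-expansion of
        the rule; supersets of another satisfying set are pruned.
        """
        if self.root is None:
            return [frozenset()]
        return self.root.minimal_gene_sets()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _parse_or(tokens: list[str], pos: int):
    node, pos = _parse_and(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return children[0], pos
    return _Or(tuple(children)), pos


def _parse_and(tokens: list[str], pos: int):
    node, pos = _parse_atom(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return children[0], pos
    return _And(tuple(children)), pos


def _parse_atom(tokens: list[str], pos: int):
    if pos >= len(tokens):
        raise GprSyntaxError("unexpected end of gene rule")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GprSyntaxError("unbalanced parenthesis in gene rule")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprSyntaxError(f"unexpected token {tok!r} in gene rule")
    return _Leaf(tok), pos + 1
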