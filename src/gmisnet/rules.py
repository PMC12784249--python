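"""Boolean rule trees for gene-protein-reaction (GPR) logic.

A GPR rule states when a reaction's catalysing enzyme is available as a
Boolean expression over genes ("g1 and (g2 or g3)").  Extended GPR rules
additionally use negation to express transcriptional repression, so the
full node vocabulary is AND / OR / NOT / gene literal / TRUE / FALSE.

Rules are immutable, hash-consable trees.  Construction goes through the
smart constructors (:func:`and_`, :func:`or_`, :func:`not_`, :func:`lit`),
which flatten nested connectives, deduplicate children and apply the
obvious identity/absorption laws so that structurally equal expressions
compare equal.  Children of AND/OR are kept in a canonical sorted order,
which makes serialisation (and everything built on top of rule hashing)
deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "BooleanRule",
    "GprParseError",
    "TRUE",
    "FALSE",
    "lit",
    "not_",
    "and_",
    "or_",
    "parse_gpr",
]


class GprParseError(ValueError):
    """Raised for malformed GPR rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class BooleanRule:
    """One node of a Boolean expression DAG.

    ``op`` is one of ``"and" | "or" | "not" | "lit" | "true" | "false"``.
    Literal nodes carry the gene symbol in ``gene``; NOT nodes have exactly
    one child; TRUE/FALSE are leaves.
    """

    op: str
    children: tuple["BooleanRule", ...] = ()
    gene: str | None = None
    _key: str = field(init=False, repr=False, compare=False, default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "_key", self._serialize())

    # -- introspection -------------------------------------------------
    def genes(self) -> frozenset[str]:
        """All gene symbols appearing in the rule."""
        if self.op == "lit":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def is_true(self) -> bool:
        return self.op == "true"

    def is_false(self) -> bool:
        return self.op == "false"

    def is_negation_free(self) -> bool:
        if self.op == "not":
            return False
        return all(c.is_negation_free() for c in self.children)

    def walk(self) -> Iterator["BooleanRule"]:
        yield self
        for c in self.children:
            yield from c.walk()

    # -- algebra -------------------------------------------------------
    def nnf(self) -> "BooleanRule":
        """Negation normal form: NOT pushed onto literals by De Morgan."""
        return _nnf(self, negate=False)

    def negate(self) -> "BooleanRule":
        """De Morgan complement of the rule, in negation normal form."""
        return _nnf(self, negate=True)

    def substitute(self, mapping: dict[str, "BooleanRule"]) -> "BooleanRule":
        """Replace literals by rules (NOT g maps to the negated replacement)."""
        if self.op == "lit":
            return mapping.get(self.gene, self)  # type: ignore[arg-type]
        if self.op == "not":
            return not_(self.children[0].substitute(mapping))
        if self.op == "and":
            return and_(c.substitute(mapping) for c in self.children)
        if self.op == "or":
            return or_(c.substitute(mapping) for c in self.children)
        return self

    def evaluate(self, state: dict[str, bool]) -> bool:
        """Evaluate under a total truth assignment of the genes."""
        if self.op == "true":
            return True
        if self.op == "false":
            return False
        if self.op == "lit":
            return state[self.gene]  # type: ignore[index]
        if self.op == "not":
            return not self.children[0].evaluate(state)
        if self.op == "and":
            return all(c.evaluate(state) for c in self.children)
        return any(c.evaluate(state) for c in self.children)

    # -- serialisation -------------------------------------------------
    def _serialize(self) -> str:
        if self.op == "true":
            return "TRUE"
        if self.op == "false":
            return "FALSE"
        if self.op == "lit":
            return self.gene  # type: ignore[return-value]
        if self.op == "not":
            inner = self.children[0]
            s = inner._key if inner._key else inner._serialize()
            if inner.op in ("and", "or"):
                return f"not ({s})"
            return f"not {s}"
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c._key if c._key else c._serialize()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            elif c.op == self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def to_string(self) -> str:
        """Render back to GPR-style text; ``parse_gpr`` round-trips it."""
        return self._key

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self._key


TRUE = BooleanRule("true")
FALSE = BooleanRule("false")


def lit(gene: str) -> BooleanRule:
    if not gene or "::" in gene:
        raise ValueError(f"invalid gene symbol: {gene!r}")
    return BooleanRule("lit", gene=gene)


def not_(rule: BooleanRule) -> BooleanRule:
    if rule.op == "true":
        return FALSE
    if rule.op == "false":
        return TRUE
    if rule.op == "not":
        return rule.children[0]
    return BooleanRule("not", (rule,))


def _gather(rules: Iterable[BooleanRule], op: str) -> list[BooleanRule]:
    out: list[BooleanRule] = []
    for r in rules:
        if r.op == op:
            out.extend(r.children)
        else:
            out.append(r)
    return out


def and_(rules: Iterable[BooleanRule]) -> BooleanRule:
    kids = _gather(rules, "and")
    if any(k.is_false() for k in kids):
        return FALSE
    uniq = sorted({k._key: k for k in kids if not k.is_true()}.values(),
                  key=lambda r: r._key)
    if not uniq:
        return TRUE
    if len(uniq) == 1:
        return uniq[0]
    return BooleanRule("and", tuple(uniq))


def or_(rules: Iterable[BooleanRule]) -> BooleanRule:
    kids = _gather(rules, "or")
    if any(k.is_true() for k in kids):
        return TRUE
    uniq = sorted({k._key: k for k in kids if not k.is_false()}.values(),
                  key=lambda r: r._key)
    if not uniq:
        return FALSE
    if len(uniq) == 1:
        return uniq[0]
    return BooleanRule("or", tuple(uniq))


def _nnf(rule: BooleanRule, negate: bool) -> BooleanRule:
    if rule.op == "true":
        return FALSE if negate else TRUE
    if rule.op == "false":
        return TRUE if negate else FALSE
    if rule.op == "lit":
        return BooleanRule("not", (rule,)) if negate else rule
    if rule.op == "not":
        return _nnf(rule.children[0], not negate)
    if rule.op == "and":
        kids = (_nnf(c, negate) for c in rule.children)
        return or_(kids) if negate else and_(kids)
    kids = (_nnf(c, negate) for c in rule.children)
    return and_(kids) if negate else or_(kids)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-\[\]]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GprParseError(
                f"unknown token {stripped[0]!r}", pos + len(text[pos:]) - len(stripped)
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> BooleanRule:
    """Parse a GPR rule string into a normalised :class:`BooleanRule`.

    Grammar (case-insensitive keywords): ``or`` < ``and`` < ``not`` <
    parentheses; any other token is a gene symbol.  An empty or blank string
    denotes a spontaneous reaction and parses to TRUE.
    """
    tokens = _tokenize(text)
    if not tokens:
        return TRUE
    result, idx = _parse_or(tokens, 0)
    if idx != len(tokens):
        raise GprParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return result


def _parse_or(tokens, idx):
    terms = []
    term, idx = _parse_and(tokens, idx)
    terms.append(term)
    while idx < len(tokens) and tokens[idx][0].lower() == "or":
        term, idx = _parse_and(tokens, idx + 1)
        terms.append(term)
    return or_(terms), idx


def _parse_and(tokens, idx):
    factors = []
    factor, idx = _parse_unary(tokens, idx)
    factors.append(factor)
    while idx < len(tokens) and tokens[idx][0].lower() == "and":
        factor, idx = _parse_unary(tokens, idx + 1)
        factors.append(factor)
    return and_(factors), idx


def _parse_unary(tokens, idx):
    if idx >= len(tokens):
        last = tokens[-1][1] if tokens else 0
        raise GprParseError("unexpected end of rule", last)
    tok, pos = tokens[idx]
    low = tok.lower()
    if low == "not":
        inner, idx = _parse_unary(tokens, idx + 1)
        return not_(inner), idx
    if tok == "(":
        inner, idx = _parse_or(tokens, idx + 1)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GprParseError("unbalanced parentheses", pos)
        return inner, idx + 1
    if tok == ")":
        raise GprParseError("unbalanced parentheses", pos)
    if low in ("and", "or"):
        raise GprParseError(f"misplaced operator {tok!r}", pos)
    if low == "true":
        return TRUE, idx + 1
    if low == "false":
        return FALSE, idx + 1
    return lit(tok), idx + 1
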