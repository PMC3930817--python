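"""Gene-reaction rules: boolean AND/OR trees over gene identifiers.

Genome-scale metabolic models attach a gene rule to each enzymatic
reaction describing which gene products are needed to catalyze it:
isoenzymes are combined with OR, complex subunits with AND.  When the
rule is evaluated against expression intensities, OR takes the mean of
its children and AND the minimum (a complex is limited by its scarcest
subunit; isoenzymes pool their abundance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["GeneRule", "RuleError", "parse_rule"]


class RuleError(ValueError):
    """Raised when a gene-rule string cannot be parsed."""


@dataclass(frozen=True)
class GeneRule:
    """A node of a gene-rule tree.

    ``op`` is ``"gene"`` for a leaf (with ``gene`` set), or ``"and"`` /
    ``"or"`` for an operator node with at least two children.
    """

    op: str
    gene: str | None = None
    children: tuple["GeneRule", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise RuleError("leaf rule requires a non-empty gene id")
            if self.children:
                raise RuleError("leaf rule cannot have children")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise RuleError(f"{self.op!r} rule requires >= 2 children")
        else:
            raise RuleError(f"unknown rule operator {self.op!r}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "GeneRule":
        return GeneRule("gene", gene=gene)

    @staticmethod
    def and_(*children: "GeneRule") -> "GeneRule":
        return GeneRule("and", children=tuple(children))

    @staticmethod
    def or_(*children: "GeneRule") -> "GeneRule":
        return GeneRule("or", children=tuple(children))

    # -- queries ------------------------------------------------------
    def genes(self) -> frozenset[str]:
        """All gene ids appearing at the leaves."""
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def to_string(self, symbols: bool = False) -> str:
        """Render the rule; ``symbols=True`` uses ``&`` / ``|``."""
        op_txt = {"and": "&" if symbols else "and", "or": "|" if symbols else "or"}
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for child in self.children:
            txt = child.to_string(symbols=symbols)
            if child.op != "gene":
                txt = f"({txt})"
            parts.append(txt)
        return f" {op_txt[self.op]} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|&{1,2}|\|{1,2}|[^\s()&|]+")


def _tokenize(text: str) -> list[str]:
    tokens = []
    for tok in _TOKEN_RE.findall(text):
        if tok in ("&", "&&"):
            tokens.append("and")
        elif tok in ("|", "||"):
            tokens.append("or")
        elif tok.lower() in ("and", "or"):
            tokens.append(tok.lower())
        else:
            tokens.append(tok)
    return tokens


def parse_rule(text: str) -> GeneRule | None:
    """Parse a gene-rule string into a :class:`GeneRule` tree.

    The grammar honors parentheses and binds AND tighter than OR, so
    ``"g1 and g2 or g3"`` parses as ``OR(AND(g1, g2), g3)``.  ``and``/
    ``or`` keywords are case-insensitive; ``&`` and ``|`` are accepted
    as synonyms.  An empty or whitespace-only string yields ``None``
    (a non-enzymatic reaction).

    Raises
    ------
    RuleError
        On unbalanced parentheses or malformed operator placement.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GeneRule:
        children = [parse_and()]
        while peek() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else GeneRule.or_(*children)

    def parse_and() -> GeneRule:
        children = [parse_atom()]
        while peek() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else GeneRule.and_(*children)

    def parse_atom() -> GeneRule:
        tok = peek()
        if tok is None:
            raise RuleError(f"unexpected end of rule in {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise RuleError(f"unbalanced parentheses in rule {text!r}")
            take()
            return inner
        if tok in (")", "and", "or"):
            raise RuleError(f"unexpected token {tok!r} in rule {text!r}")
        return GeneRule.leaf(take())

    rule = parse_or()
    if pos != len(tokens):
        raise RuleError(f"trailing tokens {tokens[pos:]!r} in rule {text!r}")
    return rule
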