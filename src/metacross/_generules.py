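"""Boolean gene rules shared by metabolic reactions and signaling nodes.

A rule is either a single gene id (``str``) or a tuple ``(op, (rule, ...))``
with ``op`` in ``{"and", "or"}``.  AND models enzyme complexes (all subunits
required), OR models isozymes (any suffices).  Rules evaluate on continuous
expression values in [0, 1] with the min/max convention: AND -> min of the
member values, OR -> max.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

Rule = Union[str, tuple]

_OPS = {"and": min, "or": max}


def rule_genes(rule: Rule) -> set[str]:
    """Set of gene ids referenced anywhere in a rule."""
    if isinstance(rule, str):
        return {rule}
    op, args = rule
    out: set[str] = set()
    for a in args:
        out |= rule_genes(a)
    return out


def evaluate_rule(rule: Rule, expr: Mapping[str, float], missing: float | None = None) -> float:
    """Evaluate a rule on a per-gene expression mapping.

    ``missing`` substitutes genes absent from ``expr``; ``None`` raises.
    """
    if isinstance(rule, str):
        if rule in expr:
            return float(expr[rule])
        if missing is None:
            raise KeyError(f"gene {rule!r} absent from expression profile")
        return float(missing)
    op, args = rule
    vals = [evaluate_rule(a, expr, missing) for a in args]
    return float(_OPS[op](vals))


def rename_genes(rule: Rule, mapping: Mapping[str, str]) -> Rule:
    if isinstance(rule, str):
        return mapping.get(rule, rule)
    op, args = rule
    return (op, tuple(rename_genes(a, mapping) for a in args))


def format_rule(rule: Rule) -> str:
    """Serialize a rule to text: ``and`` -> '&', ``or`` -> '|', parentheses."""
    if isinstance(rule, str):
        return rule
    op, args = rule
    sep = " & " if op == "and" else " | "
    parts = []
    for a in args:
        s = format_rule(a)
        if not isinstance(a, str):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def parse_rule(text: str) -> Rule:
    """Parse the textual rule dialect produced by :func:`format_rule`.

    Accepts '&'/'AND' and '|'/'OR' connectives and parentheses; OR binds
    looser than AND.
    """
    tokens = _tokenize(text)
    rule, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in gene rule: {text!r}")
    return rule


def _tokenize(text: str) -> list[str]:
    out: list[str] = []
    buf = ""
    for ch in text:
        if ch in "()&|" or ch.isspace():
            if buf:
                out.append(buf)
            buf = ""
            if not ch.isspace():
                out.append(ch)
        else:
            buf += ch
    if buf:
        out.append(buf)
    # normalize word connectives
    norm = []
    for t in out:
        low = t.lower()
        if low == "and":
            norm.append("&")
        elif low == "or":
            norm.append("|")
        else:
            norm.append(t)
    return norm


def _parse_or(tokens: list[str], pos: int):
    terms = []
    term, pos = _parse_and(tokens, pos)
    terms.append(term)
    while pos < len(tokens) and tokens[pos] == "|":
        term, pos = _parse_and(tokens, pos + 1)
        terms.append(term)
    if len(terms) == 1:
        return terms[0], pos
    return ("or", tuple(terms)), pos


def _parse_and(tokens: list[str], pos: int):
    terms = []
    term, pos = _parse_atom(tokens, pos)
    terms.append(term)
    while pos < len(tokens) and tokens[pos] == "&":
        term, pos = _parse_atom(tokens, pos + 1)
        terms.append(term)
    if len(terms) == 1:
        return terms[0], pos
    return ("and", tuple(terms)), pos


def _parse_atom(tokens: list[str], pos: int):
    if pos >= len(tokens):
        raise ValueError("unexpected end of gene rule")
    tok = tokens[pos]
    if tok == "(":
        rule, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parentheses in gene rule")
        return rule, pos + 1
    if tok in "()&|":
        raise ValueError(f"unexpected token {tok!r} in gene rule")
    return tok, pos + 1


def all_genes(rules: Iterable[Rule]) -> set[str]:
    out: set[str] = set()
    for r in rules:
        out |= rule_genes(r)
    return out
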