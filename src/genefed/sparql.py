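"""Restricted SPARQL dialect: data model and parser.

Supported: ``PREFIX``, ``SELECT [DISTINCT]``, ``WHERE { triple patterns,
FILTER(=, !=, <, >, CONTAINS), SERVICE <iri> { ... } }``, ``LIMIT n``.
Anything else (OPTIONAL, UNION, subqueries, aggregates, property paths) is
rejected with an "unsupported feature" error rather than silently ignored:
the dialect covers exactly what the shipped query catalogue needs while
staying small enough to verify against brute-force evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .terms import IRI, BlankNode, Literal, PatternTerm, RDFError, Term, Variable
from .vocab import RDF, XSD


class QueryError(ValueError):
    """Malformed or unsupported query text."""


UNSUPPORTED_KEYWORDS = {
    "OPTIONAL", "UNION", "GRAPH", "MINUS", "BIND", "VALUES", "ORDER",
    "GROUP", "HAVING", "OFFSET", "ASK", "CONSTRUCT", "DESCRIBE", "EXISTS",
}


@dataclass(frozen=True, slots=True)
class TriplePattern:
    """A triple with variables allowed in any slot."""

    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def variables(self) -> set[Variable]:
        return {t for t in (self.subject, self.predicate, self.object) if isinstance(t, Variable)}

    def constants(self) -> int:
        return 3 - len([t for t in (self.subject, self.predicate, self.object) if isinstance(t, Variable)])


@dataclass(frozen=True, slots=True)
class Comparison:
    """``FILTER(?v op constant)`` with op one of ``=``, ``!=``, ``<``, ``>``.

    ``<``/``>`` compare numerically when both operands parse as decimals,
    lexicographically otherwise.
    """

    var: Variable
    op: str
    value: Term

    def evaluate(self, binding: Term) -> bool:
        if self.op == "=":
            return binding == self.value
        if self.op == "!=":
            return binding != self.value
        left = binding.lexical if isinstance(binding, Literal) else str(binding)
        right = self.value.lexical if isinstance(self.value, Literal) else str(self.value)
        try:
            lnum: float = float(left)
            rnum: float = float(right)
            lt = lnum < rnum
            eq = lnum == rnum
        except ValueError:
            lt = left < right
            eq = left == right
        if self.op == "<":
            return lt
        if self.op == ">":
            return not lt and not eq
        raise QueryError(f"unknown comparison operator {self.op!r}")

    def variables(self) -> set[Variable]:
        return {self.var}


@dataclass(frozen=True, slots=True)
class Contains:
    """``FILTER(CONTAINS(?v, "needle"))`` — case-insensitive substring test."""

    var: Variable
    needle: str

    def evaluate(self, binding: Term) -> bool:
        text = binding.lexical if isinstance(binding, Literal) else str(binding)
        return self.needle.lower() in text.lower()

    def variables(self) -> set[Variable]:
        return {self.var}


Filter = Union[Comparison, Contains]


@dataclass(frozen=True, slots=True)
class ServiceBlock:
    """A sub-BGP pinned to a specific endpoint IRI."""

    endpoint: IRI
    bgp: tuple[TriplePattern, ...]
    filters: tuple[Filter, ...] = ()


@dataclass(frozen=True, slots=True)
class ValuesClause:
    """Enumerated bindings injected by the bind-join machinery (internal;
    not part of the surface dialect)."""

    variables: tuple[Variable, ...]
    rows: tuple[tuple[Term, ...], ...]


@dataclass(frozen=True)
class Query:
    variables: tuple[Variable, ...]
    bgp: tuple[TriplePattern, ...] = ()
    filters: tuple[Filter, ...] = ()
    distinct: bool = False
    limit: Optional[int] = None
    service_blocks: tuple[ServiceBlock, ...] = ()
    values: Optional[ValuesClause] = None

    def __post_init__(self) -> None:
        in_scope = {v for p in self.bgp for v in p.variables()}
        for block in self.service_blocks:
            in_scope |= {v for p in block.bgp for v in p.variables()}
        for v in self.variables:
            if v not in in_scope:
                raise QueryError(f"projected variable {v} does not appear in the query body")
        if self.limit is not None and self.limit < 0:
            raise QueryError("LIMIT must be non-negative")

    def all_patterns(self) -> tuple[TriplePattern, ...]:
        return self.bgp + tuple(p for b in self.service_blocks for p in b.bgp)

    def all_filters(self) -> tuple[Filter, ...]:
        return self.filters + tuple(f for b in self.service_blocks for f in b.filters)

    def with_limit(self, limit: Optional[int]) -> "Query":
        return replace(self, limit=limit)


_SPARQL_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<comment>\#[^\n]*)
    | (?P<iriref><[^<>"{}|^`\\\s]*>)
    | (?P<string>"(?:[^"\\\n]|\\.)*")
    | (?P<langtag>@[a-zA-Z]+(?:-[a-zA-Z0-9]+)*)
    | (?P<dtype>\^\^)
    | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
    | (?P<blank>_:[A-Za-z0-9][A-Za-z0-9_.-]*)
    | (?P<pname>[A-Za-z][A-Za-z0-9_.-]*:[A-Za-z0-9][A-Za-z0-9_.%-]*)
    | (?P<name>[A-Za-z][A-Za-z0-9_-]*)
    | (?P<number>[+-]?\d+(?:\.\d+)?)
    | (?P<op>!=|[=<>])
    | (?P<punct>[{}().;,:])
    """,
    re.VERBOSE,
)

_STRING_UNESCAPES = {"\\\\": "\\", '\\"': '"', "\\n": "\n", "\\t": "\t", "\\r": "\r"}


def _unescape_string(raw: str) -> str:
    out = raw
    for esc, plain in (("\\n", "\n"), ("\\t", "\t"), ("\\r", "\r"), ('\\"', '"')):
        out = out.replace(esc, plain)
    return out.replace("\\\\", "\\")


class _QueryParser:
    def __init__(self, text: str):
        self.tokens: list[tuple[str, str]] = []
        pos = 0
        while pos < len(text):
            m = _SPARQL_TOKEN_RE.match(text, pos)
            if m is None:
                raise QueryError(f"unexpected character {text[pos]!r} in query")
            if m.lastgroup not in ("ws", "comment"):
                self.tokens.append((m.lastgroup or "", m.group()))
            pos = m.end()
        self.i = 0
        self.prefixes: dict[str, str] = {}

    def peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise QueryError("unexpected end of query text")
        self.i += 1
        return tok

    def _check_keyword(self, word: str) -> None:
        if word.upper() in UNSUPPORTED_KEYWORDS:
            raise QueryError(f"unsupported feature: {word.upper()}")

    def expect_name(self, word: str) -> None:
        kind, value = self.next()
        if kind != "name" or value.upper() != word:
            raise QueryError(f"expected {word}, got {value!r}")

    def expect_punct(self, char: str) -> None:
        kind, value = self.next()
        if value != char:
            raise QueryError(f"expected {char!r}, got {value!r}")

    def _iri(self, raw: str) -> IRI:
        try:
            return IRI(raw[1:-1])
        except RDFError as exc:
            raise QueryError(str(exc)) from None

    def _pname(self, raw: str) -> IRI:
        prefix, _, local = raw.partition(":")
        if prefix not in self.prefixes:
            raise QueryError(f"unknown prefix {prefix!r}")
        return IRI(self.prefixes[prefix] + local)

    def pattern_term(self) -> PatternTerm:
        kind, value = self.next()
        if kind == "var":
            return Variable(value[1:])
        if kind == "iriref":
            return self._iri(value)
        if kind == "pname":
            return self._pname(value)
        if kind == "blank":
            return BlankNode(value[2:])
        if kind == "name":
            if value == "a":
                return RDF.type
            self._check_keyword(value)
            raise QueryError(f"unexpected token {value!r} in triple pattern")
        if kind == "string":
            lexical = _unescape_string(value[1:-1])
            nxt = self.peek()
            if nxt and nxt[0] == "dtype":
                self.next()
                dkind, dval = self.next()
                if dkind == "iriref":
                    return Literal(lexical, datatype=self._iri(dval))
                if dkind == "pname":
                    return Literal(lexical, datatype=self._pname(dval))
                raise QueryError("expected datatype IRI after ^^")
            if nxt and nxt[0] == "langtag":
                self.next()
                return Literal(lexical, lang=nxt[1][1:])
            return Literal(lexical)
        if kind == "number":
            dt = XSD.decimal if "." in value else XSD.integer
            return Literal(value, datatype=dt)
        raise QueryError(f"unexpected token {value!r} in triple pattern")

    def parse_filter(self) -> Filter:
        self.expect_punct("(")
        kind, value = self.next()
        if kind == "name" and value.upper() == "CONTAINS":
            self.expect_punct("(")
            vkind, vval = self.next()
            if vkind != "var":
                raise QueryError("CONTAINS requires a variable as first argument")
            self.expect_punct(",")
            skind, sval = self.next()
            if skind != "string":
                raise QueryError("CONTAINS requires a string literal as second argument")
            self.expect_punct(")")
            self.expect_punct(")")
            return Contains(Variable(vval[1:]), _unescape_string(sval[1:-1]))
        if kind == "name":
            self._check_keyword(value)
            raise QueryError(f"unsupported filter function {value!r}")
        if kind != "var":
            raise QueryError("FILTER must compare a variable against a constant")
        var = Variable(value[1:])
        okind, op = self.next()
        if okind != "op":
            raise QueryError(f"expected comparison operator, got {op!r}")
        operand = self.pattern_term()
        if isinstance(operand, Variable):
            raise QueryError("variable-to-variable comparisons are not supported")
        if isinstance(operand, BlankNode):
            raise QueryError("cannot compare against a blank node")
        self.expect_punct(")")
        return Comparison(var, op, operand)

    def parse_group(self, allow_service: bool) -> tuple[list[TriplePattern], list[Filter], list[ServiceBlock]]:
        patterns: list[TriplePattern] = []
        filters: list[Filter] = []
        services: list[ServiceBlock] = []
        self.expect_punct("{")
        while True:
            tok = self.peek()
            if tok is None:
                raise QueryError("unterminated group: missing '}'")
            kind, value = tok
            if value == "}":
                self.next()
                break
            if kind == "name" and value.upper() == "FILTER":
                self.next()
                filters.append(self.parse_filter())
                self._maybe_dot()
                continue
            if kind == "name" and value.upper() == "SERVICE":
                if not allow_service:
                    raise QueryError("unsupported feature: nested SERVICE")
                self.next()
                ikind, ival = self.next()
                if ikind == "iriref":
                    endpoint = self._iri(ival)
                elif ikind == "pname":
                    endpoint = self._pname(ival)
                else:
                    raise QueryError("SERVICE requires an endpoint IRI")
                sub_p, sub_f, _ = self.parse_group(allow_service=False)
                services.append(ServiceBlock(endpoint, tuple(sub_p), tuple(sub_f)))
                self._maybe_dot()
                continue
            if kind == "name" and value.upper() in UNSUPPORTED_KEYWORDS:
                raise QueryError(f"unsupported feature: {value.upper()}")
            if value == "{":
                raise QueryError("unsupported feature: nested group graph patterns (UNION/OPTIONAL)")
            s = self.pattern_term()
            p = self.pattern_term()
            o = self.pattern_term()
            patterns.append(TriplePattern(s, p, o))
            self._maybe_dot()
        return patterns, filters, services

    def _maybe_dot(self) -> None:
        tok = self.peek()
        if tok and tok[1] == ".":
            self.next()

    def parse(self) -> Query:
        while True:
            tok = self.peek()
            if tok and tok[0] == "name" and tok[1].upper() == "PREFIX":
                self.next()
                nkind, label = self.next()
                if nkind != "name":
                    raise QueryError("expected prefix label")
                # the tokenizer has no bare-colon pname, so the colon arrives
                # fused with the following IRI only via punct ':' — not in
                # this token set; accept "label : <iri>" shape
                self._expect_colon()
                ikind, ival = self.next()
                if ikind != "iriref":
                    raise QueryError("expected IRI in PREFIX declaration")
                self.prefixes[label] = ival[1:-1]
                continue
            break
        self.expect_name("SELECT")
        distinct = False
        tok = self.peek()
        if tok and tok[0] == "name" and tok[1].upper() == "DISTINCT":
            self.next()
            distinct = True
        variables: list[Variable] = []
        while True:
            tok = self.peek()
            if tok is None:
                raise QueryError("unexpected end of query after SELECT")
            if tok[0] == "var":
                self.next()
                variables.append(Variable(tok[1][1:]))
                continue
            break
        if not variables:
            raise QueryError("SELECT requires at least one projected variable")
        tok = self.peek()
        if tok and tok[0] == "name" and tok[1].upper() == "WHERE":
            self.next()
        patterns, filters, services = self.parse_group(allow_service=True)
        limit: Optional[int] = None
        tok = self.peek()
        if tok and tok[0] == "name":
            if tok[1].upper() == "LIMIT":
                self.next()
                nkind, nval = self.next()
                if nkind != "number" or "." in nval or int(nval) < 0:
                    raise QueryError("LIMIT requires a non-negative integer")
                limit = int(nval)
            elif tok[1].upper() in UNSUPPORTED_KEYWORDS:
                raise QueryError(f"unsupported feature: {tok[1].upper()}")
        tok = self.peek()
        if tok is not None:
            if tok[0] == "name" and tok[1].upper() in UNSUPPORTED_KEYWORDS:
                raise QueryError(f"unsupported feature: {tok[1].upper()}")
            raise QueryError(f"unexpected trailing token {tok[1]!r}")
        return Query(
            variables=tuple(variables),
            bgp=tuple(patterns),
            filters=tuple(filters),
            distinct=distinct,
            limit=limit,
            service_blocks=tuple(services),
        )

    def _expect_colon(self) -> None:
        kind, value = self.next()
        if value != ":":
            raise QueryError(f"expected ':' in PREFIX declaration, got {value!r}")


def parse_query(text: str, extra_prefixes: Optional[dict[str, str]] = None) -> Query:
    """Parse restricted-SPARQL text into a :class:`Query`.

    Unsupported SPARQL keywords raise :class:`QueryError` mentioning the
    feature; unknown prefixes raise as well.
    """
    parser = _QueryParser(text)
    if extra_prefixes:
        parser.prefixes.update(extra_prefixes)
    return parser.parse()
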