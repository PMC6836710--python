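"""Relational-to-RDF mapping rules: the declarative heart of the OBDA engine.

A mapping document is a sequence of blocks in an Ontop-like line dialect::

    prefix orth: <http://purl.org/net/orth#>

    mappingId  gene-class
    source     SELECT geneId FROM gene
    target     <http://example.org/genefed/gene/{geneId}> a orth:Gene .

The ``source`` is a SQL SELECT statement over the embedded database; the
``target`` is a list of triple templates in Turtle-like syntax where
``{column}`` marks a placeholder and ``{column|name}`` additionally applies
a registered transformation (e.g. ``uberon`` for CURIE-to-underscore
identifier rewriting).  Placeholder values in IRI templates are
percent-encoded.  A NULL value in any referenced column suppresses that
single triple rather than erroring, mirroring R2RML semantics.
"""

from __future__ import annotations

import re
import sqlite3
import urllib.parse
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .terms import IRI, Literal, RDFError, Term, Triple
from .transforms import INVERSES, TRANSFORMS, TransformError
from .vocab import PREFIXES, RDF


class MappingError(ValueError):
    """Malformed mapping document or rule application failure."""


_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)(?:\|([A-Za-z_]+))?\}")


@dataclass(frozen=True, slots=True)
class Placeholder:
    column: str
    transform: Optional[str] = None


@dataclass(frozen=True)
class Template:
    """A string template producing an IRI or literal per database row."""

    parts: tuple[Union[str, Placeholder], ...]
    kind: str  # "iri" | "literal"
    datatype: Optional[IRI] = None

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(p.column for p in self.parts if isinstance(p, Placeholder))

    @property
    def placeholders(self) -> tuple[Placeholder, ...]:
        return tuple(p for p in self.parts if isinstance(p, Placeholder))

    def expand(self, row: dict) -> Optional[Term]:
        """Instantiate against a row; returns None if any column is NULL."""
        out: list[str] = []
        for part in self.parts:
            if isinstance(part, str):
                out.append(part)
                continue
            if part.column not in row:
                raise MappingError(f"row is missing column {part.column!r}")
            value = row[part.column]
            if value is None:
                return None
            text = str(value)
            if part.transform is not None:
                try:
                    text = TRANSFORMS[part.transform](text)
                except TransformError as exc:
                    raise MappingError(f"transformation {part.transform!r} failed: {exc}") from exc
            if self.kind == "iri":
                text = urllib.parse.quote(text, safe="")
            out.append(text)
        joined = "".join(out)
        if self.kind == "iri":
            try:
                return IRI(joined)
            except RDFError as exc:
                raise MappingError(str(exc)) from exc
        return Literal(joined, datatype=self.datatype)

    def invert(self, term: Term) -> Optional[dict[str, str]]:
        """Recover column values from a constant term, when possible.

        Returns a column->value dict for single-placeholder templates whose
        transformation is invertible; ``None`` when inversion is not
        available (the engine then post-filters); raises
        :class:`_Mismatch` when the constant cannot match this template at
        all.
        """
        if self.kind == "iri":
            if not isinstance(term, IRI):
                raise _Mismatch
            text = term.value
        else:
            if not isinstance(term, Literal) or term.datatype != self.datatype or term.lang is not None:
                raise _Mismatch
            text = term.lexical
        phs = self.placeholders
        if len(phs) != 1:
            return None
        prefix = "".join(p for p in self.parts[: self.parts.index(phs[0])] if isinstance(p, str))
        suffix = "".join(p for p in self.parts[self.parts.index(phs[0]) + 1 :] if isinstance(p, str))
        if not (text.startswith(prefix) and text.endswith(suffix) and len(text) >= len(prefix) + len(suffix)):
            raise _Mismatch
        middle = text[len(prefix) : len(text) - len(suffix)]
        if self.kind == "iri":
            middle = urllib.parse.unquote(middle)
        ph = phs[0]
        if ph.transform is not None:
            inverse = INVERSES.get(ph.transform)
            if inverse is None:
                return None
            try:
                middle = inverse(middle)
            except TransformError:
                raise _Mismatch from None
        return {ph.column: middle}


class _Mismatch(Exception):
    """A query constant can never be produced by a template."""


TemplateSlot = Union[IRI, Literal, Template]


@dataclass(frozen=True)
class TripleTemplate:
    """Three slots, each a constant term or a template; the predicate slot
    must be a constant IRI."""

    subject: TemplateSlot
    predicate: IRI
    object: TemplateSlot

    def __post_init__(self) -> None:
        if not isinstance(self.predicate, IRI):
            raise MappingError("predicate templates must be constant IRIs")

    @property
    def slots(self) -> tuple[TemplateSlot, TemplateSlot, TemplateSlot]:
        return (self.subject, self.predicate, self.object)

    def columns(self) -> set[str]:
        cols: set[str] = set()
        for slot in self.slots:
            if isinstance(slot, Template):
                cols.update(slot.columns)
        return cols

    def expand(self, row: dict) -> Optional[Triple]:
        terms: list[Term] = []
        for slot in self.slots:
            if isinstance(slot, Template):
                value = slot.expand(row)
                if value is None:
                    return None
                terms.append(value)
            else:
                terms.append(slot)
        subject, predicate, obj = terms
        if isinstance(subject, Literal):
            raise MappingError("template produced a literal subject")
        assert isinstance(predicate, IRI)
        return Triple(subject, predicate, obj)


@dataclass(frozen=True)
class MappingRule:
    id: str
    source: str
    targets: tuple[TripleTemplate, ...]

    def columns(self) -> set[str]:
        cols: set[str] = set()
        for t in self.targets:
            cols.update(t.columns())
        return cols


def expand_rule(rule: MappingRule, row: dict) -> list[Triple]:
    """Apply every triple template of a rule to one source row.

    Templates touching a NULL column contribute no triple (skip, not
    error); a column absent from the row raises :class:`MappingError`.
    """
    triples: list[Triple] = []
    for template in rule.targets:
        missing = [c for c in template.columns() if c not in row]
        if missing:
            raise MappingError(f"rule {rule.id!r}: row is missing column {missing[0]!r}")
        t = template.expand(row)
        if t is not None:
            triples.append(t)
    return triples


# --- target-text parsing -------------------------------------------------

_TARGET_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<iriref><[^<>\s]*>)
    | (?P<string>"(?:[^"\\]|\\.)*")
    | (?P<dtype>\^\^)
    | (?P<pname>[A-Za-z][A-Za-z0-9_.-]*:[A-Za-z0-9][A-Za-z0-9_.%-]*)
    | (?P<a>a\b)
    | (?P<punct>[.;,])
    """,
    re.VERBOSE,
)


def _parse_template_string(raw: str, kind: str, datatype: Optional[IRI]) -> TemplateSlot:
    parts: list[Union[str, Placeholder]] = []
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(raw):
        if m.start() > pos:
            parts.append(raw[pos : m.start()])
        transform = m.group(2)
        if transform is not None and transform not in TRANSFORMS:
            raise MappingError(f"unknown transformation {transform!r}")
        parts.append(Placeholder(m.group(1), transform))
        pos = m.end()
    if pos < len(raw):
        parts.append(raw[pos:])
    if not any(isinstance(p, Placeholder) for p in parts):
        if kind == "iri":
            try:
                return IRI(raw)
            except RDFError as exc:
                raise MappingError(str(exc)) from exc
        return Literal(raw, datatype=datatype)
    return Template(tuple(parts), kind, datatype)


class _TargetParser:
    def __init__(self, text: str, prefixes: dict[str, str]):
        self.tokens: list[tuple[str, str]] = []
        pos = 0
        while pos < len(text):
            m = _TARGET_TOKEN_RE.match(text, pos)
            if m is None:
                raise MappingError(f"unexpected character {text[pos]!r} in target")
            if m.lastgroup != "ws":
                self.tokens.append((m.lastgroup or "", m.group()))
            pos = m.end()
        self.i = 0
        self.prefixes = prefixes

    def _peek(self) -> Optional[tuple[str, str]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, str]:
        tok = self._peek()
        if tok is None:
            raise MappingError("unexpected end of target")
        self.i += 1
        return tok

    def _slot(self, position: str) -> TemplateSlot:
        kind, value = self._next()
        if kind == "iriref":
            return _parse_template_string(value[1:-1], "iri", None)
        if kind == "pname":
            prefix, _, local = value.partition(":")
            if prefix not in self.prefixes:
                raise MappingError(f"unknown prefix {prefix!r} in target")
            return IRI(self.prefixes[prefix] + local)
        if kind == "a" and position == "predicate":
            return RDF.type
        if kind == "string" and position == "object":
            raw = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            datatype: Optional[IRI] = None
            nxt = self._peek()
            if nxt and nxt[0] == "dtype":
                self._next()
                dkind, dval = self._next()
                if dkind == "iriref":
                    datatype = IRI(dval[1:-1])
                elif dkind == "pname":
                    prefix, _, local = dval.partition(":")
                    if prefix not in self.prefixes:
                        raise MappingError(f"unknown prefix {prefix!r} in target")
                    datatype = IRI(self.prefixes[prefix] + local)
                else:
                    raise MappingError("expected datatype after ^^")
            return _parse_template_string(raw, "literal", datatype)
        raise MappingError(f"unexpected token {value!r} in target {position} position")

    def parse(self) -> list[TripleTemplate]:
        templates: list[TripleTemplate] = []
        while self._peek() is not None:
            subject = self._slot("subject")
            while True:
                predicate = self._slot("predicate")
                if not isinstance(predicate, IRI):
                    raise MappingError("predicate templates must be constant IRIs")
                while True:
                    obj = self._slot("object")
                    templates.append(TripleTemplate(subject, predicate, obj))
                    nxt = self._peek()
                    if nxt and nxt[1] == ",":
                        self._next()
                        continue
                    break
                nxt = self._peek()
                if nxt and nxt[1] == ";":
                    self._next()
                    after = self._peek()
                    if after and after[1] == ".":
                        self._next()
                        break
                    continue
                kind, value = self._next()
                if value != ".":
                    raise MappingError(f"expected '.', got {value!r}")
                break
        return templates


def source_columns(conn: sqlite3.Connection, sql: str) -> list[str]:
    """The projected column names of a source SELECT (via a LIMIT-0 probe)."""
    cur = conn.execute(f"SELECT * FROM ({sql}) LIMIT 0")
    return [d[0] for d in cur.description]


def load_mappings(doc: str, conn: Optional[sqlite3.Connection] = None) -> list[MappingRule]:
    """Parse a mapping document; optionally validate sources and placeholders
    against a live database connection.

    Errors name the offending rule id: duplicate ids, unknown prefixes or
    transformations, and (with a connection) placeholders missing from the
    source projection.
    """
    prefixes = dict(PREFIXES)
    rules: list[MappingRule] = []
    seen_ids: set[str] = set()

    # fold continuation lines (leading whitespace) into logical lines
    logical: list[str] = []
    for raw in doc.splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            logical.append("")
            continue
        if raw[:1].isspace() and logical and logical[-1]:
            logical[-1] += " " + raw.strip()
        else:
            logical.append(raw.strip())

    block: dict[str, str] = {}

    def flush() -> None:
        if not block:
            return
        for key in ("mappingId", "source", "target"):
            if key not in block:
                raise MappingError(f"mapping block missing {key!r} (id={block.get('mappingId', '?')!r})")
        rule_id = block["mappingId"]
        if rule_id in seen_ids:
            raise MappingError(f"duplicate mapping id {rule_id!r}")
        seen_ids.add(rule_id)
        targets = _TargetParser(block["target"], prefixes).parse()
        if not targets:
            raise MappingError(f"rule {rule_id!r} has an empty target")
        rule = MappingRule(rule_id, block["source"], tuple(targets))
        if conn is not None:
            try:
                projected = set(source_columns(conn, rule.source))
            except sqlite3.Error as exc:
                raise MappingError(f"rule {rule_id!r}: source query failed: {exc}") from exc
            missing = rule.columns() - projected
            if missing:
                raise MappingError(
                    f"rule {rule_id!r}: placeholder column(s) {sorted(missing)} "
                    f"not in source projection {sorted(projected)}"
                )
        rules.append(rule)
        block.clear()

    for line in logical:
        if not line:
            continue
        m = re.match(r"(prefix|mappingId|source|target)\s+(.*)$", line)
        if m is None:
            raise MappingError(f"unrecognized mapping line: {line!r}")
        key, rest = m.group(1), m.group(2).strip()
        if key == "prefix":
            pm = re.match(r"([A-Za-z][A-Za-z0-9_-]*):\s*<([^<>\s]+)>$", rest)
            if pm is None:
                raise MappingError(f"malformed prefix declaration: {line!r}")
            prefixes[pm.group(1)] = pm.group(2)
            continue
        if key == "mappingId" and block:
            flush()
        if key in block:
            raise MappingError(f"duplicate {key!r} line in mapping block {block.get('mappingId', '?')!r}")
        block[key] = rest
    flush()
    return rules
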