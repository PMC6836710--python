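"""Ontology-based data access over the embedded relational database.

A :class:`VirtualGraph` pairs a SQLite connection with a list of mapping
rules and supports two answering modes:

* ``materialize()`` — expand every rule over every source row into an
  explicit :class:`~genefed.terms.Graph` (the materialization side of the
  virtualization/materialization trade-off);
* ``answer_bgp_virtual()`` — answer a BGP query on the fly by unifying each
  triple pattern against the triple templates, pushing invertible query
  constants down into SQL ``WHERE`` clauses, post-filtering where a
  transformation is not invertible, and joining per-pattern candidate
  bindings in memory.

The two modes are required (and tested) to agree exactly.
"""

from __future__ import annotations

import sqlite3
from typing import Iterable, Optional

from .evaluate import Binding, SolutionSet, finalize_bindings
from .mappings import MappingRule, MappingError, Template, TripleTemplate, _Mismatch, expand_rule, load_mappings, source_columns
from .sparql import Query, QueryError, TriplePattern
from .terms import Graph, IRI, Literal, Term, Variable


class VirtualGraph:
    """A relational database exposed as a virtual RDF graph via mappings."""

    def __init__(self, conn: sqlite3.Connection, rules: Iterable[MappingRule]):
        self.conn = conn
        self.rules = list(rules)
        for rule in self.rules:
            projected = set(source_columns(conn, rule.source))
            missing = rule.columns() - projected
            if missing:
                raise MappingError(
                    f"rule {rule.id!r}: placeholder column(s) {sorted(missing)} not in source projection"
                )

    @classmethod
    def from_mapping_document(cls, conn: sqlite3.Connection, doc: str) -> "VirtualGraph":
        return cls(conn, load_mappings(doc, conn))

    # -- materialization ---------------------------------------------------

    def _rows(self, sql: str, params: tuple = (), rule_id: str = "?") -> tuple[list[str], list[tuple]]:
        try:
            cur = self.conn.execute(sql, params)
        except sqlite3.Error as exc:
            raise MappingError(f"rule {rule_id!r}: relational query failed: {exc}") from exc
        cols = [d[0] for d in cur.description]
        return cols, cur.fetchall()

    def materialize(self) -> Graph:
        """Expand all rules over all rows; deterministic for a fixed DB."""
        g = Graph()
        for rule in self.rules:
            cols, rows = self._rows(rule.source, rule_id=rule.id)
            for row in rows:
                g.update(expand_rule(rule, dict(zip(cols, row))))
        return g

    # -- virtual answering -------------------------------------------------

    def _pattern_candidates(self, pattern: TriplePattern) -> list[Binding]:
        """All bindings under which the pattern matches the virtual graph.

        Candidates are deduplicated: each corresponds to one distinct
        matching triple of the materialization, so downstream joins carry
        the same multiplicities as matching against the materialized set.
        """
        seen: set[tuple] = set()
        out: list[Binding] = []
        for rule in self.rules:
            for template in rule.targets:
                self._template_candidates(pattern, rule, template, seen, out)
        return out

    def _template_candidates(
        self,
        pattern: TriplePattern,
        rule: MappingRule,
        template: TripleTemplate,
        seen: set[tuple],
        out: list[Binding],
    ) -> None:
        constraints: dict[str, str] = {}
        post: list[tuple[Template, Term]] = []
        var_slots: list[tuple[Variable, object]] = []
        for pslot, tslot in zip((pattern.subject, pattern.predicate, pattern.object), template.slots):
            if isinstance(pslot, Variable):
                var_slots.append((pslot, tslot))
                continue
            if isinstance(tslot, (IRI, Literal)):
                if pslot != tslot:
                    return  # constant-vs-constant mismatch
                continue
            assert isinstance(tslot, Template)
            try:
                inverted = tslot.invert(pslot)
            except _Mismatch:
                return
            if inverted is None:
                post.append((tslot, pslot))
            else:
                for col, val in inverted.items():
                    if col in constraints and constraints[col] != val:
                        return
                    constraints[col] = val
        sql = f"SELECT * FROM ({rule.source})"
        params: tuple = ()
        if constraints:
            items = sorted(constraints.items())
            # values recovered from IRIs are strings; cast so INTEGER columns
            # (e.g. taxon identifiers) compare on their text form
            sql += " WHERE " + " AND ".join(f'CAST("{col}" AS TEXT) = ?' for col, _ in items)
            params = tuple(val for _, val in items)
        cols, rows = self._rows(sql, params, rule.id)
        for raw in rows:
            row = dict(zip(cols, raw))
            ok = True
            for tslot, expected in post:
                value = tslot.expand(row)
                if value is None or value != expected:
                    ok = False
                    break
            if not ok:
                continue
            binding: Binding = {}
            for var, tslot in var_slots:
                if isinstance(tslot, Template):
                    value = tslot.expand(row)
                    if value is None:
                        ok = False
                        break
                else:
                    value = tslot  # constant slot binds the variable directly
                bound = binding.get(var)
                if bound is None:
                    binding[var] = value
                elif bound != value:
                    ok = False
                    break
            if not ok:
                continue
            key = tuple(sorted(((v.name, b) for v, b in binding.items()), key=lambda kv: kv[0]))
            if key in seen:
                continue
            seen.add(key)
            out.append(binding)

    def answer_bgp_virtual(self, q: Query) -> SolutionSet:
        """Answer a service-free query directly against the database.

        Result is guaranteed (and tested) to equal
        ``match_bgp(self.materialize(), q)`` as a multiset.
        """
        if q.service_blocks:
            raise QueryError("virtual answering does not handle SERVICE blocks")
        bindings: list[Binding] = [{}]
        for pattern in q.bgp:
            candidates = self._pattern_candidates(pattern)
            nxt: list[Binding] = []
            for b in bindings:
                for c in candidates:
                    merged = dict(b)
                    ok = True
                    for var, val in c.items():
                        bound = merged.get(var)
                        if bound is None:
                            merged[var] = val
                        elif bound != val:
                            ok = False
                            break
                    if ok:
                        nxt.append(merged)
            bindings = nxt
            if not bindings:
                break
        return finalize_bindings(bindings, q)


def materialize(v: VirtualGraph) -> Graph:
    return v.materialize()


def answer_bgp_virtual(v: VirtualGraph, q: Query) -> SolutionSet:
    return v.answer_bgp_virtual(q)
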