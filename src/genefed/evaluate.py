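"""Naive in-memory BGP evaluation: the correctness oracle.

``match_bgp`` enumerates bindings pattern by pattern with a nested loop over
the whole graph — no indexes, no ordering tricks.  Correctness over speed:
every other answering path in the package (the OBDA engine, the federation
engine) is required by tests to agree with this one.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Iterator, Mapping, Optional

from .sparql import Filter, Query, QueryError, TriplePattern, ValuesClause
from .terms import Graph, PatternTerm, Term, Triple, Variable

Binding = dict[Variable, Term]


class SolutionSet:
    """A multiset of solution mappings over a fixed variable tuple.

    Equality is multiset equality, independent of solution order (the
    dialect has no ORDER BY, so order is unspecified).
    """

    def __init__(self, variables: Iterable[Variable], solutions: Iterable[Mapping[Variable, Term]] = ()):
        self.variables: tuple[Variable, ...] = tuple(variables)
        self.solutions: list[Binding] = [dict(s) for s in solutions]

    def add(self, solution: Mapping[Variable, Term]) -> None:
        self.solutions.append(dict(solution))

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self) -> Iterator[Binding]:
        return iter(self.solutions)

    def _key(self, solution: Binding) -> tuple:
        return tuple(solution.get(v) for v in self.variables)

    def as_multiset(self) -> Counter:
        return Counter(self._key(s) for s in self.solutions)

    def as_set(self) -> set[tuple]:
        return {self._key(s) for s in self.solutions}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SolutionSet):
            return NotImplemented
        return set(self.variables) == set(other.variables) and Counter(
            tuple(sorted(((v.name, s.get(v)) for v in self.variables), key=lambda kv: kv[0]))
            for s in self.solutions
        ) == Counter(
            tuple(sorted(((v.name, s.get(v)) for v in other.variables), key=lambda kv: kv[0]))
            for s in other.solutions
        )

    def __repr__(self) -> str:
        return f"SolutionSet({[str(v) for v in self.variables]}, {len(self)} solutions)"


def _unify(pattern: TriplePattern, triple: Triple, binding: Binding) -> Optional[Binding]:
    out = dict(binding)
    for slot, value in zip((pattern.subject, pattern.predicate, pattern.object), triple):
        if isinstance(slot, Variable):
            bound = out.get(slot)
            if bound is None:
                out[slot] = value
            elif bound != value:
                return None
        elif slot != value:
            return None
    return out


def _apply_filters(bindings: list[Binding], filters: Iterable[Filter]) -> list[Binding]:
    out = bindings
    for f in filters:
        kept = []
        for b in out:
            value = b.get(f.var)
            # An unbound filter variable yields an evaluation error in SPARQL,
            # which eliminates the solution.
            if value is not None and f.evaluate(value):
                kept.append(b)
        out = kept
    return out


def _compatible_with_values(binding: Binding, values: ValuesClause) -> bool:
    for row in values.rows:
        ok = True
        for var, val in zip(values.variables, row):
            bound = binding.get(var)
            if bound is not None and bound != val:
                ok = False
                break
        if ok:
            return True
    return False


def finalize_bindings(bindings: list[Binding], q: Query) -> SolutionSet:
    """Shared solution-modifier tail: filters, VALUES compatibility,
    projection, DISTINCT and LIMIT, in that order."""
    bindings = _apply_filters(bindings, q.filters)
    if q.values is not None:
        bindings = [b for b in bindings if _compatible_with_values(b, q.values)]
    projected = [{v: b[v] for v in q.variables if v in b} for b in bindings]
    if q.distinct:
        seen: set[tuple] = set()
        unique: list[Binding] = []
        for p in projected:
            key = tuple(p.get(v) for v in q.variables)
            if key not in seen:
                seen.add(key)
                unique.append(p)
        projected = unique
    if q.limit is not None:
        projected = projected[: q.limit]
    return SolutionSet(q.variables, projected)


def match_bgp(g: Graph, q: Query) -> SolutionSet:
    """Evaluate a service-free query against a graph.

    Returns all solution mappings whose substitution into every pattern
    yields triples present in ``g`` and which pass every filter; then
    applies the internal VALUES constraint (bind-join support), projection,
    DISTINCT, and LIMIT, in that order.  An empty BGP yields exactly one
    empty solution (the join identity).  Evaluation is a naive nested loop
    over the whole graph per pattern.
    """
    if q.service_blocks:
        raise QueryError("match_bgp cannot evaluate SERVICE blocks; use the federation engine")
    bindings: list[Binding] = [{}]
    for pattern in q.bgp:
        nxt: list[Binding] = []
        for b in bindings:
            for triple in g:
                unified = _unify(pattern, triple, b)
                if unified is not None:
                    nxt.append(unified)
        bindings = nxt
        if not bindings:
            break
    return finalize_bindings(bindings, q)
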