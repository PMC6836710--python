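"""Federated query decomposition and bind-join execution (the SQI layer).

A conjunctive query spanning several datasets is decomposed into
per-endpoint sub-queries using the dataset descriptions (which predicates
and classes each store serves), ordered by a constant-counting selectivity
heuristic, and executed with bind joins: the bindings accumulated so far are
shipped into the next stage as enumerated value constraints, bounding
intermediate results.  A plan is only accepted where every later stage
shares at least one variable with the earlier stages that is *covered* by a
declared, active virtual link — the formal join contract between datasets.

The specificity lesson is structural: a stage constrained by more constants
and filters is planned earlier, so e.g. a clade-restricted orthology stage
both runs earlier and ships fewer bindings than an unrestricted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .evaluate import Binding, SolutionSet, finalize_bindings, match_bgp
from .obda import VirtualGraph
from .sparql import Filter, Query, QueryError, ServiceBlock, TriplePattern, ValuesClause
from .terms import Graph, IRI, Literal, Term, Variable
from .vocab import A
from .voidext import ACTIVE, DatasetDescription, VirtualLinkSet


class FederationError(ValueError):
    """Unanswerable pattern, unplannable query or execution failure."""


class EndpointUnavailable(RuntimeError):
    """The endpoint did not answer."""


# --- endpoints ------------------------------------------------------------


class GraphEndpoint:
    """An in-process endpoint answering queries over a materialized graph."""

    def __init__(self, id: str, graph: Graph, available: bool = True):
        self.id = id
        self.graph = graph
        self.available = available

    def answer(self, q: Query) -> SolutionSet:
        if not self.available:
            raise EndpointUnavailable(self.id)
        return match_bgp(self.graph, q)


class VirtualEndpoint:
    """An endpoint answering queries through the OBDA engine on the fly."""

    def __init__(self, id: str, virtual: VirtualGraph, available: bool = True):
        self.id = id
        self.virtual = virtual
        self.available = available

    def answer(self, q: Query) -> SolutionSet:
        if not self.available:
            raise EndpointUnavailable(self.id)
        return self.virtual.answer_bgp_virtual(q)


def check_availability(endpoints: Mapping[str, "GraphEndpoint | VirtualEndpoint"]) -> dict[str, str]:
    """Probe each endpoint with the empty-BGP query; report up/down."""
    report: dict[str, str] = {}
    probe = Query(variables=())
    for eid, ep in endpoints.items():
        try:
            result = ep.answer(probe)
            report[eid] = "up" if len(result) == 1 else "down"
        except Exception:
            report[eid] = "down"
    return report


# --- metadata -------------------------------------------------------------


@dataclass
class FederationMetadata:
    """Dataset descriptions plus the declared virtual links."""

    datasets: dict[IRI, DatasetDescription]
    links: list[VirtualLinkSet]

    def dataset_for_endpoint(self, endpoint: str) -> DatasetDescription:
        for ds in self.datasets.values():
            if ds.endpoint == endpoint:
                return ds
        raise FederationError(f"no registered dataset for endpoint {endpoint!r}")

    def active_links_between(self, a: IRI, b: IRI) -> list[VirtualLinkSet]:
        return [
            l for l in self.links
            if l.status == ACTIVE and l.datasets() == frozenset((a, b))
        ]


# --- source selection -----------------------------------------------------


def _candidates(pattern: TriplePattern, meta: FederationMetadata) -> list[IRI]:
    pred = pattern.predicate
    if isinstance(pred, Variable):
        raise FederationError("variable-predicate patterns are not supported in federation")
    if not isinstance(pred, IRI):
        raise FederationError("pattern predicate must be an IRI")
    out: list[IRI] = []
    for ds_id in sorted(meta.datasets, key=lambda d: d.value):
        ds = meta.datasets[ds_id]
        if pred == A and isinstance(pattern.object, IRI):
            if pattern.object in ds.classes:
                out.append(ds_id)
        elif pred in ds.predicates:
            out.append(ds_id)
    if not out:
        raise FederationError(f"unanswerable pattern: no dataset covers predicate {pred.value}")
    return out


def select_sources(q: Query, meta: FederationMetadata) -> list[tuple[TriplePattern, IRI]]:
    """Assign each main-BGP pattern to a dataset.

    Patterns answerable by several datasets go to the dataset already
    holding the most patterns (maximize sub-query size, minimize remote
    joins); remaining ties break on dataset id.  Patterns inside explicit
    SERVICE blocks are pinned by the caller and are not assigned here.
    """
    cand = {i: _candidates(p, meta) for i, p in enumerate(q.bgp)}
    assignment: dict[int, IRI] = {i: c[0] for i, c in cand.items() if len(c) == 1}
    # seed counts with pinned SERVICE stages so ambiguous patterns gravitate
    counts: dict[IRI, int] = {ds: 0 for ds in meta.datasets}
    for ds_id in assignment.values():
        counts[ds_id] += 1
    for block in q.service_blocks:
        ds = meta.dataset_for_endpoint(block.endpoint.value)
        counts[ds.id] += len(block.bgp)
    for i, p in enumerate(q.bgp):
        if i in assignment:
            continue
        # most-loaded candidate wins; remaining ties break on dataset id
        best = sorted(cand[i], key=lambda d: (-counts[d], d.value))[0]
        assignment[i] = best
        counts[best] += 1
    return [(p, assignment[i]) for i, p in enumerate(q.bgp)]


# --- planning -------------------------------------------------------------


@dataclass(frozen=True)
class PlanStage:
    dataset: IRI
    endpoint: str
    bgp: tuple[TriplePattern, ...]
    filters: tuple[Filter, ...]
    score: int
    join_vars: tuple[Variable, ...] = ()

    def variables(self) -> set[Variable]:
        return {v for p in self.bgp for v in p.variables()}


@dataclass(frozen=True)
class FederatedPlan:
    stages: tuple[PlanStage, ...]
    query: Query


def _stage_classes_of_var(stage: PlanStage, ds: DatasetDescription, var: Variable) -> set[IRI]:
    """Classes a join variable can be inferred to range over in a stage."""
    classes: set[IRI] = set()
    for p in stage.bgp:
        if p.predicate == A and p.subject == var and isinstance(p.object, IRI):
            classes.add(p.object)
        if isinstance(p.predicate, IRI) and p.predicate != A:
            sig = ds.signatures.get(p.predicate)
            if sig is None:
                continue
            if p.subject == var and sig.subject_class is not None:
                classes.add(sig.subject_class)
            if p.object == var and sig.object_class is not None:
                classes.add(sig.object_class)
    return classes


def _var_covered(
    var: Variable,
    stage_a: PlanStage,
    stage_b: PlanStage,
    meta: FederationMetadata,
) -> bool:
    links = meta.active_links_between(stage_a.dataset, stage_b.dataset)
    if not links:
        return False
    ds_a = meta.datasets[stage_a.dataset]
    ds_b = meta.datasets[stage_b.dataset]
    classes_a = _stage_classes_of_var(stage_a, ds_a, var)
    classes_b = _stage_classes_of_var(stage_b, ds_b, var)
    for link in links:
        if link.kind == "shared-instance":
            if link.cls in classes_a and link.cls in classes_b:
                return True
        else:
            preds_a = {p.predicate for p in stage_a.bgp if p.object == var}
            preds_b = {p.predicate for p in stage_b.bgp if p.object == var}
            if (link.predicate_a in preds_a and link.predicate_b in preds_b) or (
                link.predicate_b in preds_a and link.predicate_a in preds_b
            ):
                return True
    return False


def plan(
    q: Query,
    assignment: Optional[Sequence[tuple[TriplePattern, IRI]]] = None,
    meta: Optional[FederationMetadata] = None,
) -> FederatedPlan:
    """Group assigned patterns into per-endpoint stages and order them.

    Stages are ordered by descending selectivity score (constant terms in
    the stage's patterns plus filters applicable at the stage).  Each later
    stage must share at least one virtual-link-covered variable with the
    stages before it, otherwise a "missing virtual link" error names the
    dataset pair.
    """
    if meta is None:
        raise FederationError("plan() requires federation metadata")
    if assignment is None:
        assignment = select_sources(q, meta)

    groups: dict[IRI, list[TriplePattern]] = {}
    order: list[IRI] = []
    for pattern, ds_id in assignment:
        if ds_id not in groups:
            groups[ds_id] = []
            order.append(ds_id)
        groups[ds_id].append(pattern)

    stages: list[PlanStage] = []
    for ds_id in order:
        bgp = tuple(groups[ds_id])
        stage_vars = {v for p in bgp for v in p.variables()}
        filters = tuple(f for f in q.filters if f.var in stage_vars)
        score = sum(p.constants() for p in bgp) + len(filters)
        stages.append(PlanStage(ds_id, meta.datasets[ds_id].endpoint, bgp, filters, score))
    for block in q.service_blocks:
        ds = meta.dataset_for_endpoint(block.endpoint.value)
        stage_vars = {v for p in block.bgp for v in p.variables()}
        extra = tuple(f for f in q.filters if f.var in stage_vars)
        filters = block.filters + extra
        score = sum(p.constants() for p in block.bgp) + len(filters)
        stages.append(PlanStage(ds.id, ds.endpoint, block.bgp, filters, score))

    if not stages:
        return FederatedPlan(stages=(), query=q)

    # Greedy connectivity-constrained ordering: start from the most
    # selective stage, then repeatedly take the most selective remaining
    # stage that shares a link-covered join variable with what is planned.
    remaining = sorted(stages, key=lambda s: -s.score)
    ordered: list[PlanStage] = [remaining.pop(0)]
    while remaining:
        chosen: Optional[int] = None
        chosen_shared: list[Variable] = []
        for i, stage in enumerate(remaining):
            shared: list[Variable] = []
            covered = False
            for earlier in ordered:
                common = stage.variables() & earlier.variables()
                shared.extend(v for v in common if v not in shared)
                for v in common:
                    if _var_covered(v, earlier, stage, meta):
                        covered = True
            if covered:
                chosen = i
                chosen_shared = shared
                break
        if chosen is None:
            pair = sorted(
                {s.dataset.value for s in remaining} | {e.dataset.value for e in ordered}
            )
            raise FederationError(
                "missing virtual link: no declared active link covers a join "
                f"variable between datasets {', '.join(pair)}"
            )
        stage = remaining.pop(chosen)
        ordered.append(
            replace(stage, join_vars=tuple(sorted(chosen_shared, key=lambda v: v.name)))
        )
    return FederatedPlan(stages=tuple(ordered), query=q)


# --- execution ------------------------------------------------------------


def _needed_vars(stage: PlanStage, plan_: FederatedPlan) -> tuple[Variable, ...]:
    """Variables the stage must return: final projection, filter variables
    and variables shared with any other stage."""
    stage_vars = stage.variables()
    keep = set(plan_.query.variables) & stage_vars
    keep |= {f.var for f in plan_.query.filters} & stage_vars
    for other in plan_.stages:
        if other is stage:
            continue
        keep |= stage_vars & other.variables()
    return tuple(sorted(keep, key=lambda v: v.name))


def execute(
    plan_: FederatedPlan,
    endpoints: Mapping[str, "GraphEndpoint | VirtualEndpoint"],
    batch_size: int = 50,
    intermediate_cap: Optional[int] = 10_000,
) -> SolutionSet:
    """Run a federated plan with bind joins.

    The first stage runs as-is; each later stage receives the accumulated
    bindings of its join variables as enumerated value constraints, shipped
    in batches of ``batch_size``.  Stage results are merged by natural join.
    Exceeding ``intermediate_cap`` accumulated bindings aborts with advice
    to refine the query (specific queries keep intermediate results small).
    """
    q = plan_.query
    if not plan_.stages:
        return finalize_bindings([{}], q)
    if batch_size < 1:
        raise FederationError("batch_size must be positive")

    for stage in plan_.stages:
        if stage.endpoint not in endpoints:
            raise FederationError(f"no endpoint registered under {stage.endpoint!r}")

    def answer(stage: PlanStage, sub_q: Query) -> SolutionSet:
        try:
            return endpoints[stage.endpoint].answer(sub_q)
        except EndpointUnavailable as exc:
            raise FederationError(f"endpoint {stage.endpoint!r} is down") from exc

    accumulated: list[Binding] = []
    acc_vars: set[Variable] = set()
    for idx, stage in enumerate(plan_.stages):
        needed = _needed_vars(stage, plan_)
        sub_q = Query(variables=needed, bgp=stage.bgp, filters=stage.filters)
        if idx == 0:
            accumulated = [dict(s) for s in answer(stage, sub_q)]
        else:
            join_vars = tuple(v for v in stage.join_vars if v in acc_vars)
            stage_solutions: list[Binding] = []
            if join_vars:
                tuples = sorted(
                    {tuple(b[v] for v in join_vars) for b in accumulated if all(v in b for v in join_vars)},
                    key=str,
                )
                for i in range(0, len(tuples), batch_size):
                    batch = tuples[i : i + batch_size]
                    vq = replace(sub_q, values=ValuesClause(join_vars, tuple(batch)))
                    stage_solutions.extend(dict(s) for s in answer(stage, vq))
            else:
                stage_solutions = [dict(s) for s in answer(stage, sub_q)]
            # natural join on all shared variables
            shared = tuple(sorted(acc_vars & set(needed), key=lambda v: v.name))
            index: dict[tuple, list[Binding]] = {}
            for s in stage_solutions:
                index.setdefault(tuple(s.get(v) for v in shared), []).append(s)
            merged: list[Binding] = []
            for b in accumulated:
                key = tuple(b.get(v) for v in shared)
                for s in index.get(key, ()):
                    m = dict(b)
                    m.update(s)
                    merged.append(m)
            accumulated = merged
        acc_vars |= set(needed)
        if intermediate_cap is not None and len(accumulated) > intermediate_cap:
            raise FederationError(
                f"result cap exceeded ({len(accumulated)} > {intermediate_cap}) after stage "
                f"{idx + 1}; refine the query to be more specific"
            )
        if not accumulated:
            break
    return finalize_bindings(accumulated, q)


def federated_query(
    q: Query,
    meta: FederationMetadata,
    endpoints: Mapping[str, "GraphEndpoint | VirtualEndpoint"],
    batch_size: int = 50,
    intermediate_cap: Optional[int] = 10_000,
) -> SolutionSet:
    """Plan and execute a query in one call."""
    return execute(plan(q, meta=meta), endpoints, batch_size, intermediate_cap)
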