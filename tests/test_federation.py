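"""Federation: source selection, planning, bind joins, availability."""

from __future__ import annotations

import random
from dataclasses import replace

import pytest

from genefed.evaluate import match_bgp
from genefed.federation import (
    FederationError,
    FederationMetadata,
    GraphEndpoint,
    check_availability,
    execute,
    federated_query,
    plan,
    select_sources,
)
from genefed.fixtures import (
    BGEE_DATASET,
    BGEE_ENDPOINT,
    OMA_DATASET,
    OMA_ENDPOINT,
    UNIPROT_DATASET,
    UNIPROT_ENDPOINT,
)
from genefed.ground_truth import centralized_answer
from genefed.randomized import random_linked_query
from genefed.sparql import Query, TriplePattern
from genefed.terms import IRI, Variable
from genefed.vocab import A, EXPRESSED_IN, GENE_CLASS, OBO, ORTHOLOGOUS_TO, UP, XREF_UNIPROT
from genefed.voidext import BROKEN


def _short(endpoint: str) -> str:
    return endpoint.rsplit("/", 1)[-1]


def test_single_dataset_query_yields_single_stage(fx):
    g = Variable("g")
    q = Query(variables=(g,), bgp=(TriplePattern(g, EXPRESSED_IN, OBO.UBERON_0000955),))
    p = plan(q, meta=fx.meta)
    assert len(p.stages) == 1
    assert _short(p.stages[0].endpoint) == "bgee"
    assert execute(p, fx.endpoints) == fx.endpoints[BGEE_ENDPOINT].answer(q)


def test_unanswerable_pattern_names_the_predicate(fx):
    q = Query(
        variables=(Variable("s"),),
        bgp=(TriplePattern(Variable("s"), IRI("http://example.org/unknownPred"), Variable("o")),),
    )
    with pytest.raises(FederationError, match="unanswerable pattern.*unknownPred"):
        select_sources(q, fx.meta)


def test_variable_predicate_is_rejected(fx):
    q = Query(
        variables=(Variable("s"),),
        bgp=(TriplePattern(Variable("s"), Variable("p"), Variable("o")),),
    )
    with pytest.raises(FederationError, match="variable-predicate"):
        select_sources(q, fx.meta)


def test_q12_three_way_assignment_and_disease_stage_first(fx, rendered_queries):
    """The disease-constrained protein stage carries the most constants and
    is planned first; the three stages hit three different endpoints."""
    p = plan(rendered_queries["Q12"], meta=fx.meta)
    order = [_short(s.endpoint) for s in p.stages]
    assert order == ["uniprot", "oma", "bgee"]
    assert p.stages[0].score > p.stages[1].score > p.stages[2].score


def test_plans_partition_the_bgp(fx, rendered_queries):
    for q in rendered_queries.values():
        p = plan(q, meta=fx.meta)
        planned = [pat for s in p.stages for pat in s.bgp]
        expected = list(q.bgp) + [pat for b in q.service_blocks for pat in b.bgp]
        assert sorted(map(str, planned)) == sorted(map(str, expected))


def test_missing_virtual_link_rejects_unjoinable_stages(fx):
    g, p_, v = Variable("g"), Variable("p"), Variable("v")
    # two stages sharing no variable at all
    q = Query(
        variables=(g, p_),
        bgp=(
            TriplePattern(g, EXPRESSED_IN, OBO.UBERON_0000955),
            TriplePattern(p_, UP.existence, v),
        ),
    )
    with pytest.raises(FederationError, match="missing virtual link"):
        plan(q, meta=fx.meta)


def test_removing_a_link_turns_plannable_into_missing_link_error(fx):
    g, h = Variable("g"), Variable("h")
    q = Query(
        variables=(g, h),
        bgp=(
            TriplePattern(g, EXPRESSED_IN, OBO.UBERON_0000955),
            TriplePattern(g, ORTHOLOGOUS_TO, h),
        ),
    )
    assert len(plan(q, meta=fx.meta).stages) == 2
    no_gene_link = FederationMetadata(
        datasets=fx.meta.datasets,
        links=[l for l in fx.meta.links if l.cls != GENE_CLASS],
    )
    with pytest.raises(FederationError, match="missing virtual link"):
        plan(q, meta=no_gene_link)
    # a broken link behaves like an absent one
    broken = FederationMetadata(
        datasets=fx.meta.datasets,
        links=[replace(l, status=BROKEN) if l.cls == GENE_CLASS else l for l in fx.meta.links],
    )
    with pytest.raises(FederationError, match="missing virtual link"):
        plan(q, meta=broken)


def test_federated_equals_centralized_on_random_linked_queries(fx, union_graph):
    """40 randomized 2-/3-dataset queries here (acceptance runs >= 100)."""
    rng = random.Random(23)
    anats = sorted({t.object for t in fx.bgee_graph if t.predicate == EXPRESSED_IN}, key=str)
    taxa = sorted({t.object for t in fx.orth_graph if t.predicate.value.endswith("RO_0002162")}, key=str)
    for _ in range(40):
        q = random_linked_query(rng, anats, taxa)
        fed = federated_query(q, fx.meta, fx.endpoints)
        assert fed == centralized_answer(union_graph, q)


def test_bind_join_batch_size_does_not_change_results(fx, rendered_queries, ground_truth):
    q = rendered_queries["Q10"]
    p = plan(q, meta=fx.meta)
    results = [execute(p, fx.endpoints, batch_size=b) for b in (1, 10, 100)]
    assert results[0] == results[1] == results[2] == ground_truth["Q10"]


def test_intermediate_result_cap_aborts_with_advice(fx, rendered_queries):
    p = plan(rendered_queries["Q10"], meta=fx.meta)
    with pytest.raises(FederationError, match="result cap exceeded"):
        execute(p, fx.endpoints, intermediate_cap=2)


def test_endpoint_down_mid_execution_names_the_endpoint(fx, rendered_queries):
    endpoints = dict(fx.endpoints)
    endpoints[UNIPROT_ENDPOINT] = GraphEndpoint(
        UNIPROT_ENDPOINT, fx.protein_graph, available=False
    )
    p = plan(rendered_queries["Q12"], meta=fx.meta)
    with pytest.raises(FederationError, match="uniprot.*down"):
        execute(p, endpoints)


def test_check_availability(fx):
    report = check_availability(fx.endpoints)
    assert set(report.values()) == {"up"}
    down = dict(fx.endpoints)
    down[OMA_ENDPOINT] = GraphEndpoint(OMA_ENDPOINT, fx.orth_graph, available=False)
    report = check_availability(down)
    assert report[OMA_ENDPOINT] == "down" and report[BGEE_ENDPOINT] == "up"
    assert check_availability({}) == {}
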