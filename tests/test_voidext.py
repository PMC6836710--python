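"""Virtual-link metadata: discovery, round-trip serialization, validation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from genefed.federation import GraphEndpoint
from genefed.fixtures import BGEE_DATASET, OMA_DATASET, UNIPROT_DATASET
from genefed.terms import Graph, IRI, Literal, Triple
from genefed.vocab import A, GENE_CLASS, LABEL, PROTEIN_CLASS, TAXON_CLASS
from genefed.voidext import (
    ACTIVE,
    BROKEN,
    UNVERIFIED,
    DatasetDescription,
    VirtualLinkSet,
    VoidextError,
    discover_links,
    parse_voidext,
    serialize_voidext,
    validate_links,
)

DS_A = IRI("http://e.org/ds/a")
DS_B = IRI("http://e.org/ds/b")


def test_disjoint_graphs_discover_nothing():
    g1 = Graph([Triple(IRI("http://e.org/x"), A, IRI("http://e.org/C1"))])
    g2 = Graph([Triple(IRI("http://e.org/y"), A, IRI("http://e.org/C2"))])
    assert discover_links(g1, g2, DS_A, DS_B) == []


def test_fixture_discovery_finds_the_expected_links(fx):
    """Gene instances link expression<->orthology; taxon instances link
    expression<->protein; protein instances link orthology<->protein."""
    links = fx.meta.links
    kinds = {(l.dataset_a, l.dataset_b, l.kind, l.cls) for l in links}
    assert (BGEE_DATASET, OMA_DATASET, "shared-instance", GENE_CLASS) in kinds
    assert (BGEE_DATASET, UNIPROT_DATASET, "shared-instance", TAXON_CLASS) in kinds
    assert (OMA_DATASET, UNIPROT_DATASET, "shared-instance", PROTEIN_CLASS) in kinds
    gene_link = next(l for l in links if l.cls == GENE_CLASS and l.dataset_b == OMA_DATASET)
    n_genes = fx.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
    assert gene_link.cardinality == n_genes
    taxon_link = next(
        l for l in links if l.cls == TAXON_CLASS and l.dataset_b == UNIPROT_DATASET
    )
    assert taxon_link.cardinality == fx.spec.n_species


def test_discovery_is_symmetric_up_to_slot_swap(fx):
    fwd = discover_links(fx.bgee_graph, fx.orth_graph, DS_A, DS_B)
    rev = discover_links(fx.orth_graph, fx.bgee_graph, DS_B, DS_A)
    fwd_keys = {(l.kind, l.cls, l.cardinality) for l in fwd if l.kind == "shared-instance"}
    rev_keys = {(l.kind, l.cls, l.cardinality) for l in rev if l.kind == "shared-instance"}
    assert fwd_keys == rev_keys


_classes = st.sampled_from([IRI(f"http://e.org/C{i}") for i in range(4)])
_preds = st.sampled_from([IRI(f"http://e.org/p{i}") for i in range(4)])


@st.composite
def _link_lists(draw):
    n = draw(st.integers(0, 5))
    links = []
    for i in range(n):
        if draw(st.booleans()):
            links.append(
                VirtualLinkSet(
                    id=IRI(f"http://e.org/link{i}"),
                    dataset_a=DS_A,
                    dataset_b=DS_B,
                    kind="shared-instance",
                    cls=draw(_classes),
                    cardinality=draw(st.integers(0, 100)),
                    status=draw(st.sampled_from([ACTIVE, BROKEN, UNVERIFIED])),
                )
            )
        else:
            links.append(
                VirtualLinkSet(
                    id=IRI(f"http://e.org/link{i}"),
                    dataset_a=DS_A,
                    dataset_b=DS_B,
                    kind="literal-match",
                    predicate_a=draw(_preds),
                    predicate_b=draw(_preds),
                    transformation=draw(st.sampled_from([None, "uberon"])),
                    cardinality=draw(st.integers(0, 100)),
                )
            )
    return links


@settings(max_examples=60, derandomize=True)
@given(_link_lists())
def test_voidext_round_trip_identity(links):
    datasets = [
        DatasetDescription(DS_A, "http://e.org/sparql/a", frozenset({IRI("http://e.org/C0")}), frozenset()),
        DatasetDescription(DS_B, "http://e.org/sparql/b", frozenset(), frozenset({IRI("http://e.org/p0")})),
    ]
    g = serialize_voidext(links, datasets)
    ds2, links2 = parse_voidext(g)
    assert sorted(ds2, key=lambda d: d.id.value) == sorted(datasets, key=lambda d: d.id.value)
    assert sorted(links2, key=lambda l: l.id.value) == sorted(links, key=lambda l: l.id.value)


def test_voidext_round_trip_on_fixture_metadata(fx):
    g = serialize_voidext(fx.meta.links, fx.meta.datasets.values())
    ds, links = parse_voidext(g)
    assert sorted(links, key=lambda l: l.id.value) == sorted(fx.meta.links, key=lambda l: l.id.value)
    assert sorted(ds, key=lambda d: d.id.value) == sorted(fx.meta.datasets.values(), key=lambda d: d.id.value)


def test_serialize_rejects_dangling_dataset_reference():
    link = VirtualLinkSet(
        id=IRI("http://e.org/l"), dataset_a=DS_A, dataset_b=DS_B,
        kind="shared-instance", cls=IRI("http://e.org/C0"),
    )
    with pytest.raises(VoidextError, match="unregistered"):
        serialize_voidext([link], [])


def test_parse_rejects_kindless_links():
    link = VirtualLinkSet(
        id=IRI("http://e.org/l"), dataset_a=DS_A, dataset_b=DS_B,
        kind="shared-instance", cls=IRI("http://e.org/C0"),
    )
    datasets = [
        DatasetDescription(DS_A, "a", frozenset({IRI("http://e.org/C0")}), frozenset()),
        DatasetDescription(DS_B, "b", frozenset({IRI("http://e.org/C0")}), frozenset()),
    ]
    g = serialize_voidext([link], datasets)
    from genefed.vocab import VOIDEXT

    stripped = Graph(t for t in g if t.predicate != VOIDEXT.kind)
    with pytest.raises(VoidextError, match="kind"):
        parse_voidext(stripped)


def test_invariants_of_link_construction():
    with pytest.raises(VoidextError):
        VirtualLinkSet(IRI("http://e.org/l"), DS_A, DS_A, "shared-instance", cls=_c())
    with pytest.raises(VoidextError):
        VirtualLinkSet(IRI("http://e.org/l"), DS_A, DS_B, "shared-instance")
    with pytest.raises(VoidextError):
        VirtualLinkSet(IRI("http://e.org/l"), DS_A, DS_B, "literal-match", predicate_a=_p())


def _c() -> IRI:
    return IRI("http://e.org/C0")


def _p() -> IRI:
    return IRI("http://e.org/p0")


def _endpoints_by_dataset(fx):
    return {ds_id: fx.endpoints[ds.endpoint] for ds_id, ds in fx.meta.datasets.items()}


def test_validation_on_unperturbed_fixtures_keeps_cardinalities(fx):
    refreshed, reports = validate_links(fx.meta.links, _endpoints_by_dataset(fx), fx.meta.datasets)
    assert all(r.status == ACTIVE for r in reports)
    assert all(r.cardinality_after == r.cardinality_before for r in reports)


def test_rewritten_gene_iris_break_the_gene_link(fx):
    rewritten = Graph(
        Triple(
            _rebase(t.subject), t.predicate, _rebase(t.object)
        )
        for t in fx.orth_graph
    )
    endpoints = dict(_endpoints_by_dataset(fx))
    endpoints[OMA_DATASET] = GraphEndpoint("oma-rewritten", rewritten)
    refreshed, reports = validate_links(fx.meta.links, endpoints, fx.meta.datasets)
    by_key = {(r.link.cls, r.link.datasets()): r for r in reports if r.link.kind == "shared-instance"}
    gene_report = by_key[(GENE_CLASS, frozenset((BGEE_DATASET, OMA_DATASET)))]
    assert gene_report.status == BROKEN and gene_report.cardinality_after == 0
    taxon_report = by_key[(TAXON_CLASS, frozenset((BGEE_DATASET, UNIPROT_DATASET)))]
    assert taxon_report.status == ACTIVE


def test_offline_endpoint_marks_links_unverified(fx):
    endpoints = dict(_endpoints_by_dataset(fx))
    down = GraphEndpoint("down", fx.orth_graph, available=False)
    endpoints[OMA_DATASET] = down
    _refreshed, reports = validate_links(fx.meta.links, endpoints, fx.meta.datasets)
    for r in reports:
        if OMA_DATASET in r.link.datasets():
            assert r.status == UNVERIFIED
        else:
            assert r.status == ACTIVE


def _rebase(term):
    if isinstance(term, IRI) and term.value.startswith("http://example.org/genefed/gene/"):
        return IRI(term.value.replace("/genefed/gene/", "/elsewhere/gene/"))
    return term
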