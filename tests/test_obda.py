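"""OBDA engine: mapping rules, transformations, materialization and
virtual answering (oracle equivalence)."""

from __future__ import annotations

import random
import sqlite3

import pytest

from genefed.evaluate import match_bgp
from genefed.mappings import MappingError, expand_rule, load_mappings
from genefed.obda import VirtualGraph
from genefed.randomized import random_bgp
from genefed.sparql import Query, TriplePattern
from genefed.terms import IRI, Literal, Variable
from genefed.transforms import (
    TransformError,
    transform_scientific_name,
    transform_uberon,
    underscore_to_curie,
)
from genefed.io import serialize_graph
from genefed.vocab import EXPRESSED_IN, GENE_CLASS, OBO, A


def test_transform_uberon_colon_to_underscore():
    assert transform_uberon("UBERON:0000955").value.endswith("UBERON_0000955")
    assert transform_uberon("UBERON:0002107").value.endswith("UBERON_0002107")
    with pytest.raises(TransformError):
        transform_uberon("0000955")


def test_transform_uberon_inverse_is_identity():
    for curie in ("UBERON:0000955", "DEV:0000002", "GO:0005179"):
        iri = transform_uberon(curie)
        local = iri.value.rsplit("/", 1)[1]
        assert underscore_to_curie(local) == curie


def test_transform_scientific_name_concatenates():
    assert transform_scientific_name("Homo", "sapiens") == Literal("Homo sapiens")
    assert transform_scientific_name("Rattus", "norvegicus") == Literal("Rattus norvegicus")
    with pytest.raises(TransformError):
        transform_scientific_name("", "sapiens")


def test_load_mappings_empty_and_errors(fx):
    assert load_mappings("") == []
    bad = """
mappingId broken
source    SELECT geneName FROM gene
target    <http://example.org/genefed/gene/{geneId}> a orth:Gene .
"""
    with pytest.raises(MappingError, match="broken"):
        load_mappings(bad, fx.conn)
    dup = """
mappingId same
source    SELECT geneId FROM gene
target    <http://example.org/genefed/gene/{geneId}> a orth:Gene .

mappingId same
source    SELECT geneId FROM gene
target    <http://example.org/genefed/gene/{geneId}> a orth:Gene .
"""
    with pytest.raises(MappingError, match="duplicate"):
        load_mappings(dup, fx.conn)


def test_shipped_mapping_file_covers_expression_vocabulary(fx):
    rules = load_mappings(fx.mapping_doc, fx.conn)
    ids = {r.id for r in rules}
    assert {"gene-class", "gene-label", "gene-taxon", "taxon", "anat-entity",
            "expressed-in", "absent-in", "highly-expressed-in"} <= ids


def test_expand_rule_null_skips_and_missing_column_errors(fx):
    rules = {r.id: r for r in load_mappings(fx.mapping_doc, fx.conn)}
    label_rule = rules["gene-label"]
    triples = expand_rule(label_rule, {"geneId": "X1", "geneName": "INS"})
    assert len(triples) == 1 and triples[0].object == Literal("INS")
    assert expand_rule(label_rule, {"geneId": "X1", "geneName": None}) == []
    with pytest.raises(MappingError, match="geneName"):
        expand_rule(label_rule, {"geneId": "X1"})


def test_expand_applies_uberon_transform(fx):
    rules = {r.id: r for r in load_mappings(fx.mapping_doc, fx.conn)}
    triples = expand_rule(rules["anat-entity"], {"anatEntityId": "UBERON:0000955", "name": "brain"})
    assert any(t.subject.value.endswith("UBERON_0000955") for t in triples)


def test_materialize_empty_database():
    conn = sqlite3.connect(":memory:")
    conn.execute("CREATE TABLE gene (geneId TEXT, geneName TEXT, speciesId INTEGER)")
    doc = """
mappingId gene-class
source    SELECT geneId FROM gene
target    <http://example.org/genefed/gene/{geneId}> a orth:Gene .
"""
    vg = VirtualGraph.from_mapping_document(conn, doc)
    assert len(vg.materialize()) == 0


def test_materialize_counts_and_determinism(fx):
    g = fx.virtual.materialize()
    n_genes = fx.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
    gene_memberships = [t for t in g if t.predicate == A and t.object == GENE_CLASS]
    assert len(gene_memberships) == n_genes
    assert serialize_graph(g) == serialize_graph(fx.virtual.materialize())


def test_virtual_answer_matches_oracle_on_targeted_patterns(fx):
    g = Variable("g")
    typed = Query(variables=(g,), bgp=(TriplePattern(g, A, GENE_CLASS),))
    assert fx.virtual.answer_bgp_virtual(typed) == match_bgp(fx.bgee_graph, typed)
    # a predicate no template produces
    missing = Query(
        variables=(g,),
        bgp=(TriplePattern(g, IRI("http://example.org/none"), Variable("o")),),
    )
    assert len(fx.virtual.answer_bgp_virtual(missing)) == 0
    # expression lookup with a transformed constant (liver)
    liver = Query(variables=(g,), bgp=(TriplePattern(g, EXPRESSED_IN, OBO.UBERON_0002107),))
    assert fx.virtual.answer_bgp_virtual(liver) == match_bgp(fx.bgee_graph, liver)
    assert len(fx.virtual.answer_bgp_virtual(liver)) > 0


def test_virtual_equals_materialize_then_match_on_random_bgps(fx):
    """Oracle equivalence on 60 random BGPs (the acceptance run uses 200)."""
    rng = random.Random(11)
    for _ in range(60):
        q = random_bgp(rng, fx.bgee_graph)
        assert fx.virtual.answer_bgp_virtual(q) == match_bgp(fx.bgee_graph, q)
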