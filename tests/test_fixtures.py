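"""Synthetic-data generator: schema rules, coverage contracts,
reproducibility and the hand-written worked example."""

from __future__ import annotations

import pytest

from genefed.fixtures import (
    FixtureError,
    FixtureSpec,
    build_expression_db,
    build_fixtures,
    build_hogs_and_proteins,
    dump_database,
    gene_iri,
    worked_example,
)
from genefed.io import serialize_graph
from genefed.orthology import leaves
from genefed.terms import IRI, Literal
from genefed.vocab import A, ENCODED_BY, GENE_CLASS, PROTEIN_CLASS, SCIENTIFIC_NAME, TAXON_CLASS


def test_spec_validation():
    with pytest.raises(FixtureError):
        FixtureSpec(p_expressed=0.9, p_absent=0.3).validate()
    with pytest.raises(FixtureError):
        FixtureSpec(p_high=0.5, p_expressed=0.3).validate()
    with pytest.raises(FixtureError):
        FixtureSpec(n_species=99).validate()
    FixtureSpec().validate()


def test_zero_genes_gives_empty_gene_table():
    conn = build_expression_db(FixtureSpec(n_genes_per_species=0))
    assert conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0] == 0


def test_row_counts_follow_spec_arithmetic(fx):
    spec = fx.spec
    n_species = fx.conn.execute("SELECT COUNT(*) FROM species").fetchone()[0]
    n_genes = fx.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
    assert n_species == spec.n_species
    assert n_genes == spec.n_species * spec.n_genes_per_species
    assert fx.conn.execute("SELECT COUNT(*) FROM anatEntity").fetchone()[0] == spec.n_anat_entities
    assert fx.conn.execute("SELECT COUNT(*) FROM stage").fetchone()[0] == spec.n_stages


def test_absent_calls_have_null_level(fx):
    rows = fx.conn.execute(
        "SELECT COUNT(*) FROM expression WHERE callType='absent' AND level IS NOT NULL"
    ).fetchone()[0]
    assert rows == 0
    assert fx.conn.execute("SELECT COUNT(*) FROM expression WHERE callType='absent'").fetchone()[0] > 0


def test_orthology_store_covers_every_database_gene(fx):
    db_genes = {gene_iri(r[0]) for r in fx.conn.execute("SELECT geneId FROM gene")}
    hog_genes = {l.gene for h in fx.hogs for l in leaves(h)}
    assert db_genes == hog_genes


def test_protein_store_covers_only_a_subset(fx):
    """Coverage asymmetry: some orthology genes lack a protein node."""
    hog_genes = {l.gene for h in fx.hogs for l in leaves(h)}
    protein_genes = {t.object for t in fx.protein_graph if t.predicate == ENCODED_BY}
    assert protein_genes < hog_genes


def test_taxon_iris_and_scientific_names_are_shared_verbatim(fx):
    """The literal-level and instance-level join contracts: taxon IRIs and
    genus+species literals coincide byte-for-byte across stores."""
    bgee_taxa = {t.subject for t in fx.bgee_graph if t.predicate == A and t.object == TAXON_CLASS}
    up_taxa = {t.subject for t in fx.protein_graph if t.predicate == A and t.object == TAXON_CLASS}
    assert bgee_taxa == up_taxa and len(bgee_taxa) == fx.spec.n_species
    bgee_names = {t.object for t in fx.bgee_graph if t.predicate == SCIENTIFIC_NAME}
    up_names = {t.object for t in fx.protein_graph if t.predicate == SCIENTIFIC_NAME}
    assert bgee_names == up_names
    assert Literal("Homo sapiens") in bgee_names


def test_no_disease_annotations_when_probability_zero():
    spec = FixtureSpec(p_disease_annotated=0.0)
    conn = build_expression_db(spec)
    _hogs, g = build_hogs_and_proteins(spec, conn)
    from genefed.vocab import DISEASE_ANNOTATION_CLASS

    planted = {"9606_EGFR", "9606_APP"}  # planted disease genes keep theirs
    disease_nodes = {t.subject for t in g if t.predicate == A and t.object == DISEASE_ANNOTATION_CLASS}
    assert len(disease_nodes) == len(planted)


def test_identical_seed_gives_byte_identical_outputs():
    a, b = build_fixtures(FixtureSpec(seed=7)), build_fixtures(FixtureSpec(seed=7))
    assert dump_database(a.conn) == dump_database(b.conn)
    assert serialize_graph(a.bgee_graph) == serialize_graph(b.bgee_graph)
    assert serialize_graph(a.orth_graph) == serialize_graph(b.orth_graph)
    assert serialize_graph(a.protein_graph) == serialize_graph(b.protein_graph)


def test_different_seed_changes_the_random_fraction():
    a, b = build_fixtures(FixtureSpec(seed=1)), build_fixtures(FixtureSpec(seed=2))
    assert dump_database(a.conn) != dump_database(b.conn)


def test_worked_example_construction(we):
    """<=30 genes; 3 glioblastoma-annotated human genes, 2 with rat
    orthologs, 1 of those expressed in rat brain."""
    n_genes = we.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
    assert n_genes <= 30
    from genefed.vocab import COMMENT, DISEASE_ANNOTATION_CLASS, UP_ANNOTATION

    disease_nodes = {
        t.subject for t in we.protein_graph
        if t.predicate == A and t.object == DISEASE_ANNOTATION_CLASS
    }
    assert len(disease_nodes) == 3
    rat_brain = we.conn.execute(
        "SELECT geneId FROM expression JOIN gene USING (geneId) "
        "WHERE anatEntityId='UBERON:0000955' AND callType='present' AND speciesId=10116"
    ).fetchall()
    assert rat_brain == [("10116_Egfr",)]
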