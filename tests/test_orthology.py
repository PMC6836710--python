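"""HOG pairwise derivation (vs a brute-force LCA oracle), clade
restriction, graph emission and the serialization formats."""

from __future__ import annotations

import random

import pytest

from genefed.orthology import (
    DUPLICATION,
    HOG,
    HOGError,
    HOGLeaf,
    HOGNode,
    PairwiseRelation,
    SPECIATION,
    derive_pairwise,
    dump_hogs,
    emit_orth_graph,
    leaves,
    load_hogs,
    load_orthoxml,
    restrict_to_clade,
)
from genefed.randomized import random_hog
from genefed.terms import IRI, Triple
from genefed.vocab import A, GENE_CLASS, ORTHOLOGOUS_TO, PARALOGOUS_TO, TAXON


def _leaf(n: int, taxon: str = "9606") -> HOGLeaf:
    return HOGLeaf(IRI(f"http://e.org/g{n}"), TAXON(taxon), label=f"g{n}")


def lca_oracle(h: HOG) -> set[PairwiseRelation]:
    """Independent oracle: find each pair's LCA by explicit root paths."""
    paths: dict[IRI, list[HOG]] = {}

    def walk(node: HOG, path: list[HOG]) -> None:
        here = path + [node]
        if isinstance(node, HOGLeaf):
            paths[node.gene] = here
            return
        for child in node.children:
            walk(child, here)

    walk(h, [])
    genes = sorted(paths, key=lambda g: g.value)
    out: set[PairwiseRelation] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            lca = None
            for x, y in zip(paths[a], paths[b]):
                if x is y:
                    lca = x
                else:
                    break
            assert isinstance(lca, HOGNode)
            rel = "ortholog" if lca.event == SPECIATION else "paralog"
            out.add(PairwiseRelation(a, b, rel))
    return out


def test_two_leaves_under_speciation_is_one_ortholog_pair():
    h = HOGNode(SPECIATION, (_leaf(1, "9606"), _leaf(2, "10090")))
    assert derive_pairwise(h) == {PairwiseRelation(_leaf(1).gene, _leaf(2).gene, "ortholog")}


def test_duplication_over_two_speciation_subtrees():
    """Cross-subtree pairs are paralogs (4), within-subtree orthologs (2)."""
    h = HOGNode(
        DUPLICATION,
        (
            HOGNode(SPECIATION, (_leaf(1, "9606"), _leaf(2, "10090"))),
            HOGNode(SPECIATION, (_leaf(3, "9606"), _leaf(4, "10090"))),
        ),
    )
    rels = derive_pairwise(h)
    assert len(rels) == 6
    assert sum(1 for r in rels if r.relation == "paralog") == 4
    assert sum(1 for r in rels if r.relation == "ortholog") == 2
    assert rels == lca_oracle(h)


def test_single_leaf_yields_no_pairs():
    assert derive_pairwise(_leaf(1)) == set()


def test_duplicate_gene_across_leaves_is_an_error():
    h = HOGNode(SPECIATION, (_leaf(1), _leaf(1)))
    with pytest.raises(HOGError, match="more than one leaf"):
        derive_pairwise(h)


def test_pairwise_agrees_with_lca_oracle_on_random_hogs():
    """100 random topologies (<= 12 leaves): same relations, and every pair
    classified exactly once (ortholog xor paralog)."""
    rng = random.Random(5)
    for _ in range(100):
        h = random_hog(rng)
        rels = derive_pairwise(h)
        assert rels == lca_oracle(h)
        n = len(leaves(h))
        assert len(rels) == n * (n - 1) // 2
        assert len({r.genes for r in rels}) == len(rels)


def test_relation_symmetry_is_normalized():
    a, b = IRI("http://e.org/b"), IRI("http://e.org/a")
    assert PairwiseRelation(a, b, "ortholog") == PairwiseRelation(b, a, "ortholog")
    with pytest.raises(HOGError):
        PairwiseRelation(a, a, "ortholog")


def test_restrict_to_clade():
    h = HOGNode(SPECIATION, (_leaf(1, "9606"), _leaf(2, "10090"), _leaf(3, "7227")))
    rels = derive_pairwise(h)
    taxon_of = {l.gene: l.taxon for l in leaves(h)}
    assert restrict_to_clade(rels, [], taxon_of) == set()
    assert restrict_to_clade(rels, set(taxon_of.values()), taxon_of) == rels
    primate_only = restrict_to_clade(rels, {TAXON("9606")}, taxon_of)
    assert primate_only == {r for r in rels if any(taxon_of[g] == TAXON("9606") for g in r.genes)}
    with pytest.raises(HOGError, match="unknown taxon"):
        restrict_to_clade(rels, {TAXON("9606")}, {})


def test_emit_orth_graph_counts_and_symmetry(fx):
    g = fx.orth_graph
    n_genes = fx.conn.execute("SELECT COUNT(*) FROM gene").fetchone()[0]
    assert sum(1 for t in g if t.predicate == A and t.object == GENE_CLASS) == n_genes
    for pred in (ORTHOLOGOUS_TO, PARALOGOUS_TO):
        asserted = {(t.subject, t.object) for t in g if t.predicate == pred}
        assert asserted == {(o, s) for s, o in asserted}
    assert len(emit_orth_graph([])) == 0


def test_hog_json_round_trip(fx):
    text = dump_hogs(fx.hogs)
    again = load_hogs(text)
    assert dump_hogs(again) == text
    assert [derive_pairwise(h) for h in again] == [derive_pairwise(h) for h in fx.hogs]


def test_orthoxml_subset_reader():
    doc = """<?xml version="1.0"?>
<orthoXML xmlns="http://orthoXML.org/2011/" version="0.3">
  <species name="Homo sapiens" NCBITaxId="9606">
    <database name="db" version="1"><genes>
      <gene id="1" geneId="HS1" protId="P1"/>
      <gene id="2" geneId="HS2"/>
    </genes></database>
  </species>
  <species name="Mus musculus" NCBITaxId="10090">
    <database name="db" version="1"><genes>
      <gene id="3" geneId="MM1" protId="P3"/>
    </genes></database>
  </species>
  <groups>
    <orthologGroup id="h1">
      <geneRef id="3"/>
      <paralogGroup><geneRef id="1"/><geneRef id="2"/></paralogGroup>
    </orthologGroup>
  </groups>
</orthoXML>
"""
    hogs = load_orthoxml(doc)
    assert len(hogs) == 1
    rels = derive_pairwise(hogs[0])
    by_kind = {r.relation for r in rels}
    assert by_kind == {"ortholog", "paralog"}
    assert len(rels) == 3
    ls = leaves(hogs[0])
    assert {l.taxon for l in ls} == {TAXON("9606"), TAXON("10090")}
    assert sum(1 for l in ls if l.protein is not None) == 2
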