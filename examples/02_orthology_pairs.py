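"""Derive pairwise ortholog/paralog relations from a hierarchical group.

A HOG is a tree of speciation/duplication events over gene leaves: a leaf
pair is orthologous iff its lowest common ancestor is a speciation event.
The derived relations are emitted as a small RDF graph, the shape the
orthology endpoint serves in the federation.
"""

from genefed.io import serialize_graph
from genefed.orthology import (
    DUPLICATION,
    HOGLeaf,
    HOGNode,
    SPECIATION,
    derive_pairwise,
    emit_orth_graph,
)
from genefed.terms import IRI
from genefed.vocab import TAXON

human, rat = TAXON("9606"), TAXON("10116")
leaf = lambda name, taxon: HOGLeaf(IRI(f"http://example.org/genefed/gene/{name}"), taxon, name)

# One duplication inside the rat lineage under a speciation root:
hog = HOGNode(
    SPECIATION,
    (
        leaf("TP53", human),
        HOGNode(DUPLICATION, (leaf("Tp53", rat), leaf("Tp53b", rat))),
    ),
)

for rel in sorted(derive_pairwise(hog), key=lambda r: (r.relation, r.geneA.value)):
    a = rel.geneA.value.rsplit("/", 1)[1]
    b = rel.geneB.value.rsplit("/", 1)[1]
    print(f"{a:8s} -- {rel.relation:8s} -- {b}")
# The two rat copies are paralogs (they split by duplication); each is
# orthologous to the human gene (that split was the speciation).

graph = emit_orth_graph([hog])
print(f"\nemitted orthology graph: {len(graph)} triples; excerpt:")
print("\n".join(serialize_graph(graph).splitlines()[:4]))
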