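"""Seeded generators of randomized check inputs.

Used by the test suite and the acceptance script to stress the equivalence
contracts: random BGPs against the expression store, random link-covered
federated queries against the three stores, and random HOG topologies for
pairwise-relation derivation.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

from .orthology import DUPLICATION, HOG, HOGLeaf, HOGNode, SPECIATION
from .sparql import Query, TriplePattern
from .terms import Graph, IRI, Variable
from .vocab import (
    A,
    ABSENT_IN,
    EXPRESSED_IN,
    GENE_CLASS,
    HIGHLY_EXPRESSED_IN,
    IN_TAXON,
    ORTHOLOGOUS_TO,
    PARALOGOUS_TO,
    PROTEIN_CLASS,
    TAXON,
    UP,
    UP_ANNOTATION,
    XREF_UNIPROT,
)


def random_bgp(rng: random.Random, g: Graph, max_patterns: int = 3) -> Query:
    """A random 1..max_patterns BGP seeded from actual graph triples.

    Slots are randomly generalized to (occasionally shared) variables, so
    queries mix constants that match, joins, and the occasional miss.
    """
    triples = sorted(
        g, key=lambda t: (str(t.subject), t.predicate.value, str(t.object))
    )
    varpool = [Variable(n) for n in ("a", "b", "c", "d")]
    patterns = []
    for _ in range(rng.randint(1, max_patterns)):
        t = rng.choice(triples)
        s = t.subject if rng.random() < 0.5 else rng.choice(varpool)
        p = t.predicate if rng.random() < 0.8 else rng.choice(varpool)
        o = t.object if rng.random() < 0.5 else rng.choice(varpool)
        patterns.append(TriplePattern(s, p, o))
    variables = tuple({v for pat in patterns for v in pat.variables()})
    if not variables:
        # all-constant patterns carry no projection; re-draw with a variable
        return random_bgp(rng, g, max_patterns)
    return Query(variables=variables, bgp=tuple(patterns))


def random_linked_query(
    rng: random.Random,
    anat_iris: Sequence[IRI],
    taxon_iris: Sequence[IRI],
) -> Query:
    """A random 2- or 3-dataset conjunctive query joined on declared links.

    Shapes follow the catalogue's join topology: expression-to-orthology
    joins ride the shared gene instances, orthology-to-protein joins ride
    the shared protein instances.  Patterns stick to predicates served by a
    single store (or to triples replicated identically across stores), so
    federated and centralized answers must coincide.
    """
    gene, other, protein, ann = (
        Variable("g"), Variable("h"), Variable("p"), Variable("ann"),
    )
    expr_pred = rng.choice((EXPRESSED_IN, ABSENT_IN, HIGHLY_EXPRESSED_IN))
    expr_obj = rng.choice(list(anat_iris) + [Variable("anat")])
    bgee_patterns = [TriplePattern(gene, expr_pred, expr_obj)]
    if rng.random() < 0.5:
        bgee_patterns.append(TriplePattern(gene, A, GENE_CLASS))

    orth_pred = rng.choice((ORTHOLOGOUS_TO, PARALOGOUS_TO))
    oma_patterns = [TriplePattern(gene, orth_pred, other)]
    if rng.random() < 0.5:
        oma_patterns.append(TriplePattern(other, IN_TAXON, rng.choice(list(taxon_iris))))

    shape = rng.choice(("bgee-oma", "oma-uniprot", "three"))
    if shape == "bgee-oma":
        patterns = bgee_patterns + oma_patterns
    elif shape == "oma-uniprot":
        patterns = oma_patterns + [
            TriplePattern(other, XREF_UNIPROT, protein),
            TriplePattern(protein, rng.choice((UP.existence, UP.mnemonic)), Variable("v")),
        ]
    else:
        patterns = bgee_patterns + oma_patterns + [
            TriplePattern(other, XREF_UNIPROT, protein),
            TriplePattern(protein, UP_ANNOTATION, ann),
        ]
    variables = tuple(sorted({v for p in patterns for v in p.variables()}, key=lambda v: v.name))
    return Query(variables=variables, bgp=tuple(patterns), distinct=rng.random() < 0.3)


def random_hog(
    rng: random.Random,
    max_leaves: int = 12,
    n_taxa: int = 5,
    _counter: Optional[list[int]] = None,
) -> HOG:
    """A random HOG topology with unique genes over a small taxon pool."""
    n_leaves = rng.randint(1, max_leaves)
    counter = [0]
    taxa = [TAXON(str(1000 + i)) for i in range(n_taxa)]

    def make_leaf() -> HOGLeaf:
        counter[0] += 1
        return HOGLeaf(
            gene=IRI(f"http://example.org/genefed/gene/RND{counter[0]}"),
            taxon=rng.choice(taxa),
            label=f"RND{counter[0]}",
        )

    def build(leaves_left: int) -> HOG:
        if leaves_left == 1:
            return make_leaf()
        split = rng.randint(1, leaves_left - 1)
        children = (build(split), build(leaves_left - split))
        event = SPECIATION if rng.random() < 0.6 else DUPLICATION
        return HOGNode(event, children)

    return build(n_leaves)
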