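"""Hierarchical orthologous groups (HOGs) and pairwise homology relations.

A HOG is a tree whose internal nodes are labelled with the evolutionary
event that created the split — speciation (optionally carrying the ancestral
taxon) or duplication — and whose leaves are extant genes.  Two genes in the
same HOG are orthologs iff their lowest common ancestor is a speciation
node, paralogs iff it is a duplication node; deriving all pairwise relations
therefore classifies every leaf pair exactly once.

The module also emits the ORTH-style RDF graph that plays the orthology
store's role in the federation: gene class membership, labels, taxon links
(shared taxon instance IRIs), protein cross-references and symmetric
ortholog/paralog property assertions.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .terms import Graph, IRI, Literal, Triple
from .vocab import (
    A,
    GENE,
    GENE_CLASS,
    IN_CLADE,
    IN_TAXON,
    LABEL,
    ORTHOLOGOUS_TO,
    PARALOGOUS_TO,
    PROTEIN,
    PROTEIN_CLASS,
    TAXON,
    TAXON_CLASS,
    XREF_UNIPROT,
)

SPECIATION = "speciation"
DUPLICATION = "duplication"


class HOGError(ValueError):
    """Structurally invalid HOG."""


@dataclass(frozen=True)
class HOGLeaf:
    """An extant gene: IRI, taxon, display label, optional protein xref."""

    gene: IRI
    taxon: IRI
    label: Optional[str] = None
    protein: Optional[IRI] = None


@dataclass(frozen=True)
class HOGNode:
    event: str  # SPECIATION or DUPLICATION
    children: tuple["HOG", ...]
    taxon: Optional[IRI] = None  # ancestral taxon scope of a speciation node

    def __post_init__(self) -> None:
        if self.event not in (SPECIATION, DUPLICATION):
            raise HOGError(f"unknown event {self.event!r}")
        if len(self.children) < 1:
            raise HOGError("internal HOG node needs at least one child")


HOG = Union[HOGLeaf, HOGNode]


@dataclass(frozen=True)
class PairwiseRelation:
    """An unordered gene pair classified as ortholog or paralog."""

    geneA: IRI
    geneB: IRI
    relation: str  # "ortholog" | "paralog"

    def __post_init__(self) -> None:
        if self.geneA == self.geneB:
            raise HOGError("a gene cannot be its own ortholog/paralog")
        if self.relation not in ("ortholog", "paralog"):
            raise HOGError(f"unknown relation {self.relation!r}")
        # normalize to an unordered pair
        if self.geneB.value < self.geneA.value:
            a, b = self.geneA, self.geneB
            object.__setattr__(self, "geneA", b)
            object.__setattr__(self, "geneB", a)

    @property
    def genes(self) -> tuple[IRI, IRI]:
        return (self.geneA, self.geneB)


def leaves(h: HOG) -> list[HOGLeaf]:
    if isinstance(h, HOGLeaf):
        return [h]
    out: list[HOGLeaf] = []
    for child in h.children:
        out.extend(leaves(child))
    return out


def validate_hog(h: HOG) -> None:
    """Every gene IRI occurs in at most one leaf."""
    seen: set[IRI] = set()
    for leaf in leaves(h):
        if leaf.gene in seen:
            raise HOGError(f"gene {leaf.gene} appears in more than one leaf")
        seen.add(leaf.gene)


def derive_pairwise(h: HOG) -> set[PairwiseRelation]:
    """All C(n,2) pairwise relations within one HOG.

    The relation of a leaf pair is decided by the event at their lowest
    common ancestor; the recursion classifies each cross-child pair at the
    node where the two lineages split, which is exactly the LCA.
    """
    validate_hog(h)

    def walk(node: HOG) -> tuple[list[IRI], set[PairwiseRelation]]:
        if isinstance(node, HOGLeaf):
            return [node.gene], set()
        relation = "ortholog" if node.event == SPECIATION else "paralog"
        genes: list[IRI] = []
        rels: set[PairwiseRelation] = set()
        child_gene_lists: list[list[IRI]] = []
        for child in node.children:
            cg, cr = walk(child)
            rels |= cr
            child_gene_lists.append(cg)
        for i, left in enumerate(child_gene_lists):
            for right in child_gene_lists[i + 1 :]:
                for a in left:
                    for b in right:
                        rels.add(PairwiseRelation(a, b, relation))
        for cg in child_gene_lists:
            genes.extend(cg)
        return genes, rels

    return walk(h)[1]


def restrict_to_clade(
    relations: Iterable[PairwiseRelation],
    taxa: Iterable[IRI],
    taxon_of: Mapping[IRI, IRI],
) -> set[PairwiseRelation]:
    """Keep pairs with a partner inside the given clade (set of taxon IRIs).

    Used to shrink intermediate results: restricting the orthology stage to
    a clade before joining is the difference between a broad scan and a
    targeted one.  Raises :class:`HOGError` for genes without a known taxon.
    """
    clade = set(taxa)
    out: set[PairwiseRelation] = set()
    for rel in relations:
        for gene in rel.genes:
            if gene not in taxon_of:
                raise HOGError(f"unknown taxon for gene {gene}")
        if any(taxon_of[g] in clade for g in rel.genes):
            out.add(rel)
    return out


def emit_orth_graph(
    hogs: Iterable[HOG],
    clade_map: Optional[Mapping[IRI, Iterable[IRI]]] = None,
) -> Graph:
    """Serialize HOGs as the orthology store's RDF graph.

    Per gene: ``orth:Gene`` membership, label, taxon link and protein
    cross-reference (proteins additionally typed ``up:Protein`` so that the
    protein-level virtual link is discoverable).  Per pairwise relation:
    both directed property assertions (the relations are symmetric).
    ``clade_map`` adds taxon-to-clade membership triples used by
    clade-restricted queries.
    """
    g = Graph()
    taxon_of: dict[IRI, IRI] = {}
    for hog in hogs:
        validate_hog(hog)
        for leaf in leaves(hog):
            if leaf.gene in taxon_of:
                raise HOGError(f"gene {leaf.gene} appears in more than one HOG")
            taxon_of[leaf.gene] = leaf.taxon
            g.add(Triple(leaf.gene, A, GENE_CLASS))
            g.add(Triple(leaf.gene, IN_TAXON, leaf.taxon))
            g.add(Triple(leaf.taxon, A, TAXON_CLASS))
            if leaf.label is not None:
                g.add(Triple(leaf.gene, LABEL, Literal(leaf.label)))
            if leaf.protein is not None:
                g.add(Triple(leaf.gene, XREF_UNIPROT, leaf.protein))
                g.add(Triple(leaf.protein, A, PROTEIN_CLASS))
        for rel in derive_pairwise(hog):
            pred = ORTHOLOGOUS_TO if rel.relation == "ortholog" else PARALOGOUS_TO
            g.add(Triple(rel.geneA, pred, rel.geneB))
            g.add(Triple(rel.geneB, pred, rel.geneA))
    if clade_map:
        for taxon, clades in clade_map.items():
            for clade in clades:
                g.add(Triple(taxon, IN_CLADE, clade))
    return g


# --- serialization --------------------------------------------------------


def hog_to_dict(h: HOG) -> dict:
    if isinstance(h, HOGLeaf):
        d: dict = {"gene": h.gene.value, "taxon": h.taxon.value}
        if h.label is not None:
            d["label"] = h.label
        if h.protein is not None:
            d["protein"] = h.protein.value
        return d
    d = {"event": h.event, "children": [hog_to_dict(c) for c in h.children]}
    if h.taxon is not None:
        d["taxon"] = h.taxon.value
    return d


def hog_from_dict(d: dict) -> HOG:
    if "gene" in d:
        return HOGLeaf(
            gene=IRI(d["gene"]),
            taxon=IRI(d["taxon"]),
            label=d.get("label"),
            protein=IRI(d["protein"]) if d.get("protein") else None,
        )
    if "event" not in d or "children" not in d:
        raise HOGError(f"node needs 'event' and 'children' (or 'gene'): {sorted(d)}")
    return HOGNode(
        event=d["event"],
        children=tuple(hog_from_dict(c) for c in d["children"]),
        taxon=IRI(d["taxon"]) if d.get("taxon") else None,
    )


def dump_hogs(hogs: Iterable[HOG]) -> str:
    return json.dumps({"hogs": [hog_to_dict(h) for h in hogs]}, indent=2, sort_keys=True)


def load_hogs(text: str) -> list[HOG]:
    doc = json.loads(text)
    return [hog_from_dict(d) for d in doc["hogs"]]


# --- OrthoXML subset ------------------------------------------------------

_OXML_NS = "{http://orthoXML.org/2011/}"


def load_orthoxml(text: str) -> list[HOG]:
    """Read an OrthoXML-subset document into HOGs.

    Supported: ``species``/``database``/``genes``/``gene`` declarations
    (``geneId`` becomes the gene IRI local name, ``protId`` the protein
    accession) and nested ``orthologGroup``/``paralogGroup`` with
    ``geneRef`` leaves.
    """
    root = ET.fromstring(text)

    def tag(el: ET.Element) -> str:
        return el.tag.removeprefix(_OXML_NS)

    gene_table: dict[str, HOGLeaf] = {}
    for species in root:
        if tag(species) != "species":
            continue
        taxid = species.get("NCBITaxId")
        if taxid is None:
            raise HOGError("species element missing NCBITaxId")
        taxon = TAXON(taxid)
        for gene in species.iter(f"{_OXML_NS}gene"):
            internal = gene.get("id")
            gene_id = gene.get("geneId")
            if internal is None or gene_id is None:
                raise HOGError("gene element needs 'id' and 'geneId'")
            prot = gene.get("protId")
            gene_table[internal] = HOGLeaf(
                gene=GENE(gene_id),
                taxon=taxon,
                label=gene_id,
                protein=PROTEIN(prot) if prot else None,
            )

    def build(el: ET.Element) -> HOG:
        t = tag(el)
        if t == "geneRef":
            ref = el.get("id")
            if ref not in gene_table:
                raise HOGError(f"geneRef to undeclared gene id {ref!r}")
            return gene_table[ref]
        if t in ("orthologGroup", "paralogGroup"):
            children = tuple(build(c) for c in el if tag(c) in ("orthologGroup", "paralogGroup", "geneRef"))
            event = SPECIATION if t == "orthologGroup" else DUPLICATION
            return HOGNode(event=event, children=children)
        raise HOGError(f"unsupported element {t!r} in groups")

    groups = root.find(f"{_OXML_NS}groups")
    if groups is None:
        return []
    return [build(el) for el in groups if tag(el) in ("orthologGroup", "paralogGroup")]
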