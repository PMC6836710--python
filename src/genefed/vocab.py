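"""Namespaces and vocabulary constants used across the three data stores.

The gene-expression terms (GenEx-style), orthology terms (ORTH-style) and
protein terms (UniProt-core-style) are the minimal subset needed by the
shipped query catalogue.  VoIDext terms for virtual-link metadata are minted
under a project namespace.
"""

from __future__ import annotations

from .terms import IRI


class Namespace:
    """An IRI prefix that mints terms via attribute or call syntax."""

    def __init__(self, base: str):
        self.base = base

    def __getattr__(self, local: str) -> IRI:
        if local.startswith("_"):
            raise AttributeError(local)
        return IRI(self.base + local)

    def __call__(self, local: str) -> IRI:
        return IRI(self.base + local)

    def __contains__(self, iri: object) -> bool:
        return isinstance(iri, IRI) and iri.value.startswith(self.base)


RDF = Namespace("http://www.w3.org/1999/02/22-rdf-syntax-ns#")
RDFS = Namespace("http://www.w3.org/2000/01/rdf-schema#")
XSD = Namespace("http://www.w3.org/2001/XMLSchema#")
VOID = Namespace("http://rdfs.org/ns/void#")

# Domain vocabularies (orthology, UniProt core, gene expression, OBO).
ORTH = Namespace("http://purl.org/net/orth#")
UP = Namespace("http://purl.uniprot.org/core/")
GENEX = Namespace("http://purl.org/genex#")
OBO = Namespace("http://purl.obolibrary.org/obo/")
LSCR = Namespace("http://purl.org/lscr#")

# Project namespaces for instances and the VoIDext vocabulary.
EX = Namespace("http://example.org/genefed/")
GENE = Namespace("http://example.org/genefed/gene/")
PROTEIN = Namespace("http://purl.uniprot.org/uniprot/")
TAXON = Namespace("http://purl.uniprot.org/taxonomy/")
CONDITION = Namespace("http://example.org/genefed/condition/")
CLADE = Namespace("http://example.org/genefed/clade/")
ANNOTATION = Namespace("http://example.org/genefed/annotation/")
VOIDEXT = Namespace("http://example.org/genefed/voidext#")

A = RDF.type
LABEL = RDFS.label
COMMENT = RDFS.comment

# "in taxon" (RO:0002162): links a gene to the taxon it belongs to.
IN_TAXON = OBO.RO_0002162

GENE_CLASS = ORTH.Gene
ORTHOLOGOUS_TO = ORTH.isOrthologousTo
PARALOGOUS_TO = ORTH.isParalogousTo

PROTEIN_CLASS = UP.Protein
TAXON_CLASS = UP.Taxon
SCIENTIFIC_NAME = UP.scientificName
ENCODED_BY = UP.encodedBy
ORGANISM = UP.organism
EXISTENCE = UP.existence
CLASSIFIED_WITH = UP.classifiedWith
UP_ANNOTATION = UP.annotation
DISEASE_ANNOTATION_CLASS = UP.Disease_Annotation
FUNCTION_ANNOTATION_CLASS = UP.Function_Annotation
XREF_UNIPROT = LSCR.xrefUniprot

EXPRESSED_IN = GENEX.isExpressedIn
ABSENT_IN = GENEX.isAbsentIn
HIGHLY_EXPRESSED_IN = GENEX.isHighlyExpressedIn
EXPRESSED_IN_CONDITION = GENEX.isExpressedInCondition
CONDITION_CLASS = GENEX.ExpressionCondition
HAS_ANAT_ENTITY = GENEX.hasAnatomicalEntity
HAS_STAGE = GENEX.hasDevelopmentalStage
ANAT_ENTITY_CLASS = GENEX.AnatomicalEntity
STAGE_CLASS = GENEX.DevelopmentalStage

IN_CLADE = EX.inClade

# Prefix table shared by the Turtle reader/writer, the SPARQL parser and the
# mapping-file parser.
PREFIXES: dict[str, str] = {
    "rdf": RDF.base,
    "rdfs": RDFS.base,
    "xsd": XSD.base,
    "void": VOID.base,
    "orth": ORTH.base,
    "up": UP.base,
    "genex": GENEX.base,
    "obo": OBO.base,
    "lscr": LSCR.base,
    "ex": EX.base,
    "gene": GENE.base,
    "protein": PROTEIN.base,
    "taxon": TAXON.base,
    "condition": CONDITION.base,
    "clade": CLADE.base,
    "annotation": ANNOTATION.base,
    "voidext": VOIDEXT.base,
}
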