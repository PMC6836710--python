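"""Seeded synthetic data: three coupled stores with by-construction truth.

The generator emulates a desk-scale slice of the production setting: a
relational gene-expression database (species, genes, anatomical entities,
developmental stages, expression calls), an orthology store of hierarchical
orthologous groups covering *every* database gene, and a protein store
covering a *subset* of genes (the coverage asymmetry between orthology and
protein databases) with taxa, scientific names, evidence levels and
disease/function annotations.

Alongside the randomized fraction, a fixed cast of well-known genes (INS,
HBB-Y, Tp53, APP, EGFR, ...) is planted so that every catalogue query has at
least one answer by construction.  Gene and taxon IRIs are minted once and
reused verbatim across all three stores — the virtual-link contract; there
is no sameAs bridging.

``worked_example()`` returns a separate, fully hand-written instance of the
motivating question (disease keyword -> orthologs -> expression in the rat
brain) whose single expected answer is stated in this file.
"""

from __future__ import annotations

import random
import sqlite3
import urllib.parse
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

from .federation import FederationMetadata, GraphEndpoint, VirtualEndpoint
from .obda import VirtualGraph
from .orthology import DUPLICATION, HOG, HOGLeaf, HOGNode, SPECIATION, emit_orth_graph
from .terms import Graph, IRI, Literal, Triple
from .vocab import (
    A,
    ANNOTATION,
    CLADE,
    CLASSIFIED_WITH,
    COMMENT,
    DISEASE_ANNOTATION_CLASS,
    ENCODED_BY,
    EX,
    EXISTENCE,
    FUNCTION_ANNOTATION_CLASS,
    GENE,
    OBO,
    ORGANISM,
    PROTEIN,
    PROTEIN_CLASS,
    SCIENTIFIC_NAME,
    TAXON,
    TAXON_CLASS,
    UP,
    UP_ANNOTATION,
)
from .voidext import describe_dataset, discover_links

BGEE_ENDPOINT = "http://example.org/genefed/sparql/bgee"
OMA_ENDPOINT = "http://example.org/genefed/sparql/oma"
UNIPROT_ENDPOINT = "http://example.org/genefed/sparql/uniprot"

BGEE_DATASET = EX("dataset/bgee")
OMA_DATASET = EX("dataset/oma")
UNIPROT_DATASET = EX("dataset/uniprot")


class FixtureError(ValueError):
    """Invalid fixture specification."""


# (taxid, genus, species, clades) — order is fixed; n_species takes a prefix.
SPECIES_TABLE: tuple[tuple[int, str, str, tuple[str, ...]], ...] = (
    (9606, "Homo", "sapiens", ("Primates", "Mammalia", "Vertebrata")),
    (9598, "Pan", "troglodytes", ("Primates", "Mammalia", "Vertebrata")),
    (9544, "Macaca", "mulatta", ("Primates", "Mammalia", "Vertebrata")),
    (10090, "Mus", "musculus", ("Glires", "Mammalia", "Vertebrata")),
    (10116, "Rattus", "norvegicus", ("Glires", "Mammalia", "Vertebrata")),
    (9986, "Oryctolagus", "cuniculus", ("Glires", "Mammalia", "Vertebrata")),
    (7955, "Danio", "rerio", ("Fish", "Vertebrata")),
    (7227, "Drosophila", "melanogaster", ("Insecta",)),
)

UNIVERSAL_CLADE = "Cellular_organisms"

MNEMONIC = {
    9606: "HUMAN", 9598: "PANTR", 9544: "MACMU", 10090: "MOUSE",
    10116: "RAT", 9986: "RABIT", 7955: "DANRE", 7227: "DROME",
}

# (anatEntityId, name) — brain, liver and pancreas first: the catalogue
# depends on them.
ANAT_TABLE: tuple[tuple[str, str], ...] = (
    ("UBERON:0000955", "brain"),
    ("UBERON:0002107", "liver"),
    ("UBERON:0001264", "pancreas"),
    ("UBERON:0000948", "heart"),
    ("UBERON:0002113", "kidney"),
    ("UBERON:0002048", "lung"),
)

STAGE_TABLE: tuple[tuple[str, str], ...] = (
    ("DEV:0000001", "embryo stage"),
    ("DEV:0000002", "infant stage"),
    ("DEV:0000003", "adult stage"),
    ("DEV:0000004", "aged stage"),
)

GO_TERMS = ("GO_0005179", "GO_0005615", "GO_0016020", "GO_0008270")

EVIDENCE_IRIS = (
    UP("Evidence_at_Protein_Level_Existence"),
    UP("Evidence_at_Transcript_Level_Existence"),
)

DEFAULT_DISEASES = (
    "glioblastoma",
    "diabetes mellitus",
    "breast cancer",
    "Alzheimer disease",
    "hemolytic anemia",
)

# Hand-planted genes: (geneId, geneName, taxid, family).  Families become
# HOGs; the remaining per-species gene budget is filled with random genes.
PLANTED_GENES: tuple[tuple[str, str, int, str], ...] = (
    ("9606_INS", "INS", 9606, "INS"),
    ("10090_Ins2", "Ins2", 10090, "INS"),
    ("10116_Ins1", "Ins1", 10116, "INS"),
    ("7955_ins", "ins", 7955, "INS"),
    ("9606_HBB", "HBB", 9606, "HBB"),
    ("10090_Hbb-y", "HBB-Y", 10090, "HBB"),
    ("9986_HBB1", "HBB1", 9986, "HBB"),
    ("9606_TP53", "TP53", 9606, "TP53"),
    ("10116_Tp53", "Tp53", 10116, "TP53"),
    ("10116_Tp53b", "Tp53b", 10116, "TP53"),
    ("7227_dpr1", "dpr1", 7227, "CADM"),
    ("9606_CADM1", "CADM1", 9606, "CADM"),
    ("9598_CADM1", "CADM1", 9598, "CADM"),
    ("10090_Cadm1", "Cadm1", 10090, "CADM"),
    ("7955_cadm1", "cadm1", 7955, "CADM"),
    ("9606_GCG", "GCG", 9606, "GCG"),
    ("10090_Gcg", "Gcg", 10090, "GCG"),
    ("9606_APP", "APP", 9606, "APP"),
    ("10090_App", "App", 10090, "APP"),
    ("9606_EGFR", "EGFR", 9606, "EGFR"),
    ("10116_Egfr", "Egfr", 10116, "EGFR"),
    ("10090_Egfr", "Egfr", 10090, "EGFR"),
)

# (geneId, anatEntityId, stageId, callType, level)
PLANTED_EXPRESSION: tuple[tuple[str, str, str, str, Optional[str]], ...] = (
    ("10090_Ins2", "UBERON:0002107", "DEV:0000003", "present", "high"),
    ("7955_ins", "UBERON:0001264", "DEV:0000003", "present", "high"),
    ("7955_ins", "UBERON:0002107", "DEV:0000001", "present", "low"),
    ("7227_dpr1", "UBERON:0000955", "DEV:0000003", "present", "high"),
    ("9606_GCG", "UBERON:0001264", "DEV:0000003", "present", "high"),
    ("9606_INS", "UBERON:0001264", "DEV:0000003", "present", "high"),
    ("9606_APP", "UBERON:0000955", "DEV:0000002", "present", "high"),
    ("10116_Egfr", "UBERON:0000955", "DEV:0000003", "present", "low"),
)

# protein-level disease annotations planted for the disease queries
PLANTED_DISEASES: dict[str, str] = {
    "9606_EGFR": "Known association to glioblastoma (brain cancer)",
    "9606_APP": "Associated with Alzheimer disease",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; the defaults are the study conditions."""

    seed: int = 42
    n_species: int = 8
    n_genes_per_species: int = 8
    n_anat_entities: int = 6
    n_stages: int = 4
    n_hogs: int = 6
    p_expressed: float = 0.3
    p_absent: float = 0.1
    p_high: float = 0.1
    p_disease_annotated: float = 0.3
    p_protein: float = 0.8
    disease_vocabulary: tuple[str, ...] = DEFAULT_DISEASES

    def validate(self) -> None:
        if not (1 <= self.n_species <= len(SPECIES_TABLE)):
            raise FixtureError(f"n_species must be in 1..{len(SPECIES_TABLE)}")
        if self.n_genes_per_species < 0:
            raise FixtureError("n_genes_per_species must be non-negative")
        if not (1 <= self.n_anat_entities <= len(ANAT_TABLE)):
            raise FixtureError(f"n_anat_entities must be in 1..{len(ANAT_TABLE)}")
        if not (1 <= self.n_stages <= len(STAGE_TABLE)):
            raise FixtureError(f"n_stages must be in 1..{len(STAGE_TABLE)}")
        if self.n_hogs < 1:
            raise FixtureError("n_hogs must be positive")
        for name in ("p_expressed", "p_absent", "p_high", "p_disease_annotated", "p_protein"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise FixtureError(f"{name} must be a probability")
        if self.p_expressed + self.p_absent > 1.0:
            raise FixtureError("p_expressed + p_absent must not exceed 1")
        if self.p_high > self.p_expressed:
            raise FixtureError("p_high must not exceed p_expressed")


DDL = """
CREATE TABLE species (
    speciesId INTEGER PRIMARY KEY,
    genus TEXT NOT NULL,
    species TEXT NOT NULL
);
CREATE TABLE gene (
    geneId TEXT PRIMARY KEY,
    geneName TEXT,
    speciesId INTEGER NOT NULL REFERENCES species(speciesId)
);
CREATE TABLE anatEntity (
    anatEntityId TEXT PRIMARY KEY,
    name TEXT NOT NULL
);
CREATE TABLE stage (
    stageId TEXT PRIMARY KEY,
    name TEXT NOT NULL
);
CREATE TABLE expression (
    geneId TEXT NOT NULL REFERENCES gene(geneId),
    anatEntityId TEXT NOT NULL REFERENCES anatEntity(anatEntityId),
    stageId TEXT NOT NULL REFERENCES stage(stageId),
    callType TEXT NOT NULL CHECK (callType IN ('present', 'absent')),
    level TEXT CHECK (level IN ('high', 'low') OR level IS NULL),
    PRIMARY KEY (geneId, anatEntityId, stageId)
);
"""


def gene_iri(gene_id: str) -> IRI:
    """Mint the gene IRI exactly as the mapping templates do."""
    return GENE(urllib.parse.quote(gene_id, safe=""))


def taxon_iri(taxid: int) -> IRI:
    return TAXON(str(taxid))


def load_mapping_document() -> str:
    return resources.files("genefed.data").joinpath("bgee.obda").read_text(encoding="utf-8")


def build_expression_db(spec: FixtureSpec, conn: Optional[sqlite3.Connection] = None) -> sqlite3.Connection:
    """Create and populate the relational expression database.

    Planted rows go in first, then randomized expression calls: for each
    gene and anatomical entity one draw decides present (optionally highly
    expressed, at a random stage), absent (level NULL) or no call.
    """
    spec.validate()
    if conn is None:
        conn = sqlite3.connect(":memory:")
    conn.executescript(DDL)
    rng = random.Random(spec.seed)

    species = SPECIES_TABLE[: spec.n_species]
    taxids = {row[0] for row in species}
    for taxid, genus, sp, _clades in species:
        conn.execute("INSERT INTO species VALUES (?, ?, ?)", (taxid, genus, sp))
    anats = ANAT_TABLE[: spec.n_anat_entities]
    for anat_id, name in anats:
        conn.execute("INSERT INTO anatEntity VALUES (?, ?)", (anat_id, name))
    stages = STAGE_TABLE[: spec.n_stages]
    for stage_id, name in stages:
        conn.execute("INSERT INTO stage VALUES (?, ?)", (stage_id, name))

    planted_by_species: dict[int, list[tuple[str, str]]] = {t: [] for t in taxids}
    for gene_id, name, taxid, _family in PLANTED_GENES:
        if taxid in taxids:
            planted_by_species[taxid].append((gene_id, name))
    genes: list[tuple[str, str, int]] = []
    for taxid, _genus, _sp, _clades in species:
        planted = planted_by_species[taxid][: spec.n_genes_per_species]
        for gene_id, name in planted:
            genes.append((gene_id, name, taxid))
        for i in range(spec.n_genes_per_species - len(planted)):
            genes.append((f"{taxid}_R{i}", f"G{taxid}X{i}", taxid))
    for gene_id, name, taxid in genes:
        conn.execute("INSERT INTO gene VALUES (?, ?, ?)", (gene_id, name, taxid))

    seen: set[tuple[str, str, str]] = set()
    gene_ids = {g for g, _, _ in genes}
    for row in PLANTED_EXPRESSION:
        gene_id, anat_id, stage_id, call, level = row
        if gene_id not in gene_ids:
            continue
        if anat_id not in {a for a, _ in anats} or stage_id not in {s for s, _ in stages}:
            continue
        conn.execute("INSERT INTO expression VALUES (?, ?, ?, ?, ?)", row)
        seen.add((gene_id, anat_id, stage_id))
    for gene_id, _name, _taxid in genes:
        for anat_id, _aname in anats:
            u = rng.random()
            stage_id = rng.choice(stages)[0]
            if u < spec.p_expressed:
                level = "high" if u < spec.p_high else "low"
                key = (gene_id, anat_id, stage_id)
                if key not in seen:
                    seen.add(key)
                    conn.execute(
                        "INSERT INTO expression VALUES (?, ?, ?, 'present', ?)",
                        (gene_id, anat_id, stage_id, level),
                    )
            elif u < spec.p_expressed + spec.p_absent:
                key = (gene_id, anat_id, stage_id)
                if key not in seen:
                    seen.add(key)
                    conn.execute(
                        "INSERT INTO expression VALUES (?, ?, ?, 'absent', NULL)",
                        (gene_id, anat_id, stage_id),
                    )
    conn.commit()
    return conn


def _species_subtrees(members: Sequence[HOGLeaf]) -> list[HOG]:
    """Group leaves by taxon; multi-gene species become duplication nodes."""
    by_taxon: dict[IRI, list[HOGLeaf]] = {}
    order: list[IRI] = []
    for leaf in members:
        if leaf.taxon not in by_taxon:
            by_taxon[leaf.taxon] = []
            order.append(leaf.taxon)
        by_taxon[leaf.taxon].append(leaf)
    subtrees: list[HOG] = []
    for taxon in order:
        leaves = by_taxon[taxon]
        if len(leaves) == 1:
            subtrees.append(leaves[0])
        else:
            subtrees.append(HOGNode(DUPLICATION, tuple(leaves)))
    return subtrees


def _make_hog(members: Sequence[HOGLeaf]) -> HOG:
    subtrees = _species_subtrees(members)
    if len(subtrees) == 1:
        return subtrees[0]
    return HOGNode(SPECIATION, tuple(subtrees))


def build_hogs_and_proteins(
    spec: FixtureSpec, conn: sqlite3.Connection
) -> tuple[list[HOG], Graph]:
    """Derive the orthology HOGs and the protein store from the database.

    Every database gene lands in exactly one HOG leaf (the orthology store
    completely covers the expression store); only a subset of genes gets a
    protein node (planted genes always, random genes with probability
    ``p_protein``) — the coverage asymmetry between the stores.  Taxon IRIs
    and scientific-name literals are byte-identical to the expression
    store's virtual output.
    """
    spec.validate()
    rng = random.Random(spec.seed + 1)
    gene_rows = conn.execute("SELECT geneId, geneName, speciesId FROM gene ORDER BY rowid").fetchall()
    species_rows = conn.execute("SELECT speciesId, genus, species FROM species ORDER BY speciesId").fetchall()

    planted_family = {g: fam for g, _n, _t, fam in PLANTED_GENES}
    protein_acc: dict[str, str] = {}
    counter = 1
    for gene_id, _name, _taxid in gene_rows:
        planted = gene_id in planted_family
        if planted or rng.random() < spec.p_protein:
            protein_acc[gene_id] = f"P{counter:05d}"
        counter += 1

    def leaf(gene_id: str, name: str, taxid: int) -> HOGLeaf:
        acc = protein_acc.get(gene_id)
        return HOGLeaf(
            gene=gene_iri(gene_id),
            taxon=taxon_iri(taxid),
            label=name,
            protein=PROTEIN(acc) if acc else None,
        )

    families: dict[str, list[HOGLeaf]] = {}
    leftovers: list[HOGLeaf] = []
    for gene_id, name, taxid in gene_rows:
        fam = planted_family.get(gene_id)
        if fam is not None:
            families.setdefault(fam, []).append(leaf(gene_id, name, taxid))
        else:
            leftovers.append(leaf(gene_id, name, taxid))

    hogs: list[HOG] = [_make_hog(members) for _fam, members in sorted(families.items())]
    rng.shuffle(leftovers)
    if leftovers:
        buckets: list[list[HOGLeaf]] = [[] for _ in range(min(spec.n_hogs, len(leftovers)))]
        for i, lf in enumerate(leftovers):
            buckets[i % len(buckets)].append(lf)
        hogs.extend(_make_hog(b) for b in buckets if b)

    g = Graph(name=UNIPROT_DATASET)
    for taxid, genus, sp in species_rows:
        t = taxon_iri(taxid)
        g.add(Triple(t, A, TAXON_CLASS))
        g.add(Triple(t, SCIENTIFIC_NAME, Literal(f"{genus} {sp}")))
    for idx, (gene_id, name, taxid) in enumerate(gene_rows):
        acc = protein_acc.get(gene_id)
        if acc is None:
            continue
        protein = PROTEIN(acc)
        g.add(Triple(protein, A, PROTEIN_CLASS))
        g.add(Triple(protein, ENCODED_BY, gene_iri(gene_id)))
        g.add(Triple(protein, ORGANISM, taxon_iri(taxid)))
        mnemonic = f"{(name or gene_id).upper().replace('-', '')}_{MNEMONIC.get(taxid, 'UNK')}"
        g.add(Triple(protein, UP.mnemonic, Literal(mnemonic)))
        g.add(Triple(protein, EXISTENCE, EVIDENCE_IRIS[idx % len(EVIDENCE_IRIS)]))
        g.add(Triple(protein, CLASSIFIED_WITH, OBO(rng.choice(GO_TERMS))))
        fn_node = ANNOTATION(f"{acc}-fn")
        g.add(Triple(protein, UP_ANNOTATION, fn_node))
        g.add(Triple(fn_node, A, FUNCTION_ANNOTATION_CLASS))
        g.add(Triple(fn_node, COMMENT, Literal(f"{name or gene_id} protein function annotation")))
        disease: Optional[str] = PLANTED_DISEASES.get(gene_id)
        if disease is None and rng.random() < spec.p_disease_annotated:
            disease_name = rng.choice(spec.disease_vocabulary)
            disease = f"Known association to {disease_name}"
        if disease is not None:
            d_node = ANNOTATION(f"{acc}-disease")
            g.add(Triple(protein, UP_ANNOTATION, d_node))
            g.add(Triple(d_node, A, DISEASE_ANNOTATION_CLASS))
            g.add(Triple(d_node, COMMENT, Literal(disease)))
    return hogs, g


def clade_map_for(spec: FixtureSpec) -> dict[IRI, list[IRI]]:
    out: dict[IRI, list[IRI]] = {}
    for taxid, _genus, _sp, clades in SPECIES_TABLE[: spec.n_species]:
        out[taxon_iri(taxid)] = [CLADE(c) for c in clades + (UNIVERSAL_CLADE,)]
    return out


@dataclass
class FixtureSet:
    """Everything a federated session needs, built from one spec."""

    spec: FixtureSpec
    conn: sqlite3.Connection
    mapping_doc: str
    virtual: VirtualGraph
    bgee_graph: Graph
    hogs: list[HOG]
    orth_graph: Graph
    protein_graph: Graph
    meta: FederationMetadata
    endpoints: dict[str, GraphEndpoint | VirtualEndpoint]


def build_federation(
    conn: sqlite3.Connection,
    hogs: list[HOG],
    protein_graph: Graph,
    clade_map: Optional[dict[IRI, list[IRI]]] = None,
    mapping_doc: Optional[str] = None,
) -> tuple[VirtualGraph, Graph, Graph, FederationMetadata, dict[str, GraphEndpoint | VirtualEndpoint]]:
    """Wire the three stores into endpoints, descriptions and links."""
    doc = mapping_doc if mapping_doc is not None else load_mapping_document()
    virtual = VirtualGraph.from_mapping_document(conn, doc)
    bgee_graph = virtual.materialize()
    orth_graph = emit_orth_graph(hogs, clade_map)
    datasets = {
        BGEE_DATASET: describe_dataset(bgee_graph, BGEE_DATASET, BGEE_ENDPOINT),
        OMA_DATASET: describe_dataset(orth_graph, OMA_DATASET, OMA_ENDPOINT),
        UNIPROT_DATASET: describe_dataset(protein_graph, UNIPROT_DATASET, UNIPROT_ENDPOINT),
    }
    links = (
        discover_links(bgee_graph, orth_graph, BGEE_DATASET, OMA_DATASET)
        + discover_links(bgee_graph, protein_graph, BGEE_DATASET, UNIPROT_DATASET)
        + discover_links(orth_graph, protein_graph, OMA_DATASET, UNIPROT_DATASET)
    )
    meta = FederationMetadata(datasets=datasets, links=links)
    endpoints: dict[str, GraphEndpoint | VirtualEndpoint] = {
        BGEE_ENDPOINT: VirtualEndpoint(BGEE_ENDPOINT, virtual),
        OMA_ENDPOINT: GraphEndpoint(OMA_ENDPOINT, orth_graph),
        UNIPROT_ENDPOINT: GraphEndpoint(UNIPROT_ENDPOINT, protein_graph),
    }
    return virtual, bgee_graph, orth_graph, meta, endpoints


def build_fixtures(spec: Optional[FixtureSpec] = None) -> FixtureSet:
    """One-call construction of the default federated test-bed."""
    spec = spec or FixtureSpec()
    conn = build_expression_db(spec)
    hogs, protein_graph = build_hogs_and_proteins(spec, conn)
    virtual, bgee_graph, orth_graph, meta, endpoints = build_federation(
        conn, hogs, protein_graph, clade_map_for(spec)
    )
    return FixtureSet(
        spec=spec,
        conn=conn,
        mapping_doc=load_mapping_document(),
        virtual=virtual,
        bgee_graph=bgee_graph,
        hogs=hogs,
        orth_graph=orth_graph,
        protein_graph=protein_graph,
        meta=meta,
        endpoints=endpoints,
    )


def dump_database(conn: sqlite3.Connection) -> str:
    """Deterministic SQL dump of the embedded database."""
    return "\n".join(conn.iterdump()) + "\n"


# --- worked example -------------------------------------------------------

#: The single expected answer of the motivating query on the hand-written
#: instance: the human EGFR protein paired with its rat ortholog, which is
#: the only glioblastoma-annotated gene's ortholog expressed in rat brain.
WORKED_EXAMPLE_ANSWER: tuple[IRI, IRI] = (PROTEIN("PWE001"), gene_iri("10116_Egfr"))


@dataclass
class WorkedExample:
    conn: sqlite3.Connection
    hogs: list[HOG]
    orth_graph: Graph
    protein_graph: Graph
    meta: FederationMetadata
    endpoints: dict[str, GraphEndpoint | VirtualEndpoint]
    virtual: VirtualGraph
    bgee_graph: Graph
    expected_pairs: set[tuple[IRI, IRI]]


def worked_example() -> WorkedExample:
    """The fixed, seed-free motivating-example instance.

    Construction (stated, not sampled): exactly three human genes carry a
    glioblastoma annotation (EGFR, PTEN, TP53); exactly two of them (EGFR,
    PTEN) have rat orthologs; exactly one of those orthologs (rat Egfr) has
    a present expression call in the rat brain.  The expected answer to the
    motivating query is therefore the single pair
    :data:`WORKED_EXAMPLE_ANSWER`; swapping the brain term for liver yields
    zero answers because the only rat gene expressed in liver (Ins1) has no
    disease-annotated human ortholog.
    """
    conn = sqlite3.connect(":memory:")
    conn.executescript(DDL)
    for taxid, genus, sp, _clades in SPECIES_TABLE[:6]:
        if taxid in (9606, 10116, 10090):
            conn.execute(
                "INSERT INTO species VALUES (?, ?, ?)",
                (taxid, genus, sp),
            )
    genes = [
        ("9606_EGFR", "EGFR", 9606),
        ("9606_PTEN", "PTEN", 9606),
        ("9606_TP53", "TP53", 9606),
        ("9606_INS", "INS", 9606),
        ("10116_Egfr", "Egfr", 10116),
        ("10116_Pten", "Pten", 10116),
        ("10116_Ins1", "Ins1", 10116),
        ("10090_Trp53", "Trp53", 10090),
    ]
    conn.executemany("INSERT INTO gene VALUES (?, ?, ?)", genes)
    conn.executemany("INSERT INTO anatEntity VALUES (?, ?)", ANAT_TABLE[:3])
    conn.executemany("INSERT INTO stage VALUES (?, ?)", STAGE_TABLE[:3])
    conn.executemany(
        "INSERT INTO expression VALUES (?, ?, ?, ?, ?)",
        [
            ("10116_Egfr", "UBERON:0000955", "DEV:0000003", "present", "high"),
            ("10116_Ins1", "UBERON:0002107", "DEV:0000003", "present", "high"),
            ("10116_Pten", "UBERON:0000955", "DEV:0000003", "absent", None),
            ("9606_EGFR", "UBERON:0000955", "DEV:0000003", "present", "low"),
        ],
    )
    conn.commit()

    accs = {
        "9606_EGFR": "PWE001",
        "9606_PTEN": "PWE002",
        "9606_TP53": "PWE003",
        "9606_INS": "PWE004",
        "10116_Egfr": "PWE005",
        "10116_Pten": "PWE006",
        "10116_Ins1": "PWE007",
    }

    def leaf(gene_id: str, name: str, taxid: int) -> HOGLeaf:
        acc = accs.get(gene_id)
        return HOGLeaf(gene_iri(gene_id), taxon_iri(taxid), name, PROTEIN(acc) if acc else None)

    hogs: list[HOG] = [
        HOGNode(SPECIATION, (leaf("9606_EGFR", "EGFR", 9606), leaf("10116_Egfr", "Egfr", 10116))),
        HOGNode(SPECIATION, (leaf("9606_PTEN", "PTEN", 9606), leaf("10116_Pten", "Pten", 10116))),
        HOGNode(SPECIATION, (leaf("9606_TP53", "TP53", 9606), leaf("10090_Trp53", "Trp53", 10090))),
        HOGNode(SPECIATION, (leaf("9606_INS", "INS", 9606), leaf("10116_Ins1", "Ins1", 10116))),
    ]

    g = Graph(name=UNIPROT_DATASET)
    for taxid, genus, sp, _clades in SPECIES_TABLE[:6]:
        if taxid in (9606, 10116, 10090):
            t = taxon_iri(taxid)
            g.add(Triple(t, A, TAXON_CLASS))
            g.add(Triple(t, SCIENTIFIC_NAME, Literal(f"{genus} {sp}")))
    diseases = {
        "9606_EGFR": "Known association to glioblastoma",
        "9606_PTEN": "Known association to glioblastoma",
        "9606_TP53": "Known association to glioblastoma",
    }
    for gene_id, name, taxid in genes:
        acc = accs.get(gene_id)
        if acc is None:
            continue
        protein = PROTEIN(acc)
        g.add(Triple(protein, A, PROTEIN_CLASS))
        g.add(Triple(protein, ENCODED_BY, gene_iri(gene_id)))
        g.add(Triple(protein, ORGANISM, taxon_iri(taxid)))
        g.add(Triple(protein, UP.mnemonic, Literal(f"{name.upper()}_{MNEMONIC[taxid]}")))
        fn = ANNOTATION(f"{acc}-fn")
        g.add(Triple(protein, UP_ANNOTATION, fn))
        g.add(Triple(fn, A, FUNCTION_ANNOTATION_CLASS))
        g.add(Triple(fn, COMMENT, Literal(f"{name} protein function annotation")))
        if gene_id in diseases:
            d = ANNOTATION(f"{acc}-disease")
            g.add(Triple(protein, UP_ANNOTATION, d))
            g.add(Triple(d, A, DISEASE_ANNOTATION_CLASS))
            g.add(Triple(d, COMMENT, Literal(diseases[gene_id])))

    clade_map = {
        taxon_iri(t): [CLADE(c) for c in clades + (UNIVERSAL_CLADE,)]
        for t, _g, _s, clades in SPECIES_TABLE[:6]
        if t in (9606, 10116, 10090)
    }
    virtual, bgee_graph, orth_graph, meta, endpoints = build_federation(conn, hogs, g, clade_map)
    return WorkedExample(
        conn=conn,
        hogs=hogs,
        orth_graph=orth_graph,
        protein_graph=g,
        meta=meta,
        endpoints=endpoints,
        virtual=virtual,
        bgee_graph=bgee_graph,
        expected_pairs={WORKED_EXAMPLE_ANSWER},
    )
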