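"""Ground truth by brute force, independent of the OBDA/federation engines.

``export_bgee_graph`` converts the relational database to triples with
plain loops over the tables — deliberately *not* via the mapping machinery
— so that engine answers can be checked against an answer computed on a
code path that shares nothing with them except the naive evaluator.
"""

from __future__ import annotations

import sqlite3
import urllib.parse
from dataclasses import replace
from typing import Iterable, Mapping

from .evaluate import SolutionSet, match_bgp
from .sparql import Query
from .terms import Graph, IRI, Literal, Term, Triple
from .vocab import (
    A,
    ABSENT_IN,
    ANAT_ENTITY_CLASS,
    CONDITION,
    CONDITION_CLASS,
    EXPRESSED_IN,
    EXPRESSED_IN_CONDITION,
    GENE,
    GENE_CLASS,
    HAS_ANAT_ENTITY,
    HAS_STAGE,
    HIGHLY_EXPRESSED_IN,
    IN_TAXON,
    LABEL,
    OBO,
    SCIENTIFIC_NAME,
    STAGE_CLASS,
    TAXON,
    TAXON_CLASS,
)


def _gene(gene_id: str) -> IRI:
    return GENE(urllib.parse.quote(gene_id, safe=""))


def _obo(curie: str) -> IRI:
    return OBO(curie.replace(":", "_", 1))


def _condition(anat_id: str, stage_id: str) -> IRI:
    q = urllib.parse.quote
    return CONDITION(f"{q(anat_id, safe='')}-{q(stage_id, safe='')}")


def export_bgee_graph(conn: sqlite3.Connection) -> Graph:
    """Directly export the expression database as triples (no mappings)."""
    g = Graph()
    for taxid, genus, sp in conn.execute("SELECT speciesId, genus, species FROM species"):
        t = TAXON(str(taxid))
        g.add(Triple(t, A, TAXON_CLASS))
        g.add(Triple(t, SCIENTIFIC_NAME, Literal(f"{genus} {sp}")))
    for gene_id, name, taxid in conn.execute("SELECT geneId, geneName, speciesId FROM gene"):
        gi = _gene(gene_id)
        g.add(Triple(gi, A, GENE_CLASS))
        g.add(Triple(gi, IN_TAXON, TAXON(str(taxid))))
        if name is not None:
            g.add(Triple(gi, LABEL, Literal(name)))
    for anat_id, name in conn.execute("SELECT anatEntityId, name FROM anatEntity"):
        ai = _obo(anat_id)
        g.add(Triple(ai, A, ANAT_ENTITY_CLASS))
        g.add(Triple(ai, LABEL, Literal(name)))
    for stage_id, name in conn.execute("SELECT stageId, name FROM stage"):
        si = _obo(stage_id)
        g.add(Triple(si, A, STAGE_CLASS))
        g.add(Triple(si, LABEL, Literal(name)))
    rows = conn.execute("SELECT geneId, anatEntityId, stageId, callType, level FROM expression").fetchall()
    for gene_id, anat_id, stage_id, call, level in rows:
        gi, ai = _gene(gene_id), _obo(anat_id)
        if call == "present":
            g.add(Triple(gi, EXPRESSED_IN, ai))
            if level == "high":
                g.add(Triple(gi, HIGHLY_EXPRESSED_IN, ai))
            cond = _condition(anat_id, stage_id)
            g.add(Triple(cond, A, CONDITION_CLASS))
            g.add(Triple(cond, HAS_ANAT_ENTITY, ai))
            g.add(Triple(cond, HAS_STAGE, _obo(stage_id)))
            g.add(Triple(gi, EXPRESSED_IN_CONDITION, cond))
        else:
            g.add(Triple(gi, ABSENT_IN, ai))
    return g


def flatten(q: Query) -> Query:
    """Fold SERVICE blocks into the main BGP for centralized evaluation."""
    if not q.service_blocks:
        return q
    bgp = q.bgp + tuple(p for b in q.service_blocks for p in b.bgp)
    filters = q.filters + tuple(f for b in q.service_blocks for f in b.filters)
    return replace(q, bgp=bgp, filters=filters, service_blocks=())


def centralized_answer(union_graph: Graph, q: Query) -> SolutionSet:
    """Evaluate a (possibly federated) query over one merged graph."""
    return match_bgp(union_graph, flatten(q))


def compute_ground_truth(
    conn: sqlite3.Connection,
    orth_graph: Graph,
    protein_graph: Graph,
    queries: Mapping[str, Query],
) -> dict[str, SolutionSet]:
    """Answer every catalogue query by brute force over merged data."""
    union = export_bgee_graph(conn) | orth_graph | protein_graph
    return {qid: centralized_answer(union, q) for qid, q in queries.items()}


def solutions_to_tsv(result: SolutionSet) -> str:
    """Canonical tab-separated dump (header + sorted rows)."""
    header = "\t".join(str(v) for v in result.variables)
    rows = sorted(
        "\t".join("" if t is None else _term_str(t) for t in key)
        for key, n in result.as_multiset().items()
        for _ in range(n)
    )
    return "\n".join([header] + rows) + "\n"


def _term_str(t: Term) -> str:
    if isinstance(t, Literal):
        return t.lexical
    return str(t)
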