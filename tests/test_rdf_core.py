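"""RDF data model, N-Triples/Turtle I/O and the naive BGP evaluator."""

from __future__ import annotations

import random
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from genefed.evaluate import SolutionSet, match_bgp
from genefed.io import ParseError, parse_ntriples, parse_turtle, serialize_graph
from genefed.sparql import Query, TriplePattern
from genefed.terms import BlankNode, Graph, IRI, Literal, RDFError, Triple, Variable
from genefed.vocab import RDFS, XSD


# --- terms ----------------------------------------------------------------


def test_iri_must_be_absolute_and_whitespace_free():
    with pytest.raises(RDFError):
        IRI("relative/path")
    with pytest.raises(RDFError):
        IRI("http://example.org/has space")
    assert IRI("http://example.org/x").value == "http://example.org/x"


def test_literal_equality_requires_datatype_and_lang_agreement():
    assert Literal("1") != Literal("1", datatype=XSD.integer)
    assert Literal("chat", lang="fr") != Literal("chat")
    assert Literal("x", datatype=XSD.string) == Literal("x", datatype=XSD.string)
    with pytest.raises(RDFError):
        Literal("x", datatype=XSD.string, lang="en")


def test_triple_predicate_must_be_iri_and_subject_not_literal():
    s, p = IRI("http://e.org/s"), IRI("http://e.org/p")
    with pytest.raises(RDFError):
        Triple(Literal("no"), p, s)
    t = Triple(s, p, Literal("ok"))
    assert t.predicate == p


def test_graph_set_semantics():
    t = Triple(IRI("http://e.org/s"), IRI("http://e.org/p"), Literal("o"))
    g = Graph()
    g.add(t)
    g.add(t)
    assert len(g) == 1


# --- serialization round-trips -------------------------------------------

_iris = st.sampled_from([IRI(f"http://example.org/r{i}") for i in range(8)])
_literals = st.one_of(
    st.text(max_size=12).map(Literal),
    st.integers(0, 99).map(lambda n: Literal(str(n), datatype=XSD.integer)),
    st.sampled_from(["a b", 'quo"te', "back\\slash", "tab\there"]).map(Literal),
    st.text(min_size=1, max_size=5).map(lambda s: Literal(s, lang="en")),
)
_subjects = st.one_of(_iris, st.sampled_from([BlankNode(f"b{i}") for i in range(3)]))
_objects = st.one_of(_iris, _literals, st.sampled_from([BlankNode(f"b{i}") for i in range(3)]))
_triples = st.builds(Triple, _subjects, _iris, _objects)
_graphs = st.lists(_triples, max_size=40).map(Graph)


@settings(max_examples=100, derandomize=True)
@given(_graphs)
def test_ntriples_round_trip(g):
    """parse(serialize(g)) == g for randomized graphs, both formats."""
    assert parse_ntriples(serialize_graph(g, "ntriples")) == g
    assert parse_turtle(serialize_graph(g, "turtle")) == g


@settings(max_examples=30, derandomize=True)
@given(_graphs)
def test_ntriples_output_is_canonical_and_rdflib_compatible(g):
    """Serialization is sorted/diff-stable, and an independent RDF stack
    parses it to the same triple count."""
    rdflib = pytest.importorskip("rdflib")
    out = serialize_graph(g, "ntriples")
    assert out == serialize_graph(parse_ntriples(out), "ntriples")
    lines = [l for l in out.splitlines() if l]
    assert lines == sorted(lines)
    rg = rdflib.Graph()
    rg.parse(data=out, format="nt")
    assert len(rg) == len(g)


def test_empty_document_and_single_statement():
    assert len(parse_ntriples("")) == 0
    g = parse_ntriples("<http://e.org/s> <http://e.org/p> \"hello\" .\n")
    assert len(g) == 1
    assert serialize_graph(Graph()) == ""


def test_parse_errors_name_the_line():
    with pytest.raises(ParseError, match="line 2"):
        parse_ntriples('<http://e.org/s> <http://e.org/p> <http://e.org/o> .\n<oops\n')
    with pytest.raises(ParseError):
        parse_ntriples("<rel/iri> <http://e.org/p> <http://e.org/o> .\n")
    with pytest.raises(ValueError, match="format"):
        serialize_graph(Graph(), "trig")


def test_turtle_subset_prefixes_a_and_lists():
    text = """
    @prefix ex: <http://example.org/> .
    PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
    ex:s a ex:Klass ;
        rdfs:label "one", "two" .
    """
    g = parse_turtle(text)
    assert len(g) == 3
    assert Triple(IRI("http://example.org/s"), RDFS.label, Literal("two")) in g
    with pytest.raises(ParseError, match="unknown prefix"):
        parse_turtle("nope:s a nope:T .")


# --- evaluator vs brute force --------------------------------------------


def brute_force_bgp(g: Graph, q: Query) -> SolutionSet:
    """Independent oracle: enumerate every assignment of graph triples to
    patterns and keep consistent ones."""
    triples = list(g)
    solutions = []
    for combo in product(triples, repeat=len(q.bgp)):
        binding = {}
        ok = True
        for pat, tr in zip(q.bgp, combo):
            for slot, val in zip((pat.subject, pat.predicate, pat.object), tr):
                if isinstance(slot, Variable):
                    if binding.get(slot, val) != val:
                        ok = False
                        break
                    binding[slot] = val
                elif slot != val:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            solutions.append({v: binding[v] for v in q.variables})
    return SolutionSet(q.variables, solutions)


def test_empty_bgp_is_join_identity():
    q = Query(variables=())
    result = match_bgp(Graph(), q)
    assert len(result) == 1 and result.solutions[0] == {}


def test_match_bgp_equals_brute_force_enumeration():
    """Naive evaluation agrees with exhaustive assignment enumeration on
    200 random graph/query pairs (graphs <= 30 triples, <= 2 patterns)."""
    rng = random.Random(7)
    iris = [IRI(f"http://e.org/n{i}") for i in range(6)]
    preds = [IRI(f"http://e.org/p{i}") for i in range(3)]
    for _ in range(200):
        g = Graph(
            Triple(rng.choice(iris), rng.choice(preds), rng.choice(iris + [Literal(str(rng.randint(0, 3)))]))
            for _ in range(rng.randint(0, 30))
        )
        varpool = [Variable(n) for n in "xyz"]
        pats = []
        for _ in range(rng.randint(1, 2)):
            pats.append(
                TriplePattern(
                    rng.choice(iris + varpool),
                    rng.choice(preds + varpool),
                    rng.choice(iris + varpool),
                )
            )
        variables = tuple({v for p in pats for v in p.variables()})
        q = Query(variables=variables, bgp=tuple(pats))
        assert match_bgp(g, q) == brute_force_bgp(g, q)


def test_monotonicity_adding_triples_never_removes_solutions():
    rng = random.Random(3)
    iris = [IRI(f"http://e.org/n{i}") for i in range(5)]
    preds = [IRI(f"http://e.org/p{i}") for i in range(2)]
    base = Graph(
        Triple(rng.choice(iris), rng.choice(preds), rng.choice(iris)) for _ in range(15)
    )
    x, y = Variable("x"), Variable("y")
    q = Query(variables=(x, y), bgp=(TriplePattern(x, preds[0], y),))
    before = match_bgp(base, q).as_multiset()
    bigger = Graph(set(base) | {Triple(iris[0], preds[0], iris[4])})
    after = match_bgp(bigger, q).as_multiset()
    assert all(after[k] >= v for k, v in before.items())


def test_limit_and_distinct_semantics():
    g = Graph(
        Triple(IRI(f"http://e.org/s{i}"), IRI("http://e.org/p"), Literal("same"))
        for i in range(5)
    )
    v = Variable("v")
    s = Variable("s")
    limited = match_bgp(g, Query(variables=(s,), bgp=(TriplePattern(s, IRI("http://e.org/p"), v),), limit=3))
    assert len(limited) == 3
    distinct = match_bgp(g, Query(variables=(v,), bgp=(TriplePattern(s, IRI("http://e.org/p"), v),), distinct=True))
    assert len(distinct) == 1


def test_label_lookup_finds_unique_gene(fx):
    """A label-constrained pattern isolates the one gene carrying it."""
    from genefed.vocab import LABEL

    g = Variable("g")
    q = Query(variables=(g,), bgp=(TriplePattern(g, LABEL, Literal("HBB-Y")),))
    result = match_bgp(fx.orth_graph, q)
    assert len(result) == 1
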