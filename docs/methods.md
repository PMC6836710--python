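# Methods

This note records the model behind each layer, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical and
design choices made where more than one answer was defensible.

## The integration model

Three stores hold complementary slices of biology in three storage models:
expression calls in a relational database, orthology in hierarchical
orthologous groups, protein knowledge in RDF.  The package makes them
jointly queryable with one conjunctive query language by

1. exposing the relational store as a **virtual RDF graph** through
   declarative source/target mappings (OBDA), so nothing is duplicated;
2. minting instance IRIs **once** and reusing them verbatim across stores
   (genes shared by expression and orthology, proteins by orthology and
   protein store, taxa by all three) instead of asserting `sameAs` bridges;
3. describing those intersections formally as **virtual links** in an
   extended-VoID vocabulary, which the federation planner treats as the
   only legitimate cross-dataset join points;
4. decomposing a query into per-endpoint stages executed with **bind
   joins**, so intermediate results are bounded by what earlier, more
   selective stages produce.

## Query dialect and evaluation

The SPARQL subset is `SELECT [DISTINCT] … WHERE { patterns, FILTER(=, !=,
<, >, CONTAINS), SERVICE <iri> {…} } LIMIT n`.  It covers every construct
the 13 shipped templates need while staying small enough that the
evaluator can be checked against exhaustive assignment enumeration
(property-tested on random graphs).  Anything outside the subset is
rejected with an explicit "unsupported feature" error — silently ignoring
an `OPTIONAL` would change semantics invisibly.

Evaluation choices: `<`/`>` compare numerically when both operands parse as
decimals and lexicographically otherwise; `CONTAINS` is case-insensitive,
because disease-keyword search over free-text annotation comments is its
use; solution order is unspecified and all comparisons are multiset
comparisons; an unbound filter variable eliminates the solution (SPARQL
error semantics).  `LIMIT` truncates an unspecified order, so equivalence
tests always use limits larger than the result sets they compare.

## OBDA engine

A mapping rule's `source` is an ANSI-subset SELECT executed on the embedded
SQLite database; its `target` is a list of triple templates with `{column}`
placeholders and optional named transformations (`{anatEntityId|uberon}`).
Virtual answering unifies each triple pattern against each template:
constant-vs-constant slots must match, pattern constants over placeholder
slots become SQL `WHERE` constraints when the template is invertible
(single placeholder, invertible transformation, prefix/suffix match) and
post-filters otherwise, and the per-pattern candidate bindings are
deduplicated — each then corresponds to exactly one distinct matching
triple of the materialization, which is what makes the virtual route agree
with materialize-then-match *as a multiset*.  NULL in any referenced
column suppresses that one triple (R2RML-style); placeholder values in IRI
templates are percent-encoded; pushed-down constants are compared against
`CAST(col AS TEXT)` so integer keys (taxon identifiers) join with their
IRI text form.

The `uberon` transformation (CURIE colon → underscore) is registered with
an exact inverse; genus+species concatenation is not inverted — a constant
scientific name in a query is handled by post-filtering that rule's rows,
trading speed for unconditional correctness at this scale.

## Orthology

A HOG is a tree whose internal nodes carry speciation or duplication
events and whose leaves are genes.  `derive_pairwise` labels every leaf
pair with the event at its lowest common ancestor by classifying
cross-child pairs at each node — which visits each pair exactly once, so
the ortholog/paralog partition is a theorem of the traversal, and is
additionally property-tested against an independent path-based LCA oracle.
One ortholog property is emitted regardless of one-to-one vs many-to-many
multiplicity; no shipped query distinguishes them.  Clade restriction
keeps a pair when either member's taxon falls in the clade set — the
filter's role is to shrink the orthology stage before a join, and the
clade vocabulary is expressed as explicit taxon-to-clade membership
triples because the dialect has no value lists.

## Virtual links and federation

Link discovery intersects class extensions (shared-instance links; blank
nodes are excluded as document-scoped) and literal value sets over a
configured candidate predicate list — label-like and identifier-like
predicates only, since all-pairs literal comparison is quadratic and
mostly noise.  Revalidation recounts each link: zero intersection flips it
to `broken`; shrunk-but-nonzero stays `active` (data evolution, not schema
drift); an unreachable endpoint yields `unverified` rather than a false
`broken`.

The planner assigns each pattern to a dataset whose description covers its
predicate (or class, for type patterns), breaking ties toward the dataset
already holding the most patterns to maximize sub-query size.  Stages are
ordered greedily: most selective first (selectivity score = constant terms
plus applicable filters — no statistics, by design), then repeatedly the
most selective remaining stage that shares a **link-covered** variable
with the stages already planned.  A variable is link-covered when an
active shared-instance link's class is inferable for it on both sides
(from explicit type patterns or per-predicate subject/object-class
signatures recorded in the dataset descriptions), or when a literal-match
link's predicates bind it on both sides.  If no remaining stage joins, the
plan is rejected with a "missing virtual link" error naming the datasets —
removing or breaking a link can turn a plannable query into that error but
can never silently change results.

Execution ships the distinct join-variable tuples of the accumulated
solutions into the next stage in batches (default 50) as enumerated value
constraints.  Because each stage solution binds its join variables to
exactly one tuple, batches partition the work and the result is invariant
under batch size — asserted for sizes 1/10/100.  A configurable
intermediate-result cap (default 10 000 bindings) aborts with advice to
refine the query; the one structural lesson the stack teaches is that
specificity, not engine cleverness, bounds federated cost.  Explicit
`SERVICE` blocks pin their patterns to an endpoint and bypass source
selection; everything else is planned identically.

## Synthetic data: what it emulates, and what not

The generator produces up to 8 species (human, chimpanzee, macaque, mouse,
rat, rabbit, zebrafish, fruit fly — the organisms the template catalogue
names), 8 genes per species, 6 anatomical entities (brain, liver,
pancreas, heart, kidney, lung as UBERON terms), 4 developmental stages
(including an infant stage, needed by the stage-constrained template), and
6 random HOGs, with per-gene-per-tissue call probabilities
`p_expressed = 0.3`, `p_absent = 0.1`, `p_high = 0.1`, protein coverage
`p_protein = 0.8` and disease-annotation probability 0.3 over a five-term
vocabulary.  These sizes keep every store in the hundreds of triples —
large enough that joins and randomized equivalence checks are non-trivial,
small enough that the naive oracle evaluates everything quickly.

A fixed cast of well-known genes (INS, HBB-Y, Tp53 with a rat duplicate,
a fly gene with cross-species orthologs, GCG, APP, EGFR) is planted with
deterministic expression calls and annotations so that each of the 13
templates has at least one answer *by construction* at any seed; the rest
is seeded randomness, byte-identically reproducible for a given seed.

What the fixtures deliberately do not model: real expression levels or
Bgee's rank-based call criteria (calls are explicit `present`/`absent`
columns, because upstream databases differ in exactly those criteria),
real UBERON/taxonomy coverage beyond the handful of needed terms, gene
name synonymy, and endpoint latency or partial failure beyond a binary
up/down.  Passing tests therefore certify the *logic* of mapping,
derivation, linking and federation — not performance or robustness against
the messiness of production data.

One data-design constraint matters for the equivalence contracts: triples
that more than one store can answer (gene typing, labels and taxon links in
both expression and orthology stores; taxon names in expression and
protein stores) are identical by construction, so pattern-to-store
assignment never changes answers.  The randomized federated-query
generator and the template catalogue stay within that contract; a query
over genuinely divergent replicas is out of scope.

## Worked example

The motivating instance is hand-written, not sampled: three human genes
carry a glioblastoma annotation, two of them have rat orthologs, and
exactly one ortholog has a present call in rat brain, so the query's
answer is one pair; with liver substituted for brain the answer is empty
because the only liver-expressed rat gene has no disease-annotated
ortholog.  The expected answer is declared next to the instance and the
tests compare engine output against it, not against a recomputation.

## Known limitations

- The SPARQL subset has no OPTIONAL/UNION/aggregates/property paths and no
  variable predicates in federation; the planner's coverage inference uses
  most-common-class signatures and can be conservative on mixed-domain
  predicates.
- Bind joins are semantically, not physically, pushed down on the OBDA
  endpoint (value constraints are applied after per-pattern SQL), which is
  fine at fixture scale but not a performance claim.
- The extended-VoID vocabulary is project-minted and self-contained; it
  models only the constructs the federation consumes (kind, predicates or
  class, transformation, cardinality, status).
- The literal-match discovery default list is label-like predicates; links
  through arbitrary computed literals require registering the predicate
  pair explicitly.
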