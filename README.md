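# genefed

Federated semantic queries over heterogeneous biological databases, at desk
scale.  The package re-creates, as a self-contained library and CLI, an
ontology-driven data-integration architecture in which three stores that
disagree about everything — a **relational gene-expression database**
(Bgee-like), an **orthology store** of hierarchical orthologous groups
(OMA-like), and an **RDF protein store** (UniProt-like) — are queried
jointly with one conjunctive query language, without duplicating any data.

It is aimed at people studying or prototyping ontology-based data access
(OBDA), federated SPARQL processing and dataset-interlink metadata, who
want a small, fully verifiable stack instead of a production deployment.

## What is inside

- **`rdf_core`** (`terms`, `io`, `sparql`, `evaluate`): a minimal RDF model,
  N-Triples/Turtle-subset I/O with canonical sorted output, a restricted
  SPARQL dialect (`SELECT`/`DISTINCT`/`FILTER` with `=`, `!=`, `<`, `>`,
  `CONTAINS`/`SERVICE`/`LIMIT`), and a naive evaluator that is the
  correctness oracle for everything else.
- **`obda`** (`mappings`, `transforms`, `obda`): declarative
  `mappingId / source / target` rules expose the relational database as a
  virtual RDF graph.  Triple patterns are answered on the fly by unifying
  against the triple templates and pushing invertible constants down into
  SQL; `materialize()` is the explicit alternative.  Identifier rewriting
  (`UBERON:0000955` → `…/UBERON_0000955`) and genus+species concatenation
  (`"Homo" + "sapiens"` → `"Homo sapiens"`) produce the cross-store join
  keys byte-for-byte.
- **`orthology`**: hierarchical orthologous groups (HOGs).  A leaf pair is
  orthologous iff its lowest common ancestor is a speciation event,
  paralogous iff a duplication; `derive_pairwise` classifies every pair
  exactly once and `emit_orth_graph` serializes genes, taxa, protein
  cross-references and symmetric relation assertions.
- **`voidext`**: *virtual links* — intersection data points between two
  datasets (shared class instances, or matching literals under a predicate
  pair) — discovered from data, described in an extended-VoID RDF
  vocabulary, round-tripped, and revalidated against live endpoints
  (zero intersection ⇒ `broken`, unreachable endpoint ⇒ `unverified`).
- **`federation`**: source selection from dataset descriptions, planning by
  a constant-counting selectivity heuristic, and bind-join execution that
  ships accumulated bindings into later stages as enumerated value
  constraints.  A plan is only accepted where every cross-dataset join
  rides a declared, active virtual link.
- **`fixtures`** / **`ground_truth`**: a seeded generator for the three
  coupled stores (with planted, well-known genes so every catalogue query
  is answerable) plus an independent brute-force ground-truth path; and a
  fixed, hand-written instance of the motivating question.
- **`catalogue`** / **`cli`**: 13 plain-English query templates with
  editable slots (12 federated-query analogues plus the motivating
  example), keyword search, and a thin `genefed` command with verbs
  `make-fixtures`, `materialize`, `query`, `derive-orthology`,
  `discover-links`, `validate-links`, `fedquery`, `templates`, `status`.

## Worked example

The motivating question: *which human genes have a known association to
glioblastoma and an ortholog expressed in the rat brain?*

```bash
python examples/04_federated_motivating_query.py
```

prints

```
plan (most selective stage first):
  stage 1: uniprot  5 patterns, selectivity score 9
  stage 2: oma      3 patterns, selectivity score 4
  stage 3: bgee     1 patterns, selectivity score 2

1 human-rat pair(s):
  protein PWE001 -> rat ortholog 10116_Egfr

same query with liver instead of brain: 0 pairs
```

The disease-constrained protein stage carries the most constants and runs
first; its bindings are shipped into the orthology stage (joined on shared
protein instances) and then into the expression stage (joined on shared
gene instances).  On the hand-written instance exactly one of the three
glioblastoma-annotated human genes has a rat ortholog with a present
expression call in brain, so exactly one pair comes back — and swapping the
anatomical term away from brain yields none.

The same machinery runs from the shell:

```bash
genefed templates search disease
genefed fedquery --template Q12 --seed 42
genefed templates run Q5 --param clade=http://example.org/genefed/clade/Primates
```

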