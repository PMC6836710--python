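"""The motivating question, end to end on the hand-written instance:

    Which human genes have a known association to glioblastoma AND an
    ortholog expressed in the rat brain?

Three stores must cooperate: disease annotations live with the proteins,
orthology with the gene families, expression calls with the anatomical
data.  The planner splits the query on the declared virtual links, runs the
disease-constrained stage first and ships its bindings into the next
stages as bind joins.
"""

from genefed.catalogue import load_shipped_catalogue, render
from genefed.federation import execute, plan
from genefed.fixtures import worked_example

we = worked_example()
q12 = next(t for t in load_shipped_catalogue() if t.id == "Q12")
query = render(q12)  # defaults: glioblastoma / human / rat / brain

p = plan(query, meta=we.meta)
print("plan (most selective stage first):")
for i, stage in enumerate(p.stages, 1):
    print(f"  stage {i}: {stage.endpoint.rsplit('/', 1)[1]:8s} "
          f"{len(stage.bgp)} patterns, selectivity score {stage.score}")

result = execute(p, we.endpoints)
print(f"\n{len(result)} human-rat pair(s):")
for sol in result:
    protein, gene = (str(v) for v in sol.values())
    print(f"  protein {protein.rsplit('/', 1)[1]} -> rat ortholog {gene.rsplit('/', 1)[1]}")
# Exactly one pair by construction: of the three glioblastoma-annotated
# human genes, only EGFR has a rat ortholog with a present call in brain.

liver = render(q12, {"anat": "http://purl.obolibrary.org/obo/UBERON_0002107"})
print(f"\nsame query with liver instead of brain: {len(execute(plan(liver, meta=we.meta), we.endpoints))} pairs")
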