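"""Browse and run the plain-English template catalogue.

Templates pair an editable sentence with its SPARQL equivalent.  Narrowing
a clade slot shows the specificity lesson: a more specific query ships
fewer intermediate bindings and can only shrink the answer.
"""

from genefed.catalogue import load_shipped_catalogue, render, render_nl, search_templates
from genefed.federation import federated_query
from genefed.fixtures import build_fixtures

fx = build_fixtures()
catalogue = load_shipped_catalogue()

print("templates mentioning 'disease':")
for t in search_templates(catalogue, "disease"):
    print(f"  {t.id}: {t.nl_text}")

q5 = next(t for t in catalogue if t.id == "Q5")
broad = federated_query(render(q5), fx.meta, fx.endpoints)
primates = render(q5, {"clade": "http://example.org/genefed/clade/Primates"})
narrow = federated_query(primates, fx.meta, fx.endpoints)
print(f"\northologs of fly-brain genes, any clade: {len(broad)}")
print(f"same template narrowed to primates:      {len(narrow)}")
print(f"narrowed answers are a subset: {narrow.as_set() <= broad.as_set()}")
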