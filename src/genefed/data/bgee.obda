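# Relational-to-RDF mappings exposing the embedded gene-expression database
# as a virtual RDF graph.  Gene and taxon instance IRIs deliberately reuse
# the orthology store's and protein store's IRIs (no sameAs bridging): these
# shared instances are the virtual links the federation joins on.

prefix orth:  <http://purl.org/net/orth#>
prefix up:    <http://purl.uniprot.org/core/>
prefix genex: <http://purl.org/genex#>
prefix obo:   <http://purl.obolibrary.org/obo/>
prefix rdfs:  <http://www.w3.org/2000/01/rdf-schema#>

mappingId gene-class
source    SELECT geneId FROM gene
target    <http://example.org/genefed/gene/{geneId}> a orth:Gene .

mappingId gene-label
source    SELECT geneId, geneName FROM gene
target    <http://example.org/genefed/gene/{geneId}> rdfs:label "{geneName}" .

mappingId gene-taxon
source    SELECT geneId, speciesId FROM gene
target    <http://example.org/genefed/gene/{geneId}> obo:RO_0002162 <http://purl.uniprot.org/taxonomy/{speciesId}> .

mappingId taxon
source    SELECT speciesId, genus, species FROM species
target    <http://purl.uniprot.org/taxonomy/{speciesId}> a up:Taxon ; up:scientificName "{genus} {species}" .

mappingId anat-entity
source    SELECT anatEntityId, name FROM anatEntity
target    <http://purl.obolibrary.org/obo/{anatEntityId|uberon}> a genex:AnatomicalEntity ; rdfs:label "{name}" .

mappingId dev-stage
source    SELECT stageId, name FROM stage
target    <http://purl.obolibrary.org/obo/{stageId|uberon}> a genex:DevelopmentalStage ; rdfs:label "{name}" .

mappingId expressed-in
source    SELECT DISTINCT geneId, anatEntityId FROM expression WHERE callType = 'present'
target    <http://example.org/genefed/gene/{geneId}> genex:isExpressedIn <http://purl.obolibrary.org/obo/{anatEntityId|uberon}> .

mappingId absent-in
source    SELECT DISTINCT geneId, anatEntityId FROM expression WHERE callType = 'absent'
target    <http://example.org/genefed/gene/{geneId}> genex:isAbsentIn <http://purl.obolibrary.org/obo/{anatEntityId|uberon}> .

mappingId highly-expressed-in
source    SELECT DISTINCT geneId, anatEntityId FROM expression WHERE callType = 'present' AND level = 'high'
target    <http://example.org/genefed/gene/{geneId}> genex:isHighlyExpressedIn <http://purl.obolibrary.org/obo/{anatEntityId|uberon}> .

mappingId expression-condition
source    SELECT DISTINCT anatEntityId, stageId FROM expression WHERE callType = 'present'
target    <http://example.org/genefed/condition/{anatEntityId}-{stageId}> a genex:ExpressionCondition ; genex:hasAnatomicalEntity <http://purl.obolibrary.org/obo/{anatEntityId|uberon}> ; genex:hasDevelopmentalStage <http://purl.obolibrary.org/obo/{stageId|uberon}> .

mappingId expressed-in-condition
source    SELECT DISTINCT geneId, anatEntityId, stageId FROM expression WHERE callType = 'present'
target    <http://example.org/genefed/gene/{geneId}> genex:isExpressedInCondition <http://example.org/genefed/condition/{anatEntityId}-{stageId}> .
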