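# Default ontology-mapping registry: prefixes, content-type classes,
# field predicates. Override with a file of the same shape via --registry.
class_map:
  bioassay: obo:OBI_0000070
  biomaterial: obo:OBI_0100051
  citation: bibo:Article
  experiment: obo:OBI_0000066
  person: foaf:Person
  replicate: efo:EFO_0000683
predicate_map:
  bioassay.name: dc:title
  bioassay.platform: sx:platform
  bioassay.protocol: sx:protocol
  bioassay.raw_data_files: sx:raw_data_file
  bioassay.replicates: obo:OBI_0000293
  biomaterial.cell_line: obo:CLO_0000031
  biomaterial.cell_type: obo:CL_0000000
  biomaterial.developmental_stage: efo:EFO_0000399
  biomaterial.disease_state: obo:DOID_4
  biomaterial.name: dc:title
  biomaterial.organism: obo:OBI_0100026
  biomaterial.tissue: obo:UBERON_0001062
  biomaterial.treatment: obo:CHEBI_24431
  citation.authors: dc:creator
  citation.doi: bibo:doi
  citation.journal: dc:source
  citation.pmid: bibo:pmid
  citation.title: dc:title
  citation.year: dc:date
  experiment.assays: ro:has_part
  experiment.citations: dc:references
  experiment.contributors: dc:contributor
  experiment.created: dc:created
  experiment.description: dc:description
  experiment.experimental_factors: sx:experimental_factor
  experiment.external_links: dc:relation
  experiment.measurement_type: sx:measurement_type
  experiment.modified: dc:modified
  experiment.protocol_overview: sx:protocol_overview
  experiment.title: dc:title
  person.name: foaf:name
  replicate.biomaterial: ro:is_a
  replicate.replicate_type: sx:replicate_type
  term.alternative_equivalents: sx:alternative_equivalent
  term.equivalents: ao:preferred_equivalent
  term.label: rdfs:label
prefixes:
  ao: http://purl.org/ontology/ao/core#
  bibo: http://purl.org/ontology/bibo/
  clx: http://example.org/onto/clx/
  dc: http://purl.org/dc/terms/
  efo: http://www.ebi.ac.uk/efo/
  foaf: http://xmlns.com/foaf/0.1/
  obo: http://purl.obolibrary.org/obo/
  owl: http://www.w3.org/2002/07/owl#
  rdf: http://www.w3.org/1999/02/22-rdf-syntax-ns#
  rdfs: http://www.w3.org/2000/01/rdf-schema#
  ro: http://purl.org/obo/owl/ro#
  scx: http://example.org/onto/scx/
  sx: http://example.org/semexp/ns#
  xsd: http://www.w3.org/2001/XMLSchema#
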