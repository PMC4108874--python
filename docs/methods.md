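# Methods

This note documents the data model, the mapping conventions, the query
semantics and the synthetic fixtures behind `semexp`, together with the
design decisions that were genuinely open and the limitations a user
should know about.

## The experiment model

A repository holds experiments, each composed of bioassays; a bioassay is
performed on one or more replicates; a replicate references the biomaterial
that was assayed. The replicate semantics encode the standard distinction:
*technical* replicates of one assay reference the same biomaterial,
*biological* replicates reference pairwise-distinct biomaterials, and
validation enforces exactly that. Biomaterials carry up to seven
controlled-vocabulary annotations — organism, developmental stage, tissue,
cell type, cell line, disease state, treatment — plus free-form key/value
attributes (e.g. passage number). Vocabulary terms map to external
ontology classes: the first entry of a term's `equivalents` list is its
canonical class (emitted as `ao:preferred_equivalent`); further entries are
emitted under a package-namespace `alternative_equivalent` predicate.

Deliberate modelling choices:

* No principal-investigator field; contributors are a flat list of people.
* Visibility (public/private) is set per experiment and inherited by all
  child resources; there are no finer-grained ACLs.
* Cell line is its own annotation attribute, distinct from cell type.
* Replicates are owned by exactly one bioassay. A replicate shared across
  assays would need id-level aliasing; the model forbids it so that minted
  URIs are unambiguous.
* Both `created` and `modified` timestamps are stored and emitted
  (`dc:created`/`dc:modified`) rather than a single ambiguous `dc:date`;
  richer provenance vocabularies (e.g. PAV) are out of scope.
* Identifiers are caller-supplied URL-safe slugs, unique per entity kind
  across the repository, because the minted URI space
  `<base>/<kind>/<id>` is flat per kind.
* Biomaterials live in a repository-level id-indexed collection (parallel
  to people and citations); replicates reference them by id.

## Ontology mappings

The mapping registry is pure data (packaged as `data/registry.yaml`;
`default_registry()` builds the identical object in code, and a test pins
the two together). Core mappings: experiment → `obo:OBI_0000066`
(investigation), assay composition → `ro:has_part`, assay → replicate →
`obo:OBI_0000293`, replicate → biomaterial → `ro:is_a`, organism →
`obo:OBI_0100026`, cell type → `obo:CL_0000000`, person → `foaf:Person`,
term → external class → `ao:preferred_equivalent`.

Two of these deserve a flag. `ro:is_a` as the replicate→biomaterial link is
ontologically odd (it is a specimen-of relation, not subsumption), but it
is the predicate the public query interface expects, and compatibility with
that interface wins; it is a registry entry, so deployments that prefer a
cleaner predicate can override it — at the cost of rewriting their queries.
Likewise the biomaterial annotation predicates are ontology *root classes*
used as predicates (`obo:CL_0000000` for cell type, `obo:OBI_0100026` for
organism); the attributes with no conventional predicate (tissue, cell
line, disease state, treatment, stage) follow the same root-class pattern
(`obo:UBERON_0001062`, `obo:CLO_0000031`, `obo:DOID_4`, `obo:CHEBI_24431`,
`efo:EFO_0000399`) and are equally overridable.

Classes with no universally printed identifier are pinned to defaults and
configurable: bioassay → `obo:OBI_0000070` ("assay"), replicate →
`efo:EFO_0000683` ("replicate"), citation → `bibo:Article`, biomaterial →
`obo:OBI_0100051` ("specimen"). The measurement type is emitted as a
term-valued annotation under a package-namespace predicate: the only
ontology that historically carried some measurement-type terms (the MGED
ontology) is deprecated, so no stable external predicate exists.

The `foaf` namespace is emitted with its standard trailing slash. The
canned mouse/HSC query text reproduces the published prefix block verbatim,
including a slash-less `foaf` prefix that the query body never uses — kept
for fidelity; it cannot affect results.

## RDF generation

Every entity — including replicates and vocabulary terms — gets a minted
URI; there are no blank nodes. This is what makes the rest of the system
simple: DESCRIBE traversal only needs to follow object URIs, and the
public/admin split operates on plain triple sets. Literals are typed
minimally (plain strings; `xsd:dateTime` for timestamps, `xsd:gYear` for
publication years). Generation is deterministic: the same repository
always yields the same triple set, and the N-Triples serializer emits
lexicographically sorted lines so equal graphs are byte-equal.

## The two-store privacy architecture

Two stores, not per-triple ACLs: the public store indexes only graphs whose
visibility is public (it refuses anything else), the admin store indexes
everything and is reachable only with the correct API key (single key,
supplied via environment variable or config file — there are no user
accounts). Consequences that tests verify: the admin store's triples minus
the public store's are exactly the private experiments' RDF, and every
SELECT's public rows are contained in its admin rows. Indexing is
idempotent, so store contents are independent of insertion order and
re-indexing.

The built-in backend is an in-memory `rdflib.Graph` with optional
N-Triples persistence; SPARQL execution is delegated to rdflib's engine
behind a narrow store contract (index/select/describe/save/load) so another
engine can be plugged in. The tests do not take rdflib's answers on faith:
random basic graph patterns are checked against a hand-written brute-force
pattern matcher, and the high-level queries against an object-model filter.
Absent an explicit ORDER BY, result rows are sorted by binding values so
results are reproducible across runs and backends. DESCRIBE returns
outgoing triples only (subject match) — precisely what link-following
traversal needs; a symmetric bounded-description variant would drag in
every sibling of a shared term.

## Ontology ingest and subsumption

`load_ontology` reads RDF/XML, Turtle, N-Triples or OBO flat files
([Term]/id/name/is_a/def/synonym tags) into a snapshot of named classes,
labels and asserted `rdfs:subClassOf` edges. Restriction-valued
superclasses are ignored and no OWL reasoning is performed — subsumption
means asserted is_a reachability, which keeps behaviour identical on any
backend and the oracle trivial. The subclass graph must be acyclic; a cycle
is a load-time error listing one offending cycle. A URI-rewrite map applied
at load time handles identifier drift between ontology releases.

Annotation queries expand a class over its subclass closure by rewriting
the query with an explicit VALUES enumeration. This reproduces exactly what
a SPARQL-1.0-only store can answer; a `rdfs:subClassOf*` property-path
formulation is also supported and the two routes are tested for
equivalence. Conjunctive multi-attribute queries compose constraints on the
same biomaterial within one graph pattern.

## DESCRIBE traversal and sample tables

`describe_traverse` rebuilds a nested experiment record using only
DESCRIBE calls (experiment → assays → replicates → biomaterials → terms),
with children ordered by URI and terms memoised, so the record is
independent of triple insertion order and each entity is fetched once. The
sample table flattens the record to one row per replicate with a fixed,
fully-specified column order (identifiers, then a label/URI column pair per
annotation attribute). The TSV rendering specifies bytes exactly (tab
separators, `\n` endings, no quoting), which is what makes the R client's
output byte-comparable rather than merely semantically equal. The R client
speaks HTTP and SPARQL JSON results only — DESCRIBE results are delivered
as s/p/o bindings — so it needs no RDF parser and forces UTF-8 end to end.

## ISA-Tab export

One investigation file, one study file (a row per distinct biomaterial,
`Characteristics[...]` columns each followed by Term Source REF and Term
Accession Number), and one assay file per bioassay (a row per replicate).
Term Source REF values are ontology identifier prefixes (CLO, EFO, DOID,
NCBITaxon, UBERON, CL, CHEBI) registered in the ONTOLOGY SOURCE REFERENCE
section with their namespace URIs; the accession is the local part of the
external class URI. Only annotation attributes actually used by the
experiment's biomaterials produce columns. The reader reconstructs a
partial repository from an exported directory, and export∘read∘export is
byte-stable — the round-trip test. Protocol parameter chains, factor-value
matrices and ISA-JSON are out of scope.

## Synthetic fixtures

The fixtures are the package's study conditions, not tuning knobs.

* **Mini cell ontology** — 11 classes, 10 edges: cell (`CL_0000000`) >
  hematopoietic stem cell (`CL_0000037`) > myeloid cell (`CL_0000763`,
  with its curated definition) > the eight descendant cell types
  (granulocyte monocyte progenitor cell, megakaryocyte-erythroid progenitor
  cell, mast cell progenitor, myeloblast, monoblast, metamyelocyte,
  myelocyte, promyelocyte). The descendants' real identifiers are not part
  of the packaged knowledge, so they carry synthetic ids in a reserved
  `clx:` namespace with their real labels; the well-known classes use their
  real OBO identifiers. The Turtle emission is hand-ordered and
  byte-stable.
* **Worked example** — one public DNA-methylation (bisulphite sequencing)
  experiment: six assays on K562, LiPS and H1 cell lines at two passages
  each, one biological replicate per assay, biomaterials annotated Human
  (`NCBITaxon_9606`), Blood (`UBERON_0000178`), K562 (`CLO_0007060`),
  H1 (`EFO_0003042`), Myeloid Leukemia (`DOID_8692`), experimental factor
  "cell-line". The LiPS line and the measurement type have no printed
  public identifier and use the reserved `scx:` namespace.
* **Seeded random repositories** — `make_repository(n, public_fraction,
  seed)` draws annotations from a fixed vocabulary pool that includes
  mouse, hematopoietic stem cell and all eight myeloid descendants, so both
  the mouse/HSC query and subsumption queries are non-trivially satisfiable
  at the default sizes. Experiments get 1–3 assays; assays get 1–3
  replicates, technical (shared biomaterial) with probability 0.3,
  biological otherwise; optional annotations are present with attribute-
  specific probabilities of 0.4–0.9. `floor(n·fraction)` experiments are
  public. One `random.Random(seed)` instance drives everything; equal seeds
  give byte-identical repositories.

What the fixtures do *not* emulate: curation noise (typos, missing
mandatory annotations, label drift), multi-experiment sharing of
biomaterials, large ontologies (thousands of classes), non-tree ontology
regions with multiple parentage, or realistic text. Passing tests
demonstrate the correctness of the machinery — mapping, generation,
querying, privacy partitioning, round-trips — on clean data at desk scale;
they say nothing about curation quality or performance on millions of
triples.

## Problem sizes and numerics

Default verification sizes, chosen to exercise every code path while
keeping the whole suite quick: query-fidelity checks use 20 seeded
repositories of 30 experiments; privacy containment uses 100 random
graph patterns per repository over 3 seeds; closure checks use 100 random
DAGs of up to 50 nodes; traversal and ISA-Tab checks cover every experiment
of a 12- and an 8-experiment repository plus the worked example. Stores at
these sizes hold ~1000–2000 triples; the SPARQL-vs-brute-force comparison
is quadratic in pattern count and store size and dominates the runtime.

Tie-breaks and degenerate inputs: validation reports are sorted by
(severity, entity id, message); SELECT rows sort by their N3-rendered
bindings; closures and traversal children sort by URI; an empty repository,
an empty graph, an empty ontology and an assay-less experiment are all
legal and produce empty-but-valid outputs. DESCRIBE of an unknown URI is an
empty graph, not an error; unknown URIs in traversal are a not-found error.

## Known limitations

* No OWL reasoning (equivalence, restrictions); subsumption is asserted
  is_a only, and only is_a is traversed (no part_of/develops_from).
* No SPARQL UPDATE, federation, named graphs or JSON-LD.
* The two-tier model has exactly one API key and two visibility levels.
* ISA-Tab fidelity is limited to the modelled annotations.
* The in-memory store is appropriate for desk-scale graphs (≲10⁶ triples);
  larger deployments should plug in a dedicated engine behind the store
  contract.
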