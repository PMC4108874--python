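# semexp — Semantic Web repositories for genomics experiment metadata

`semexp` is a toolkit for publishing genomics-experiment metadata as Linked
Data. It is aimed at labs and institutions that curate experiment
repositories (in the spirit of GEO/ArrayExpress submissions or an
institutional stem-cell data commons) and want their sample annotations to
be machine-readable, queryable with SPARQL, and interoperable with the
biomedical Semantic Web — without running a full content-management stack.

It provides, as plain Python:

* **An experiment model** — experiment → bioassay → replicate → biomaterial,
  where the experiment (an OBI *investigation*, `obo:OBI_0000066`) is
  composed of assays (`ro:has_part`), each assay runs on technical or
  biological replicates (`obo:OBI_0000293`), and each replicate references
  an annotated biomaterial. Biomaterial attributes (organism, tissue, cell
  type, cell line, disease state, treatment, developmental stage) are
  controlled-vocabulary terms, each mapped to external ontology classes
  (NCBITaxon, UBERON, CL, CLO, EFO, DOID, ChEBI, …) via
  `ao:preferred_equivalent`.
* **Automatic RDF generation** driven by a declarative mapping registry
  (content type → class, field → predicate, CURIE prefix table), with
  deterministic URI minting and no blank nodes.
* **A two-tier triple store + SPARQL endpoint** — a public store holding
  only published experiments behind an open endpoint, and an admin store
  holding everything behind an API key. Privacy is structural: the public
  store never receives private triples.
* **Subsumption-aware queries** — load an ontology, compute subclass
  closures, and expand annotation queries so that "myeloid cell"
  (`CL_0000763`) also finds experiments on myeloblasts, promyelocytes and
  every other descendant type.
* **DESCRIBE-based traversal and sample tables** for analysis clients,
  including a thin R client with byte-identical output.
* **ISA-Tab export** (investigation/study/assay files) with a round-trip
  reader.

## Worked example

```python
from semexp import fixtures, rdfgen, store, query

# a seeded synthetic repository: 30 experiments, half public
repo = fixtures.make_repository(30, public_fraction=0.5, seed=1)
public_graph, all_graph = rdfgen.repository_to_rdf(repo)
pub = store.TripleStore(tier="public")
pub.index(public_graph)

# the canned query: experiments on mouse hematopoietic stem cells
vars_, rows = store.sparql_select(pub, query.mouse_hsc_query())
for (title,) in rows:
    print(title)
```

prints the titles of exactly the public experiments whose biomaterials are
annotated `Mouse` (`obo:NCBITaxon_10090`) **and** `hematopoietic stem cell`
(`obo:CL_0000037`) — for seed 1:

```
Experiment 008: methylation dynamics
Experiment 015: stem cell reprogramming
Experiment 030: lineage commitment
```

Subsumption expansion over the bundled mini cell ontology:

```python
_, snap = fixtures.make_mini_cl()
hits = query.experiments_by_annotation(
    pub, "cell_type", fixtures.MYELOID_CELL, expand=True, snap=snap)
print(len(hits))   # -> 14
```

14 public experiments carry `myeloid cell` or one of its eight descendant
cell types (granulocyte monocyte progenitor cell, myeloblast, …), even
though none of them is annotated with the parent class directly.

DESCRIBE traversal of the worked-example methylation experiment (six
bisulphite-sequencing assays on K562, LiPS and H1 cell lines) flattens into
an analysis-ready table, one row per replicate:

```python
worked = fixtures.make_worked_example()
pg, _ = rdfgen.repository_to_rdf(worked)
s = store.TripleStore(tier="public"); s.index(pg)
rec = query.describe_traverse(s, "http://example.org/experiment/13610")
query.sample_table(rec)[["assay", "replicate_type", "cell_line", "cell_line_uri"]]
```

```
  assay replicate_type cell_line                              cell_line_uri
assay-1     biological      K562 http://purl.obolibrary.org/obo/CLO_0007060
assay-2     biological      K562 http://purl.obolibrary.org/obo/CLO_0007060
assay-3     biological      LiPS    http://example.org/onto/scx/SCX_0000001
...
```

The `cell_line_uri` column carries the external ontology class of each
annotation (K562 → `CLO_0007060`), which is what makes the table joinable
with other Linked Data resources.

## Command line

```
semexp make-fixtures --n 30 --seed 1 --out fx     # repository YAML + mini ontology
semexp validate fx/repository.yaml
semexp index fx/repository.yaml                   # build + persist both store tiers
semexp load-ontology fx/mini_cl.ttl
semexp query --attribute cell_type --class obo:CL_0000763 --expand --ontology fx/mini_cl.ttl
semexp export-rdf fx/repository.yaml --format turtle --tier public --out public.ttl
semexp export-isatab fx/worked_example.yaml 13610 --out isa/
semexp serve --port 8001                          # SPARQL endpoint over the persisted stores
semexp traverse http://example.org/experiment/13610 --format tsv
```

The admin API key is read from the `SEMEXP_API_KEY` environment variable
(or the config file), never from a flag. `GET /sparql?query=…` answers from
the public store; adding an `X-API-Key` header switches to the admin store
(a wrong key gets 403). `GET /resource/<kind>/<id>.rdf` serves an entity's
DESCRIBE graph.

## Repository document schema

Repositories load from YAML (or JSON) with top-level keys `base_uri`,
`vocabularies`, `people`, `citations`, `biomaterials`, `experiments`
(UTF-8). Vocabulary terms carry an ordered `equivalents` list of external
class CURIEs — the first is the preferred equivalent. Biomaterial
annotations reference terms as `{vocabulary, label}` pairs; replicates
reference biomaterials by id. See `tests/test_model.py::MINIMAL_DOC` for a
minimal document and `semexp make-fixtures` for full examples.

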