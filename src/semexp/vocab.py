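"""CURIE/URI handling and the ontology-mapping registry.

The registry is the single piece of configuration that drives RDF
generation: it maps content types (experiment, bioassay, replicate,
biomaterial, person, citation, term) to ontology classes and model fields to
RDF predicates, together with a prefix table for CURIE expansion.  It is
pure data and ships as a packaged YAML file; :func:`default_registry`
constructs the identical registry programmatically.

Notable mapping choices (all overridable via a registry file):

* experiment -> obo:OBI_0000066 (OBI "investigation");
* bioassay -> obo:OBI_0000070 (OBI "assay");
* replicate -> efo:EFO_0000683 (EFO "replicate");
* the experiment/assay composition predicate is ro:has_part and the
  assay/replicate link is obo:OBI_0000293 ("has_specified_input");
* the replicate -> biomaterial link is ro:is_a — semantically odd, but it
  is the predicate the public query interface expects, so compatibility
  wins over ontological purity;
* biomaterial annotation predicates are the ROOT classes of the relevant
  ontologies used as predicates (obo:OBI_0100026 for organism,
  obo:CL_0000000 for cell type, and analogous roots for the attributes the
  query interface does not pin down);
* a local vocabulary term points to its canonical external class via
  ao:preferred_equivalent; additional equivalents use a package-namespace
  predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .model import Repository, Term, TermRef

__all__ = [
    "PrefixTable",
    "MappingRegistry",
    "CurieError",
    "expand_curie",
    "compress_uri",
    "default_registry",
    "load_registry",
    "resolve_term",
    "REQUIRED_PREFIXES",
]

#: Namespace for predicates/classes this package must define itself because
#: no printed mapping exists for them (platform, raw data files, ...).
APP_NS = "http://example.org/semexp/ns#"

#: Reserved namespaces for synthetic fixture identifiers (ontology classes
#: that exist in the real world but whose identifiers are not part of the
#: packaged knowledge, e.g. the mini cell-ontology descendant classes).
CLX_NS = "http://example.org/onto/clx/"
SCX_NS = "http://example.org/onto/scx/"

REQUIRED_PREFIXES = {
    "obo": "http://purl.obolibrary.org/obo/",
    "efo": "http://www.ebi.ac.uk/efo/",
    "ro": "http://purl.org/obo/owl/ro#",
    "dc": "http://purl.org/dc/terms/",
    "ao": "http://purl.org/ontology/ao/core#",
    "foaf": "http://xmlns.com/foaf/0.1/",
}


class CurieError(KeyError):
    """Unknown prefix or malformed CURIE."""


@dataclass
class PrefixTable:
    prefixes: dict[str, str] = field(default_factory=dict)

    def __contains__(self, prefix: str) -> bool:
        return prefix in self.prefixes

    def __getitem__(self, prefix: str) -> str:
        return self.prefixes[prefix]

    def items(self):
        return self.prefixes.items()


def expand_curie(curie: str, prefixes: PrefixTable) -> str:
    """Expand ``prefix:local`` to a full URI.

    Strings that are already absolute http(s) URIs (or wrapped in angle
    brackets) pass through unchanged, so term equivalents may be stored in
    either form.
    """
    if curie.startswith("<") and curie.endswith(">"):
        return curie[1:-1]
    if curie.startswith("http://") or curie.startswith("https://"):
        return curie
    if ":" not in curie:
        raise CurieError(f"not a CURIE: {curie!r}")
    prefix, local = curie.split(":", 1)
    if prefix not in prefixes:
        raise CurieError(f"unknown CURIE prefix {prefix!r}")
    return prefixes[prefix] + local


def compress_uri(uri: str, prefixes: PrefixTable) -> str:
    """Compress a URI to a CURIE using the longest matching namespace.

    Falls back to ``<uri>`` when no registered namespace is a prefix of the
    URI.  ``compress_uri(expand_curie(c)) == c`` for every CURIE over the
    table.
    """
    best: tuple[str, str] | None = None
    for prefix, ns in prefixes.items():
        if uri.startswith(ns) and (best is None or len(ns) > len(best[1])):
            best = (prefix, ns)
    if best is None:
        return f"<{uri}>"
    prefix, ns = best
    return f"{prefix}:{uri[len(ns):]}"


@dataclass
class MappingRegistry:
    """Content-type -> class and (content-type, field) -> predicate mappings."""

    class_map: dict[str, str]
    predicate_map: dict[tuple[str, str], str]
    prefix_table: PrefixTable

    def class_uri(self, content_type: str) -> str:
        return expand_curie(self.class_map[content_type], self.prefix_table)

    def predicate_uri(self, content_type: str, field_name: str) -> str:
        key = (content_type, field_name)
        if key not in self.predicate_map:
            raise KeyError(f"no predicate mapping for {content_type}.{field_name}")
        return expand_curie(self.predicate_map[key], self.prefix_table)


def _default_data() -> dict:
    prefixes = {
        **REQUIRED_PREFIXES,
        "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
        "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
        "xsd": "http://www.w3.org/2001/XMLSchema#",
        "owl": "http://www.w3.org/2002/07/owl#",
        "bibo": "http://purl.org/ontology/bibo/",
        "sx": APP_NS,
        "clx": CLX_NS,
        "scx": SCX_NS,
    }
    class_map = {
        "experiment": "obo:OBI_0000066",
        "bioassay": "obo:OBI_0000070",
        "replicate": "efo:EFO_0000683",
        "biomaterial": "obo:OBI_0100051",
        "person": "foaf:Person",
        "citation": "bibo:Article",
    }
    predicate_map = {
        "experiment.title": "dc:title",
        "experiment.description": "dc:description",
        "experiment.created": "dc:created",
        "experiment.modified": "dc:modified",
        "experiment.contributors": "dc:contributor",
        "experiment.citations": "dc:references",
        "experiment.external_links": "dc:relation",
        "experiment.assays": "ro:has_part",
        "experiment.measurement_type": "sx:measurement_type",
        "experiment.protocol_overview": "sx:protocol_overview",
        "experiment.experimental_factors": "sx:experimental_factor",
        "bioassay.name": "dc:title",
        "bioassay.platform": "sx:platform",
        "bioassay.protocol": "sx:protocol",
        "bioassay.replicates": "obo:OBI_0000293",
        "bioassay.raw_data_files": "sx:raw_data_file",
        "replicate.replicate_type": "sx:replicate_type",
        "replicate.biomaterial": "ro:is_a",
        "biomaterial.name": "dc:title",
        "biomaterial.organism": "obo:OBI_0100026",
        "biomaterial.developmental_stage": "efo:EFO_0000399",
        "biomaterial.tissue": "obo:UBERON_0001062",
        "biomaterial.cell_type": "obo:CL_0000000",
        "biomaterial.cell_line": "obo:CLO_0000031",
        "biomaterial.disease_state": "obo:DOID_4",
        "biomaterial.treatment": "obo:CHEBI_24431",
        "person.name": "foaf:name",
        "citation.title": "dc:title",
        "citation.authors": "dc:creator",
        "citation.journal": "dc:source",
        "citation.year": "dc:date",
        "citation.doi": "bibo:doi",
        "citation.pmid": "bibo:pmid",
        "term.label": "rdfs:label",
        "term.equivalents": "ao:preferred_equivalent",
        "term.alternative_equivalents": "sx:alternative_equivalent",
    }
    return {"prefixes": prefixes, "class_map": class_map, "predicate_map": predicate_map}


def _registry_from_data(data: dict) -> MappingRegistry:
    table = PrefixTable(dict(data["prefixes"]))
    missing = [p for p, ns in REQUIRED_PREFIXES.items() if table.prefixes.get(p) != ns]
    if missing:
        raise ValueError(f"registry prefix table is missing required prefixes: {missing}")
    predicate_map = {}
    for key, curie in data["predicate_map"].items():
        ctype, fname = key.split(".", 1)
        predicate_map[(ctype, fname)] = curie
    registry = MappingRegistry(
        class_map=dict(data["class_map"]),
        predicate_map=predicate_map,
        prefix_table=table,
    )
    # fail fast on any CURIE that does not expand
    for curie in list(registry.class_map.values()) + list(predicate_map.values()):
        expand_curie(curie, table)
    return registry


def default_registry() -> MappingRegistry:
    """The packaged default registry, constructed programmatically."""
    return _registry_from_data(_default_data())


def load_registry(path: str | None = None) -> MappingRegistry:
    """Load a registry from a YAML file (default: the packaged config)."""
    if path is None:
        text = resources.files("semexp").joinpath("data/registry.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return _registry_from_data(yaml.safe_load(text))


class TermNotFound(LookupError):
    pass


def resolve_term(repo: Repository, vocabulary: str, label: str) -> Term:
    """Exact, case-sensitive term lookup.

    Raises ``KeyError`` for an unknown vocabulary and :class:`TermNotFound`
    for an unknown label within a known vocabulary.
    """
    if vocabulary not in repo.vocabularies:
        raise KeyError(f"unknown vocabulary {vocabulary!r}")
    term = repo.resolve(TermRef(vocabulary, label))
    if term is None:
        raise TermNotFound(f"no term {label!r} in vocabulary {vocabulary!r}")
    return term
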