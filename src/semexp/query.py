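"""High-level query builders over an indexed store.

Three access patterns are provided:

* **Annotation queries** (:func:`experiments_by_annotation`) — find the
  experiments whose biomaterials are annotated with a given external
  ontology class, optionally expanded over the class's subclass closure so
  that a query for "myeloid cell" also matches every descendant cell type.
  Expansion is implemented by rewriting the query with an explicit VALUES
  enumeration of the closure, which behaves identically on any SPARQL
  backend (including SPARQL-1.0-only stores); a property-path formulation
  (``rdfs:subClassOf*`` against the indexed ontology) is available as an
  independent execution route.
* **The canned mouse/HSC query** (:func:`mouse_hsc_query`) — the reference
  SELECT that finds experiments done on mouse hematopoietic stem cells by
  walking experiment → assay → replicate → biomaterial → term →
  preferred-equivalent chains.
* **DESCRIBE traversal** (:func:`describe_traverse`) — rebuild a nested
  experiment record purely from successive DESCRIBE calls, the pattern a
  thin analysis client uses; :func:`sample_table` flattens the record into
  one row per replicate for downstream statistics.
"""

from __future__ import annotations

import pandas as pd

from .model import BIOMATERIAL_ANNOTATION_FIELDS
from .ontoload import OntologySnapshot, subclass_closure
from .store import TripleStore, sparql_describe, sparql_select
from .vocab import MappingRegistry, default_registry

__all__ = [
    "experiments_by_annotation",
    "mouse_hsc_query",
    "describe_traverse",
    "sample_table",
    "sample_table_tsv",
    "SAMPLE_TABLE_COLUMNS",
]

_RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
_RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
_RDFS_SUBCLASSOF = "http://www.w3.org/2000/01/rdf-schema#subClassOf"


def _normalize_attribute(attribute: str) -> str:
    attr = attribute.strip().lower().replace(" ", "_").replace("-", "_")
    if attr not in BIOMATERIAL_ANNOTATION_FIELDS:
        raise KeyError(
            f"unknown biomaterial attribute {attribute!r}; valid attributes: "
            + ", ".join(BIOMATERIAL_ANNOTATION_FIELDS)
        )
    return attr


def _chain_bgp(registry: MappingRegistry) -> str:
    return (
        f"?experiment a <{registry.class_uri('experiment')}> ;\n"
        f"    <{registry.predicate_uri('experiment', 'title')}> ?title ;\n"
        f"    <{registry.predicate_uri('experiment', 'assays')}> ?bioassay .\n"
        f"  ?bioassay <{registry.predicate_uri('bioassay', 'replicates')}> ?replicate .\n"
        f"  ?replicate <{registry.predicate_uri('replicate', 'biomaterial')}> ?biomaterial .\n"
    )


def experiments_by_annotation(
    store: TripleStore,
    attribute: str,
    class_uri: str,
    expand: bool = False,
    snap: OntologySnapshot | None = None,
    registry: MappingRegistry | None = None,
    extra: list[tuple[str, str]] | None = None,
    method: str = "values",
) -> list[tuple[str, str]]:
    """Experiments with a biomaterial whose ``attribute`` term maps into ``class_uri``.

    With ``expand`` on, matches any class in the subclass closure of
    ``class_uri`` per the supplied ontology snapshot.  ``extra`` adds
    further (attribute, class URI) constraints conjunctively in the same
    graph pattern (no expansion on those).  Returns DISTINCT
    (experiment URI, title) pairs sorted by URI.

    ``method="values"`` enumerates the closure in a VALUES clause;
    ``method="path"`` instead uses a ``rdfs:subClassOf*`` property path and
    requires the ontology to be indexed into the same store.
    """
    registry = registry or default_registry()
    attr = _normalize_attribute(attribute)
    pref_eq = registry.predicate_uri("term", "equivalents")
    parts = [_chain_bgp(registry)]

    if method == "path":
        parts.append(
            f"  ?biomaterial <{registry.predicate_uri('biomaterial', attr)}> ?term0 .\n"
            f"  ?term0 <{pref_eq}> ?class0 .\n"
        )
        if expand:
            parts.append(f"  ?class0 <{_RDFS_SUBCLASSOF}>* <{class_uri}> .\n")
        else:
            parts.append(f"  FILTER(?class0 = <{class_uri}>)\n")
    elif method == "values":
        if expand:
            if snap is None:
                raise ValueError("expand=True requires an ontology snapshot")
            members = subclass_closure(snap, class_uri, include_root=True)
        else:
            members = [class_uri]
        values = " ".join(f"<{m}>" for m in members)
        parts.append(
            f"  ?biomaterial <{registry.predicate_uri('biomaterial', attr)}> ?term0 .\n"
            f"  ?term0 <{pref_eq}> ?class0 .\n"
            f"  VALUES ?class0 {{ {values} }}\n"
        )
    else:
        raise ValueError(f"unknown method {method!r}; expected 'values' or 'path'")

    for i, (xattr, xclass) in enumerate(extra or [], start=1):
        xa = _normalize_attribute(xattr)
        parts.append(
            f"  ?biomaterial <{registry.predicate_uri('biomaterial', xa)}> ?term{i} .\n"
            f"  ?term{i} <{pref_eq}> <{xclass}> .\n"
        )

    query = "SELECT DISTINCT ?experiment ?title WHERE {\n  " + "".join(parts) + "}"
    _, rows = sparql_select(store, query)
    return sorted((str(uri), str(title)) for uri, title in rows)


#: The reference query for "experiments done on mouse hematopoietic stem
#: cells", reproduced exactly as the public endpoint documents it (the foaf
#: prefix is declared but unused, and printed without a trailing slash —
#: kept as-is for fidelity; the generated RDF itself uses the standard foaf
#: namespace with the trailing slash).
_MOUSE_HSC_QUERY = """\
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX ro: <http://purl.org/obo/owl/ro#>
PREFIX dc: <http://purl.org/dc/terms/>
PREFIX ao: <http://purl.org/ontology/ao/core#>
PREFIX foaf: <http://xmlns.com/foaf/0.1>
SELECT DISTINCT ?title WHERE {
 ?experiment a obo:OBI_0000066 ;
   dc:title ?title ;
   ro:has_part ?bioassay .
 ?bioassay obo:OBI_0000293 ?replicate .
 ?replicate ro:is_a ?biomaterial .
 ?biomaterial obo:CL_0000000 ?cell_type .
 ?cell_type ao:preferred_equivalent obo:CL_0000037 .
 ?biomaterial obo:OBI_0100026 ?organism .
 ?organism ao:preferred_equivalent obo:NCBITaxon_10090 .
}
"""


def mouse_hsc_query() -> str:
    """The canned mouse + hematopoietic-stem-cell SELECT (byte-stable text)."""
    return _MOUSE_HSC_QUERY


# --------------------------------------------------------------------------
# DESCRIBE-based traversal


def _describe_map(store: TripleStore, uri: str) -> dict[str, list[str]]:
    """DESCRIBE a URI and fold the result into predicate -> object values."""
    out: dict[str, list[str]] = {}
    for _, p, o in sparql_describe(store, uri).graph:
        out.setdefault(str(p), []).append(str(o))
    for vals in out.values():
        vals.sort()
    return out


def _first(d: dict[str, list[str]], pred: str) -> str:
    vals = d.get(pred)
    return vals[0] if vals else ""


def describe_traverse(
    store: TripleStore,
    experiment_uri: str,
    registry: MappingRegistry | None = None,
) -> dict:
    """Rebuild a nested experiment record purely from DESCRIBE calls.

    Follows the composition chain experiment → assay → replicate →
    biomaterial → term, issuing one DESCRIBE per entity (terms are
    memoised) and never touching the store any other way.  Children are
    ordered by URI, so the record is independent of triple insertion
    order.  Raises ``KeyError`` if the experiment URI is absent.
    """
    registry = registry or default_registry()
    p = registry.predicate_uri

    exp_d = _describe_map(store, experiment_uri)
    if not exp_d:
        raise KeyError(f"no such resource in store: {experiment_uri}")

    term_cache: dict[str, dict] = {}

    def term_record(term_uri: str) -> dict:
        if term_uri not in term_cache:
            d = _describe_map(store, term_uri)
            term_cache[term_uri] = {
                "uri": term_uri,
                "label": _first(d, _RDFS_LABEL),
                "class_uri": _first(d, p("term", "equivalents")),
            }
        return term_cache[term_uri]

    def biomaterial_record(bm_uri: str) -> dict:
        d = _describe_map(store, bm_uri)
        annotations = {}
        for attr in BIOMATERIAL_ANNOTATION_FIELDS:
            term_uris = d.get(p("biomaterial", attr), [])
            if term_uris:
                annotations[attr] = term_record(term_uris[0])
        return {"uri": bm_uri, "name": _first(d, p("biomaterial", "name")), "annotations": annotations}

    assays = []
    for assay_uri in sorted(exp_d.get(p("experiment", "assays"), [])):
        a_d = _describe_map(store, assay_uri)
        replicates = []
        for rep_uri in sorted(a_d.get(p("bioassay", "replicates"), [])):
            r_d = _describe_map(store, rep_uri)
            bm_uri = _first(r_d, p("replicate", "biomaterial"))
            replicates.append(
                {
                    "uri": rep_uri,
                    "replicate_type": _first(r_d, p("replicate", "replicate_type")),
                    "biomaterial": biomaterial_record(bm_uri) if bm_uri else None,
                }
            )
        assays.append(
            {
                "uri": assay_uri,
                "name": _first(a_d, p("bioassay", "name")),
                "platform": _first(a_d, p("bioassay", "platform")),
                "raw_data_files": a_d.get(p("bioassay", "raw_data_files"), []),
                "replicates": replicates,
            }
        )

    return {
        "uri": experiment_uri,
        "title": _first(exp_d, p("experiment", "title")),
        "description": _first(exp_d, p("experiment", "description")),
        "created": _first(exp_d, p("experiment", "created")),
        "modified": _first(exp_d, p("experiment", "modified")),
        "assays": assays,
    }


def _local_id(uri: str) -> str:
    return uri.rstrip("/").rsplit("/", 1)[-1]


#: Stable column order of the analysis sample table: identifiers first,
#: then one (label, class URI) column pair per biomaterial attribute.
SAMPLE_TABLE_COLUMNS = ["assay", "replicate", "replicate_type", "biomaterial"] + [
    col for attr in BIOMATERIAL_ANNOTATION_FIELDS for col in (attr, attr + "_uri")
]


def _sample_rows(record: dict) -> list[list[str]]:
    rows = []
    for assay in record["assays"]:
        for rep in assay["replicates"]:
            bm = rep.get("biomaterial") or {"name": "", "annotations": {}}
            row = [_local_id(assay["uri"]), _local_id(rep["uri"]), rep["replicate_type"], bm["name"]]
            for attr in BIOMATERIAL_ANNOTATION_FIELDS:
                ann = bm["annotations"].get(attr)
                row.extend([ann["label"], ann["class_uri"]] if ann else ["", ""])
            rows.append(row)
    return rows


def sample_table(record: dict) -> pd.DataFrame:
    """Flatten a traversal record: one row per replicate, stable columns."""
    return pd.DataFrame(_sample_rows(record), columns=SAMPLE_TABLE_COLUMNS, dtype=str)


def sample_table_tsv(record: dict) -> str:
    """Render the sample table as TSV with a fully specified byte layout.

    Header + one line per replicate, tab-separated, ``\\n`` line endings, no
    quoting — the cross-language exchange format for analysis clients.
    """
    lines = ["\t".join(SAMPLE_TABLE_COLUMNS)]
    lines.extend("\t".join(row) for row in _sample_rows(record))
    return "\n".join(lines) + "\n"
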