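"""Ontology ingest and subclass-closure reasoning.

External ontologies (e.g. the Cell Ontology) are loaded into a compact
:class:`OntologySnapshot` — class URIs, labels, optional definitions and
the asserted ``rdfs:subClassOf`` edges between *named* classes.  Only
asserted is_a edges are used: no OWL reasoning over equivalence axioms or
restrictions is attempted, which keeps behaviour predictable on any triple
store and makes the transitive closure trivially checkable.  Superclass
expressions that are not named classes (OWL restrictions) are ignored.

The subclass closure of a root class — all of its descendants — is what
turns an annotation query for "myeloid cell" into one that also matches
experiments annotated with myeloblasts, promyelocytes and the other
descendant types.

Identifier drift between ontology releases (old URIs whose path differs
from current ones) is handled by an optional URI-rewrite map applied at
load time, normalising old URIs to their current form before anything is
indexed or queried.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import obonet
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .store import TripleStore

__all__ = [
    "OntologySnapshot",
    "OntologyCycleError",
    "load_ontology",
    "index_ontology",
    "subclass_closure",
    "OBO_NS",
]

OBO_NS = "http://purl.obolibrary.org/obo/"
#: IAO "definition" annotation property, the OBO convention for textual defs.
_DEF_URI = URIRef(OBO_NS + "IAO_0000115")


class OntologyCycleError(ValueError):
    """The asserted subclass graph contains a cycle (one cycle is listed)."""


@dataclass
class OntologySnapshot:
    """An ingested ontology: named classes, labels and is_a edges."""

    classes: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)
    definitions: dict[str, str] = field(default_factory=dict)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)  # (child, parent)
    synonyms: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for child, parent in self.subclass_edges:
            if child not in self.classes or parent not in self.classes:
                raise ValueError(f"subclass edge endpoint not a known class: {child} -> {parent}")
        dg = nx.DiGraph(self.subclass_edges)
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
        raise OntologyCycleError(f"subclass hierarchy contains a cycle: {path}")

    def label_of(self, uri: str) -> str | None:
        return self.labels.get(uri)


_RDF_FORMATS = {".owl": "xml", ".rdf": "xml", ".xml": "xml", ".ttl": "turtle", ".nt": "nt"}


def _load_rdf(path: str, fmt: str) -> OntologySnapshot:
    g = Graph()
    g.parse(path, format=fmt)
    snap = OntologySnapshot()
    for cls in g.subjects(RDF.type, OWL.Class):
        if isinstance(cls, URIRef):
            snap.classes.add(str(cls))
    for cls in list(snap.classes):
        uri = URIRef(cls)
        for label in g.objects(uri, RDFS.label):
            snap.labels[cls] = str(label)
            break
        for definition in g.objects(uri, _DEF_URI):
            snap.definitions[cls] = str(definition)
            break
    for child, parent in g.subject_objects(RDFS.subClassOf):
        # named classes only; restriction-valued superclasses are skipped
        if isinstance(child, URIRef) and isinstance(parent, URIRef):
            c, p = str(child), str(parent)
            if c in snap.classes and p in snap.classes:
                snap.subclass_edges.add((c, p))
    return snap


def _load_obo(path: str) -> OntologySnapshot:
    graph = obonet.read_obo(path)
    snap = OntologySnapshot()

    def to_uri(term_id: str) -> str:
        if term_id.startswith("http://") or term_id.startswith("https://"):
            return term_id
        return OBO_NS + term_id.replace(":", "_")

    for node, data in graph.nodes(data=True):
        uri = to_uri(node)
        snap.classes.add(uri)
        if "name" in data:
            snap.labels[uri] = data["name"]
        if "def" in data:
            snap.definitions[uri] = data["def"].strip('"').split('" [')[0]
        if "synonym" in data:
            snap.synonyms[uri] = [s.split('"')[1] for s in data["synonym"] if '"' in s]
    # obonet edge direction: child --is_a--> parent
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            snap.subclass_edges.add((to_uri(child), to_uri(parent)))
    return snap


def load_ontology(path: str, rewrite: dict[str, str] | None = None) -> OntologySnapshot:
    """Load an OWL/RDF (.owl/.rdf/.ttl/.nt) or OBO flat file into a snapshot.

    ``rewrite`` maps old class URIs to current ones and is applied to every
    class, label key and edge endpoint before validation.  Raises
    :class:`OntologyCycleError` if the asserted is_a graph is cyclic.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obo":
        snap = _load_obo(path)
    elif ext in _RDF_FORMATS:
        snap = _load_rdf(path, _RDF_FORMATS[ext])
    else:
        raise ValueError(f"unrecognised ontology file extension {ext!r}")
    if rewrite:
        rw = lambda u: rewrite.get(u, u)
        snap = OntologySnapshot(
            classes={rw(c) for c in snap.classes},
            labels={rw(c): l for c, l in snap.labels.items()},
            definitions={rw(c): d for c, d in snap.definitions.items()},
            subclass_edges={(rw(c), rw(p)) for c, p in snap.subclass_edges},
            synonyms={rw(c): s for c, s in snap.synonyms.items()},
        )
    snap.validate()
    return snap


def index_ontology(store: TripleStore, snap: OntologySnapshot) -> int:
    """Index a snapshot's class/label/subClassOf triples; returns new-triple count.

    Emits |classes| rdf:type owl:Class triples, one rdfs:label per labelled
    class and one rdfs:subClassOf triple per edge; idempotent like all
    indexing.
    """
    triples = []
    for cls in snap.classes:
        triples.append((URIRef(cls), RDF.type, OWL.Class))
    for cls, label in snap.labels.items():
        triples.append((URIRef(cls), RDFS.label, Literal(label)))
    for child, parent in snap.subclass_edges:
        triples.append((URIRef(child), RDFS.subClassOf, URIRef(parent)))
    return store.index_triples(triples)


def subclass_closure(snap: OntologySnapshot, root: str, include_root: bool = True) -> list[str]:
    """All descendants of ``root`` via asserted is_a edges, sorted.

    ``include_root`` controls whether the root itself is a member.  Raises
    ``KeyError`` for a root that is not a class of the snapshot.
    """
    if root not in snap.classes:
        raise KeyError(f"unknown ontology class {root!r}")
    children: dict[str, list[str]] = {}
    for child, parent in snap.subclass_edges:
        children.setdefault(parent, []).append(child)
    seen: set[str] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    if include_root:
        seen.add(root)
    else:
        seen.discard(root)
    return sorted(seen)
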