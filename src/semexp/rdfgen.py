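"""Deterministic RDF generation from the experiment model.

Every entity — experiments, bioassays, replicates, biomaterials, people,
citations and vocabulary terms — receives a minted URI of the form
``<base_uri>/<kind>/<id>``; no blank nodes are ever emitted.  This keeps
DESCRIBE-based traversal trivial (follow object URIs, DESCRIBE each) and
lets the public/private store split operate on plain triple sets.

Literals are typed minimally: titles, descriptions and names are plain
strings; created/modified stamps are xsd:dateTime.
"""

from __future__ import annotations

import re

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .model import Experiment, Repository
from .vocab import MappingRegistry, default_registry, expand_curie

__all__ = [
    "TripleGraph",
    "mint_uri",
    "experiment_to_rdf",
    "repository_to_rdf",
    "serialize",
    "UnmappedFieldError",
]

_SLUG_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.-]*$")


class UnmappedFieldError(KeyError):
    """A model field had no predicate mapping while strict mode was on."""


class TripleGraph:
    """A set of (subject, predicate, object) triples with a visibility tier.

    Thin wrapper around :class:`rdflib.Graph` carrying the public/private
    tag that decides which store(s) the triples may be indexed into.
    """

    def __init__(self, visibility: str = "public", graph: Graph | None = None):
        if visibility not in ("public", "private"):
            raise ValueError(f"invalid visibility {visibility!r}")
        self.visibility = visibility
        self.graph = graph if graph is not None else Graph()

    def __len__(self) -> int:
        return len(self.graph)

    def __iter__(self):
        return iter(self.graph)

    def __contains__(self, triple) -> bool:
        return triple in self.graph

    def triples(self, pattern=(None, None, None)):
        return self.graph.triples(pattern)

    def add(self, triple) -> None:
        self.graph.add(triple)

    def update(self, other: "TripleGraph") -> None:
        for t in other.graph:
            self.graph.add(t)

    def as_set(self) -> set:
        return set(self.graph)


def mint_uri(base_uri: str, entity_kind: str, entity_id: str) -> URIRef:
    """Deterministically mint ``<base>/<kind>/<id>``.

    The RDF document URL for the entity is this URI + ``.rdf``.  Raises
    ``ValueError`` if the id is not a URL-safe slug.
    """
    if not _SLUG_RE.match(entity_id):
        raise ValueError(f"entity id is not a URL-safe slug: {entity_id!r}")
    if not _SLUG_RE.match(entity_kind):
        raise ValueError(f"entity kind is not a URL-safe slug: {entity_kind!r}")
    return URIRef(f"{base_uri.rstrip('/')}/{entity_kind}/{entity_id}")


def _pred(registry: MappingRegistry, ctype: str, fname: str, strict: bool) -> URIRef | None:
    try:
        return URIRef(registry.predicate_uri(ctype, fname))
    except KeyError:
        if strict:
            raise UnmappedFieldError(f"no predicate mapping for {ctype}.{fname}")
        return None


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", text).strip("_") or "x"


def _emit_term(g: Graph, repo: Repository, registry: MappingRegistry, ref, strict: bool) -> URIRef:
    """Emit label + equivalence triples for a vocabulary term; return its URI."""
    term = repo.resolve(ref)
    if term is None:
        raise ValueError(f"unresolved term reference {ref!r}")
    uri = mint_uri(repo.base_uri, "term", term.id)
    g.add((uri, RDFS.label, Literal(term.label)))
    if term.equivalents:
        pref = _pred(registry, "term", "equivalents", strict)
        if pref is not None:
            g.add((uri, pref, URIRef(expand_curie(term.equivalents[0], registry.prefix_table))))
        alt = _pred(registry, "term", "alternative_equivalents", strict=False)
        for curie in term.equivalents[1:]:
            if alt is not None:
                g.add((uri, alt, URIRef(expand_curie(curie, registry.prefix_table))))
    return uri


def experiment_to_rdf(
    exp: Experiment,
    repo: Repository,
    registry: MappingRegistry | None = None,
    strict: bool = True,
) -> TripleGraph:
    """Convert one experiment (and everything it references) to triples.

    The graph's visibility equals the experiment's visibility.  With
    ``strict`` on, a field with no registry mapping raises
    :class:`UnmappedFieldError`; otherwise the field is skipped.
    """
    registry = registry or default_registry()
    tg = TripleGraph(visibility=exp.visibility)
    g = tg.graph
    base = repo.base_uri

    exp_uri = mint_uri(base, "experiment", exp.id)
    g.add((exp_uri, RDF.type, URIRef(registry.class_uri("experiment"))))
    g.add((exp_uri, _pred(registry, "experiment", "title", True), Literal(exp.title)))
    if exp.description:
        g.add((exp_uri, _pred(registry, "experiment", "description", True), Literal(exp.description)))
    g.add((exp_uri, _pred(registry, "experiment", "created", True), Literal(exp.created, datatype=XSD.dateTime)))
    g.add((exp_uri, _pred(registry, "experiment", "modified", True), Literal(exp.modified, datatype=XSD.dateTime)))
    if exp.protocol_overview:
        p = _pred(registry, "experiment", "protocol_overview", strict)
        if p is not None:
            g.add((exp_uri, p, Literal(exp.protocol_overview)))
    for factor in exp.experimental_factors:
        p = _pred(registry, "experiment", "experimental_factors", strict)
        if p is not None:
            g.add((exp_uri, p, Literal(factor)))
    if exp.measurement_type is not None:
        p = _pred(registry, "experiment", "measurement_type", strict)
        if p is not None:
            g.add((exp_uri, p, _emit_term(g, repo, registry, exp.measurement_type, strict)))

    for pid in exp.contributors:
        person = repo.people[pid]
        person_uri = mint_uri(base, "person", person.id)
        g.add((exp_uri, _pred(registry, "experiment", "contributors", True), person_uri))
        g.add((person_uri, RDF.type, URIRef(registry.class_uri("person"))))
        g.add((person_uri, _pred(registry, "person", "name", True), Literal(person.name)))

    for cid in exp.citations:
        cit = repo.citations[cid]
        cit_uri = mint_uri(base, "citation", cit.id)
        g.add((exp_uri, _pred(registry, "experiment", "citations", True), cit_uri))
        g.add((cit_uri, RDF.type, URIRef(registry.class_uri("citation"))))
        g.add((cit_uri, _pred(registry, "citation", "title", True), Literal(cit.title)))
        for author in cit.authors:
            g.add((cit_uri, _pred(registry, "citation", "authors", True), Literal(author)))
        if cit.journal:
            g.add((cit_uri, _pred(registry, "citation", "journal", True), Literal(cit.journal)))
        if cit.year is not None:
            g.add((cit_uri, _pred(registry, "citation", "year", True), Literal(str(cit.year), datatype=XSD.gYear)))
        if cit.doi:
            g.add((cit_uri, _pred(registry, "citation", "doi", True), Literal(cit.doi)))
        if cit.pmid:
            g.add((cit_uri, _pred(registry, "citation", "pmid", True), Literal(cit.pmid)))

    for label, url in exp.external_links:
        g.add((exp_uri, _pred(registry, "experiment", "external_links", True), URIRef(url)))

    has_part = _pred(registry, "experiment", "assays", True)
    assay_rep_pred = _pred(registry, "bioassay", "replicates", True)
    rep_bm_pred = _pred(registry, "replicate", "biomaterial", True)
    for assay in exp.assays:
        assay_uri = mint_uri(base, "bioassay", assay.id)
        g.add((exp_uri, has_part, assay_uri))
        g.add((assay_uri, RDF.type, URIRef(registry.class_uri("bioassay"))))
        g.add((assay_uri, _pred(registry, "bioassay", "name", True), Literal(assay.name)))
        if assay.platform:
            p = _pred(registry, "bioassay", "platform", strict)
            if p is not None:
                g.add((assay_uri, p, Literal(assay.platform)))
        if assay.protocol:
            p = _pred(registry, "bioassay", "protocol", strict)
            if p is not None:
                g.add((assay_uri, p, Literal(assay.protocol)))
        for fname in assay.raw_data_files:
            p = _pred(registry, "bioassay", "raw_data_files", strict)
            if p is not None:
                g.add((assay_uri, p, Literal(fname)))
        for rep in assay.replicates:
            rep_uri = mint_uri(base, "replicate", rep.id)
            g.add((assay_uri, assay_rep_pred, rep_uri))
            g.add((rep_uri, RDF.type, URIRef(registry.class_uri("replicate"))))
            p = _pred(registry, "replicate", "replicate_type", strict)
            if p is not None:
                g.add((rep_uri, p, Literal(rep.replicate_type)))
            bm = repo.biomaterials[rep.biomaterial]
            bm_uri = mint_uri(base, "biomaterial", bm.id)
            g.add((rep_uri, rep_bm_pred, bm_uri))
            g.add((bm_uri, RDF.type, URIRef(registry.class_uri("biomaterial"))))
            g.add((bm_uri, _pred(registry, "biomaterial", "name", True), Literal(bm.name)))
            for attr, ref in bm.annotations():
                p = _pred(registry, "biomaterial", attr, strict)
                if p is not None:
                    g.add((bm_uri, p, _emit_term(g, repo, registry, ref, strict)))
            for key in sorted(bm.free_attributes):
                g.add((bm_uri, URIRef(registry.prefix_table["sx"] + "attr_" + _slug(key)), Literal(bm.free_attributes[key])))

    return tg


def repository_to_rdf(
    repo: Repository,
    registry: MappingRegistry | None = None,
    strict: bool = True,
) -> tuple[TripleGraph, TripleGraph]:
    """Generate the (public, all) graph pair for the two-store split.

    ``all`` is the union over every experiment; ``public`` restricts to
    experiments with public visibility, so ``public ⊆ all`` by construction.
    """
    registry = registry or default_registry()
    public = TripleGraph(visibility="public")
    everything = TripleGraph(visibility="private")
    for exp in repo.experiments:
        tg = experiment_to_rdf(exp, repo, registry, strict=strict)
        everything.update(tg)
        if exp.visibility == "public":
            public.update(tg)
    return public, everything


_FORMAT_MAP = {"turtle": "turtle", "rdfxml": "xml", "ntriples": "nt"}


def serialize(graph: TripleGraph, fmt: str = "turtle") -> bytes:
    """Serialize to Turtle, RDF/XML or canonical (sorted) N-Triples."""
    if fmt not in _FORMAT_MAP:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_FORMAT_MAP)}")
    if fmt == "ntriples":
        lines = sorted(
            f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph.graph
        )
        return ("\n".join(lines) + ("\n" if lines else "")).encode("utf-8")
    return graph.graph.serialize(format=_FORMAT_MAP[fmt], encoding="utf-8")


def parse(data: bytes, fmt: str = "turtle") -> TripleGraph:
    """Parse serialized RDF back into a TripleGraph (visibility 'public')."""
    if fmt not in _FORMAT_MAP:
        raise ValueError(f"unknown format {fmt!r}")
    g = Graph()
    g.parse(data=data, format=_FORMAT_MAP[fmt])
    return TripleGraph(visibility="public", graph=g)
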