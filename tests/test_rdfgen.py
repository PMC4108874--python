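"""RDF generation: URI minting, triple emission, serialization."""

import copy

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, RDFS

from semexp import fixtures, rdfgen
from semexp.model import Bioassay, Experiment, Replicate, Repository
from semexp.rdfgen import TripleGraph, experiment_to_rdf, mint_uri, parse, repository_to_rdf, serialize
from semexp.vocab import expand_curie

OBO = "http://purl.obolibrary.org/obo/"
HAS_PART = URIRef("http://purl.org/obo/owl/ro#has_part")
PREFERRED = URIRef("http://purl.org/ontology/ao/core#preferred_equivalent")


def test_mint_uri_by_construction_rule():
    assert str(mint_uri("http://example.org", "experiment", "13610")) == "http://example.org/experiment/13610"
    assert mint_uri("http://example.org/", "experiment", "13610") == mint_uri(
        "http://example.org", "experiment", "13610"
    )


def test_mint_uri_rejects_non_slug_ids():
    with pytest.raises(ValueError):
        mint_uri("http://example.org", "experiment", "has spaces")
    with pytest.raises(ValueError):
        mint_uri("http://example.org", "experiment", "../escape")


def test_minted_uris_are_distinct_across_the_fixture(seeded_repo):
    uris = []
    for exp in seeded_repo.experiments:
        uris.append(mint_uri(seeded_repo.base_uri, "experiment", exp.id))
        for assay in exp.assays:
            uris.append(mint_uri(seeded_repo.base_uri, "bioassay", assay.id))
            for rep in assay.replicates:
                uris.append(mint_uri(seeded_repo.base_uri, "replicate", rep.id))
    for bm_id in seeded_repo.biomaterials:
        uris.append(mint_uri(seeded_repo.base_uri, "biomaterial", bm_id))
    assert len(uris) == len(set(uris))


# ---- worked-example experiment --------------------------------------------


@pytest.fixture(scope="module")
def worked_graph(worked_repo):
    return experiment_to_rdf(worked_repo.experiments[0], worked_repo)


def test_experiment_is_typed_as_investigation(worked_graph):
    exp = URIRef("http://example.org/experiment/13610")
    assert (exp, RDF.type, URIRef(OBO + "OBI_0000066")) in worked_graph


def test_six_assays_mean_six_has_part_triples(worked_graph):
    exp = URIRef("http://example.org/experiment/13610")
    assert len(list(worked_graph.triples((exp, HAS_PART, None)))) == 6


def test_k562_term_maps_to_clo_0007060(worked_graph):
    k562_term = URIRef("http://example.org/term/cl-k562")
    assert (k562_term, PREFERRED, URIRef(OBO + "CLO_0007060")) in worked_graph
    assert (k562_term, RDFS.label, Literal("K562")) in worked_graph


def test_all_biomaterial_property_mappings_present(worked_graph):
    expected = {
        OBO + "NCBITaxon_9606",
        OBO + "UBERON_0000178",
        OBO + "CLO_0007060",
        "http://www.ebi.ac.uk/efo/EFO_0003042",
        OBO + "DOID_8692",
    }
    emitted = {str(o) for _, _, o in worked_graph.triples((None, PREFERRED, None))}
    assert expected <= emitted


def test_graph_visibility_follows_experiment(worked_repo):
    exp = copy.deepcopy(worked_repo.experiments[0])
    exp.visibility = "private"
    assert experiment_to_rdf(exp, worked_repo).visibility == "private"


def test_bare_experiment_still_has_type_and_title():
    repo = Repository(base_uri="http://example.org")
    exp = Experiment(id="bare", title="Nothing here", visibility="public")
    repo.experiments.append(exp)
    g = experiment_to_rdf(exp, repo)
    uri = URIRef("http://example.org/experiment/bare")
    assert (uri, RDF.type, URIRef(OBO + "OBI_0000066")) in g
    assert (uri, URIRef("http://purl.org/dc/terms/title"), Literal("Nothing here")) in g
    assert not list(g.triples((uri, HAS_PART, None)))


def _expected_triple_count(exp, repo, registry):
    """Independent enumeration of the triples the converter must emit.

    Counts experiment-, assay- and replicate-level triples additively and
    entity-level triples once per distinct biomaterial/term/person/citation
    (the graph is a set).
    """
    n = 0
    n += 1  # rdf:type
    n += 1  # title
    n += bool(exp.description) + 2  # description + created + modified
    n += bool(exp.protocol_overview)
    n += len(exp.experimental_factors)
    n += len(exp.external_links)
    n += (exp.measurement_type is not None)  # link triple
    n += len(exp.contributors) + len(exp.citations)  # link triples

    for pid in exp.contributors:
        n += 2  # type + name
    for cid in exp.citations:
        c = repo.citations[cid]
        n += 2 + len(c.authors) + bool(c.journal) + (c.year is not None) + bool(c.doi) + bool(c.pmid)

    terms = set()
    if exp.measurement_type is not None:
        terms.add(repo.resolve(exp.measurement_type).id)
    biomaterials = set()
    for assay in exp.assays:
        n += 1  # has_part
        n += 2  # type + name
        n += bool(assay.platform) + bool(assay.protocol) + len(assay.raw_data_files)
        for rep in assay.replicates:
            n += 4  # link + type + replicate_type + biomaterial link
            biomaterials.add(rep.biomaterial)
    for bm_id in biomaterials:
        bm = repo.biomaterials[bm_id]
        n += 2  # type + name
        n += len(bm.free_attributes)
        for _, ref in bm.annotations():
            n += 1
            terms.add(repo.resolve(ref).id)
    all_terms = {t.id: t for vocab in repo.vocabularies.values() for t in vocab}
    for tid in terms:
        t = all_terms[tid]
        n += 1 + (1 if t.equivalents else 0) + max(0, len(t.equivalents) - 1)
    return n


def test_triple_count_matches_independent_enumeration(worked_repo, worked_graph, registry):
    expected = _expected_triple_count(worked_repo.experiments[0], worked_repo, registry)
    assert len(worked_graph) == expected


def test_every_external_class_uri_comes_from_a_term(seeded_repo, registry):
    _, all_graph = repository_to_rdf(seeded_repo)
    allowed = {
        expand_curie(curie, registry.prefix_table)
        for terms in seeded_repo.vocabularies.values()
        for t in terms
        for curie in t.equivalents
    }
    emitted = {str(o) for _, _, o in all_graph.triples((None, PREFERRED, None))}
    assert emitted <= allowed


# ---- repository-level generation ------------------------------------------


def test_public_graph_is_subset_of_all(seeded_repo):
    public, everything = repository_to_rdf(seeded_repo)
    assert public.as_set() <= everything.as_set()
    assert len(public) < len(everything)  # the fixture mixes visibilities


def test_all_private_repository_has_empty_public_graph():
    repo = fixtures.make_repository(5, 0.0, seed=3)
    public, everything = repository_to_rdf(repo)
    assert len(public) == 0 and len(everything) > 0


def test_all_public_repository_has_equal_graphs():
    repo = fixtures.make_repository(5, 1.0, seed=3)
    public, everything = repository_to_rdf(repo)
    assert public.as_set() == everything.as_set()


def test_generation_is_deterministic(seeded_repo):
    a = repository_to_rdf(seeded_repo)[1].as_set()
    b = repository_to_rdf(seeded_repo)[1].as_set()
    assert a == b


def test_adding_an_assay_only_adds_triples(worked_repo):
    repo = copy.deepcopy(worked_repo)
    before = experiment_to_rdf(repo.experiments[0], repo).as_set()
    repo.experiments[0].assays.append(
        Bioassay(
            id="assay-extra",
            name="Extra assay",
            replicates=[Replicate(id="rep-extra", replicate_type="biological", biomaterial="bm-k562-p4")],
        )
    )
    after = experiment_to_rdf(repo.experiments[0], repo).as_set()
    assert before <= after


# ---- serialization ---------------------------------------------------------


@pytest.mark.parametrize("fmt", ["turtle", "rdfxml", "ntriples"])
def test_serialize_parse_round_trip(worked_graph, fmt):
    data = serialize(worked_graph, fmt)
    assert parse(data, fmt).as_set() == worked_graph.as_set()


def test_ntriples_is_canonical_and_byte_stable(worked_graph):
    a = serialize(worked_graph, "ntriples")
    b = serialize(worked_graph, "ntriples")
    assert a == b
    lines = a.decode().splitlines()
    assert lines == sorted(lines)


def test_empty_graph_serializes_to_valid_documents():
    empty = TripleGraph(visibility="public")
    for fmt in ("turtle", "rdfxml", "ntriples"):
        assert len(parse(serialize(empty, fmt), fmt)) == 0


def test_unknown_format_is_an_error(worked_graph):
    with pytest.raises(ValueError):
        serialize(worked_graph, "jsonld")
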