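"""Triple stores, SPARQL execution and the HTTP endpoint."""

import json
import random
import urllib.error
import urllib.parse
import urllib.request

import pytest

from conftest import bgp_solutions, build_stores, patterns_to_sparql, random_bgp
from semexp import rdfgen
from semexp.query import mouse_hsc_query
from semexp.store import (
    SparqlError,
    TripleStore,
    VisibilityError,
    serve,
    sparql_describe,
    sparql_select,
)


def test_indexing_is_idempotent(worked_repo):
    graph = rdfgen.experiment_to_rdf(worked_repo.experiments[0], worked_repo)
    store = TripleStore(tier="public")
    assert store.index(graph) == len(graph)
    assert store.index(graph) == 0
    assert len(store) == len(graph)


def test_indexing_empty_graph_adds_nothing():
    store = TripleStore(tier="public")
    assert store.index(rdfgen.TripleGraph(visibility="public")) == 0


def test_public_store_refuses_private_graphs(worked_repo):
    graph = rdfgen.experiment_to_rdf(worked_repo.experiments[0], worked_repo)
    graph.visibility = "private"
    with pytest.raises(VisibilityError):
        TripleStore(tier="public").index(graph)
    # the admin store takes it
    admin = TripleStore(tier="admin", api_key="k")
    graph2 = rdfgen.TripleGraph(visibility="public", graph=graph.graph)
    assert admin.index(graph2) == len(graph)


def test_admin_minus_public_is_exactly_the_private_triples(seeded_repo):
    """Set arithmetic: the two tiers differ by the private experiments' RDF."""
    public_graph, all_graph = rdfgen.repository_to_rdf(seeded_repo)
    private_union = set()
    for exp in seeded_repo.experiments:
        if exp.visibility == "private":
            private_union |= rdfgen.experiment_to_rdf(exp, seeded_repo).as_set()
    assert all_graph.as_set() - public_graph.as_set() == private_union - public_graph.as_set()


def test_store_contents_independent_of_insertion_order(seeded_repo):
    graphs = [rdfgen.experiment_to_rdf(e, seeded_repo) for e in seeded_repo.experiments[:6]]
    for g in graphs:
        g.visibility = "public"
    a = TripleStore(tier="public")
    b = TripleStore(tier="public")
    for g in graphs:
        a.index(g)
    for g in reversed(graphs):
        b.index(g)
    assert set(a.graph) == set(b.graph)


def test_persistence_round_trip(tmp_path, worked_stores):
    public, _ = worked_stores
    path = tmp_path / "store.nt"
    public.save(str(path))
    reloaded = TripleStore(tier="public")
    reloaded.load(str(path))
    assert set(reloaded.graph) == set(public.graph)


# ---- SELECT ----------------------------------------------------------------


def test_select_on_empty_store_returns_no_rows():
    _, rows = sparql_select(TripleStore(), "SELECT ?s WHERE { ?s ?p ?o }")
    assert rows == []


def test_select_rows_are_sorted_without_order_by(worked_stores):
    public, _ = worked_stores
    q = "SELECT ?s ?o WHERE { ?s <http://purl.org/obo/owl/ro#has_part> ?o }"
    _, rows = sparql_select(public, q)
    assert rows == sorted(rows, key=lambda r: tuple(t.n3() for t in r))
    assert len(rows) == 6


def test_syntax_error_is_reported_with_position(worked_stores):
    public, _ = worked_stores
    with pytest.raises(SparqlError, match="parse error"):
        sparql_select(public, "SELECT ?s WHERE { ?s ?p")


def test_non_select_form_is_rejected_by_name(worked_stores):
    public, _ = worked_stores
    with pytest.raises(SparqlError, match="unsupported query form"):
        sparql_select(public, "ASK { ?s ?p ?o }")


def test_random_bgp_queries_match_brute_force_oracle(seeded_stores):
    """100 random basic graph patterns: engine vs hand-rolled join."""
    public, _ = seeded_stores
    triples = list(public.graph)
    rng = random.Random(42)
    for _ in range(100):
        patterns, select = random_bgp(rng, triples)
        expected = bgp_solutions(triples, patterns, select)
        _, rows = sparql_select(public, patterns_to_sparql(patterns, select))
        assert set(rows) == expected


def test_public_results_contained_in_admin_results(seeded_stores):
    public, admin = seeded_stores
    triples = list(public.graph)
    rng = random.Random(7)
    for _ in range(25):
        patterns, select = random_bgp(rng, triples)
        q = patterns_to_sparql(patterns, select)
        _, pub_rows = sparql_select(public, q)
        _, adm_rows = sparql_select(admin, q)
        assert set(pub_rows) <= set(adm_rows)


# ---- DESCRIBE ---------------------------------------------------------------


def test_describe_unknown_uri_is_empty(worked_stores):
    public, _ = worked_stores
    assert len(sparql_describe(public, "http://example.org/experiment/ghost")) == 0


def test_describe_experiment_contains_its_six_assay_links(worked_stores):
    public, _ = worked_stores
    g = sparql_describe(public, "http://example.org/experiment/13610")
    from rdflib import URIRef

    has_part = URIRef("http://purl.org/obo/owl/ro#has_part")
    assert len(list(g.triples((None, has_part, None)))) == 6


def test_describe_equals_subject_filter_for_every_subject(worked_stores):
    public, _ = worked_stores
    for subject in {s for s, _, _ in public.graph}:
        described = sparql_describe(public, str(subject)).as_set()
        expected = {(s, p, o) for s, p, o in public.graph if s == subject}
        assert described == expected


# ---- HTTP endpoint ----------------------------------------------------------

API_KEY = "test-key-123"


@pytest.fixture(scope="module")
def endpoint(seeded_repo):
    public, admin = build_stores(seeded_repo, api_key=API_KEY)
    server = serve(public, admin, port=0, api_key=API_KEY, base_uri=seeded_repo.base_uri)
    yield server
    server.stop()


def _get(url, headers=None, expect_error=None):
    req = urllib.request.Request(url, headers=headers or {})
    try:
        with urllib.request.urlopen(req, timeout=10) as resp:
            return resp.status, resp.read()
    except urllib.error.HTTPError as exc:
        if expect_error:
            return exc.code, exc.read()
        raise


def _sparql_url(endpoint, query):
    return f"{endpoint.url}/sparql?query={urllib.parse.quote(query)}"


def test_no_key_answers_from_public_store(endpoint, seeded_stores):
    public, _ = seeded_stores
    status, body = _get(_sparql_url(endpoint, mouse_hsc_query()))
    assert status == 200
    got = {b["title"]["value"] for b in json.loads(body)["results"]["bindings"]}
    _, rows = sparql_select(public, mouse_hsc_query())
    assert got == {str(r[0]) for r in rows}


def test_wrong_key_is_refused(endpoint):
    status, _ = _get(
        _sparql_url(endpoint, "SELECT ?s WHERE { ?s ?p ?o } LIMIT 1"),
        headers={"X-API-Key": "wrong"},
        expect_error=True,
    )
    assert status == 403


def test_correct_key_answers_from_admin_store(endpoint, seeded_stores):
    _, admin = seeded_stores
    status, body = _get(_sparql_url(endpoint, mouse_hsc_query()), headers={"X-API-Key": API_KEY})
    assert status == 200
    got = {b["title"]["value"] for b in json.loads(body)["results"]["bindings"]}
    _, rows = sparql_select(admin, mouse_hsc_query())
    assert got == {str(r[0]) for r in rows}


def test_admin_and_public_differ_by_private_experiment_titles(endpoint, seeded_repo):
    q = "SELECT DISTINCT ?t WHERE { ?e a <http://purl.obolibrary.org/obo/OBI_0000066> ; <http://purl.org/dc/terms/title> ?t }"
    _, pub_body = _get(_sparql_url(endpoint, q))
    _, adm_body = _get(_sparql_url(endpoint, q), headers={"X-API-Key": API_KEY})
    pub = {b["t"]["value"] for b in json.loads(pub_body)["results"]["bindings"]}
    adm = {b["t"]["value"] for b in json.loads(adm_body)["results"]["bindings"]}
    private_titles = {e.title for e in seeded_repo.experiments if e.visibility == "private"}
    public_titles = {e.title for e in seeded_repo.experiments if e.visibility == "public"}
    assert pub == public_titles
    assert adm - pub == private_titles - public_titles


def test_malformed_query_is_a_400(endpoint):
    status, body = _get(_sparql_url(endpoint, "SELECT WHERE {"), expect_error=True)
    assert status == 400
    assert "error" in json.loads(body)


def test_tsv_content_negotiation(endpoint):
    q = "SELECT ?t WHERE { ?e <http://purl.org/dc/terms/title> ?t } LIMIT 2"
    status, body = _get(_sparql_url(endpoint, q), headers={"Accept": "text/tab-separated-values"})
    assert status == 200
    lines = body.decode().splitlines()
    assert lines[0] == "t" and len(lines) == 3


def test_post_form_encoded_query(endpoint):
    data = urllib.parse.urlencode({"query": "SELECT ?s WHERE { ?s ?p ?o } LIMIT 1"}).encode()
    req = urllib.request.Request(
        f"{endpoint.url}/sparql", data=data, headers={"Content-Type": "application/x-www-form-urlencoded"}
    )
    with urllib.request.urlopen(req, timeout=10) as resp:
        assert resp.status == 200


def test_resource_route_serves_describe_graph(endpoint, seeded_repo, seeded_stores):
    exp_id = next(e.id for e in seeded_repo.experiments if e.visibility == "public")
    status, body = _get(f"{endpoint.url}/resource/experiment/{exp_id}.rdf?format=ntriples")
    assert status == 200
    public, _ = seeded_stores
    expected = rdfgen.serialize(sparql_describe(public, f"{seeded_repo.base_uri}/experiment/{exp_id}"), "ntriples")
    assert body == expected


def test_describe_over_http_returns_spo_bindings(endpoint, seeded_repo):
    exp_id = next(e.id for e in seeded_repo.experiments if e.visibility == "public")
    uri = f"{seeded_repo.base_uri}/experiment/{exp_id}"
    status, body = _get(_sparql_url(endpoint, f"DESCRIBE <{uri}>"))
    assert status == 200
    doc = json.loads(body)
    assert doc["head"]["vars"] == ["s", "p", "o"]
    assert all(b["s"]["value"] == uri for b in doc["results"]["bindings"])
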