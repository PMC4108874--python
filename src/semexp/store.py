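"""Two-tier triple store with SPARQL execution and an HTTP endpoint.

Privacy is enforced structurally, with two separate stores rather than
per-triple ACLs: the *public* store only ever receives triple graphs whose
visibility is public and backs the open SPARQL endpoint; the *admin* store
receives everything and is reachable only with the correct API key.  The
admin store is therefore always a superset of the public one, and any
SELECT run against both differs only by rows contributed by private
experiments.

The built-in backend keeps triples in an :class:`rdflib.Graph` (which
maintains its own SPO indexes); the store contract is intentionally small —
index / select / describe / save / load — so an alternative engine can be
plugged in behind the same surface.

DESCRIBE follows outgoing edges only (all triples whose *subject* is the
requested URI).  That is exactly what link-following traversal needs: the
experiment's description lists its assays, each assay's description lists
its replicates, and so on down to the biomaterial annotations.

Row order: unless the query contains an explicit ORDER BY, result rows are
sorted by their binding values so that results are reproducible across runs
and backends.
"""

from __future__ import annotations

import json
import re
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

from rdflib import Graph, Literal, URIRef
from rdflib.plugins.sparql import prepareQuery

from .rdfgen import TripleGraph, serialize

__all__ = [
    "TripleStore",
    "SparqlError",
    "VisibilityError",
    "sparql_select",
    "sparql_describe",
    "serve",
    "EndpointServer",
]


class SparqlError(ValueError):
    """Query failed to parse or uses an unsupported feature."""


class VisibilityError(ValueError):
    """A private graph was offered to the public store."""


class TripleStore:
    """An indexed triple set tagged with an access tier.

    ``tier`` is ``"public"`` or ``"admin"``; only the admin store carries an
    API key.  Indexing is idempotent: re-adding a triple contributes 0 to
    the returned count, so store contents are independent of insertion
    order and repetition.
    """

    def __init__(self, tier: str = "public", api_key: str | None = None):
        if tier not in ("public", "admin"):
            raise ValueError(f"invalid tier {tier!r}")
        if tier == "public" and api_key is not None:
            raise ValueError("public store must not hold an API key")
        self.tier = tier
        self.api_key = api_key
        self.graph = Graph()

    def __len__(self) -> int:
        return len(self.graph)

    def index(self, graph: TripleGraph) -> int:
        """Add a graph's triples; return the number of NEW triples added."""
        if self.tier == "public" and graph.visibility != "public":
            raise VisibilityError("refusing to index a private graph into the public store")
        added = 0
        for t in graph.graph:
            if t not in self.graph:
                self.graph.add(t)
                added += 1
        return added

    def index_triples(self, triples) -> int:
        """Add raw (s, p, o) triples (ontology ingest); idempotent."""
        added = 0
        for t in triples:
            if t not in self.graph:
                self.graph.add(t)
                added += 1
        return added

    # -- persistence (plain N-Triples, the text-only on-disk format) -------

    def save(self, path: str) -> None:
        tg = TripleGraph(visibility="public", graph=self.graph)
        with open(path, "wb") as fh:
            fh.write(serialize(tg, "ntriples"))

    def load(self, path: str) -> int:
        g = Graph()
        g.parse(path, format="nt")
        return self.index_triples(iter(g))


_ORDER_BY_RE = re.compile(r"\bORDER\s+BY\b", re.IGNORECASE)
_DESCRIBE_RE = re.compile(r"^\s*(?:PREFIX\s+\S+\s+<[^>]*>\s*)*DESCRIBE\s+<([^>]+)>\s*$", re.IGNORECASE)


def _sort_key(row: tuple) -> tuple:
    return tuple("" if v is None else (v.n3() if hasattr(v, "n3") else str(v)) for v in row)


def sparql_select(store: TripleStore, query: str):
    """Run a SELECT query; return (variables, rows of bindings).

    Rows are tuples of rdflib terms (or None for unbound variables), sorted
    by binding values unless the query carries an ORDER BY.  A query that
    does not parse raises :class:`SparqlError` with the parser's position
    message; a non-SELECT query raises :class:`SparqlError` naming the
    unsupported form.
    """
    try:
        prepared = prepareQuery(query)
    except Exception as exc:
        raise SparqlError(f"SPARQL parse error: {exc}") from exc
    if prepared.algebra.name != "SelectQuery":
        raise SparqlError(f"unsupported query form: {prepared.algebra.name} (only SELECT and DESCRIBE-by-URI are supported)")
    result = store.graph.query(prepared)
    variables = [str(v) for v in result.vars]
    rows = [tuple(row[i] for i in range(len(variables))) for row in result]
    if not _ORDER_BY_RE.search(query):
        rows.sort(key=_sort_key)
    return variables, rows


def sparql_describe(store: TripleStore, uri: str) -> TripleGraph:
    """All triples whose subject is ``uri`` (outgoing edges only).

    An unknown URI yields an empty graph, never an error.
    """
    g = Graph()
    for t in store.graph.triples((URIRef(uri), None, None)):
        g.add(t)
    return TripleGraph(visibility="public", graph=g)


# --------------------------------------------------------------------------
# HTTP endpoint


def _json_term(term) -> dict:
    if isinstance(term, URIRef):
        return {"type": "uri", "value": str(term)}
    if isinstance(term, Literal):
        out = {"type": "literal", "value": str(term)}
        if term.datatype is not None:
            out["datatype"] = str(term.datatype)
        if term.language:
            out["xml:lang"] = term.language
        return out
    return {"type": "literal", "value": str(term)}


def results_to_json(variables: list[str], rows) -> dict:
    return {
        "head": {"vars": variables},
        "results": {
            "bindings": [
                {v: _json_term(val) for v, val in zip(variables, row) if val is not None}
                for row in rows
            ]
        },
    }


def results_to_tsv(variables: list[str], rows) -> str:
    lines = ["\t".join(variables)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    return "\n".join(lines) + "\n"


class EndpointServer:
    """The SPARQL endpoint around a (public, admin) store pair.

    Routes:

    * ``GET/POST /sparql?query=…`` — runs against the public store; with a
      correct ``X-API-Key`` header, against the admin store; a wrong key is
      refused with 403.  SELECT answers as SPARQL JSON results (default) or
      tab-separated text (``Accept: text/tab-separated-values``).  DESCRIBE
      of a single URI answers with ``s``/``p``/``o`` bindings in the same
      formats, so thin clients never need an RDF parser.
    * ``GET /resource/<kind>/<id>.rdf`` — the entity's DESCRIBE graph,
      serialized per ``?format=turtle|rdfxml|ntriples`` (default turtle).
      Requires ``base_uri`` so the path can be mapped back to a minted URI.
    """

    def __init__(
        self,
        public_store: TripleStore,
        admin_store: TripleStore,
        api_key: str,
        base_uri: str = "http://example.org",
        host: str = "127.0.0.1",
        port: int = 0,
    ):
        self.public_store = public_store
        self.admin_store = admin_store
        self.api_key = api_key
        self.base_uri = base_uri
        endpoint = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):  # quiet
                pass

            def _send(self, code: int, body: bytes, ctype: str) -> None:
                self.send_response(code)
                self.send_header("Content-Type", ctype)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def _answer_sparql(self, query: str) -> None:
                key = self.headers.get("X-API-Key")
                if key is not None:
                    if key != endpoint.api_key:
                        self._send(403, b'{"error": "invalid API key"}', "application/json")
                        return
                    store = endpoint.admin_store
                else:
                    store = endpoint.public_store
                want_tsv = "text/tab-separated-values" in (self.headers.get("Accept") or "")
                m = _DESCRIBE_RE.match(query)
                try:
                    if m:
                        tg = sparql_describe(store, m.group(1))
                        variables = ["s", "p", "o"]
                        rows = sorted(tg.graph, key=_sort_key)
                    else:
                        variables, rows = sparql_select(store, query)
                except SparqlError as exc:
                    self._send(400, json.dumps({"error": str(exc)}).encode(), "application/json")
                    return
                if want_tsv:
                    self._send(200, results_to_tsv(variables, rows).encode(), "text/tab-separated-values; charset=utf-8")
                else:
                    body = json.dumps(results_to_json(variables, rows), sort_keys=True).encode()
                    self._send(200, body, "application/sparql-results+json")

            def do_GET(self):
                parsed = urlparse(self.path)
                params = parse_qs(parsed.query)
                if parsed.path == "/sparql":
                    query = params.get("query", [None])[0]
                    if not query:
                        self._send(400, b'{"error": "missing query parameter"}', "application/json")
                        return
                    self._answer_sparql(query)
                    return
                m = re.match(r"^/resource/([A-Za-z0-9_.-]+)/([A-Za-z0-9_.-]+)\.rdf$", parsed.path)
                if m:
                    kind, entity_id = m.groups()
                    fmt = params.get("format", ["turtle"])[0]
                    uri = f"{endpoint.base_uri.rstrip('/')}/{kind}/{entity_id}"
                    key = self.headers.get("X-API-Key")
                    if key is not None and key != endpoint.api_key:
                        self._send(403, b'{"error": "invalid API key"}', "application/json")
                        return
                    store = endpoint.admin_store if key == endpoint.api_key else endpoint.public_store
                    try:
                        body = serialize(sparql_describe(store, uri), fmt)
                    except ValueError as exc:
                        self._send(400, json.dumps({"error": str(exc)}).encode(), "application/json")
                        return
                    ctype = {
                        "turtle": "text/turtle",
                        "rdfxml": "application/rdf+xml",
                        "ntriples": "application/n-triples",
                    }[fmt]
                    self._send(200, body, ctype + "; charset=utf-8")
                    return
                self._send(404, b'{"error": "not found"}', "application/json")

            def do_POST(self):
                parsed = urlparse(self.path)
                if parsed.path != "/sparql":
                    self._send(404, b'{"error": "not found"}', "application/json")
                    return
                length = int(self.headers.get("Content-Length") or 0)
                body = self.rfile.read(length).decode("utf-8")
                ctype = self.headers.get("Content-Type") or ""
                if ctype.startswith("application/x-www-form-urlencoded"):
                    query = parse_qs(body).get("query", [None])[0]
                else:
                    query = body
                if not query:
                    self._send(400, b'{"error": "missing query"}', "application/json")
                    return
                self._answer_sparql(query)

        self._httpd = ThreadingHTTPServer((host, port), Handler)
        self._thread: threading.Thread | None = None

    @property
    def port(self) -> int:
        return self._httpd.server_address[1]

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "EndpointServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)

    def serve_forever(self) -> None:
        self._httpd.serve_forever()


def serve(
    public_store: TripleStore,
    admin_store: TripleStore,
    port: int,
    api_key: str,
    base_uri: str = "http://example.org",
    host: str = "127.0.0.1",
    background: bool = True,
) -> EndpointServer:
    """Start the HTTP SPARQL endpoint; returns the running server handle."""
    server = EndpointServer(public_store, admin_store, api_key, base_uri=base_uri, host=host, port=port)
    if background:
        server.start()
    return server
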