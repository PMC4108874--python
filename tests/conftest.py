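"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: annotation
queries are verified against a brute-force filter over the object model,
SPARQL SELECT against a hand-rolled basic-graph-pattern matcher, and
subclass closures against repeated edge relaxation.
"""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from semexp import fixtures, rdfgen, store
from semexp.vocab import default_registry, expand_curie

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def worked_repo():
    return fixtures.make_worked_example()


@pytest.fixture(scope="session")
def mini_cl():
    return fixtures.make_mini_cl()


@pytest.fixture(scope="session")
def seeded_repo():
    return fixtures.make_repository(30, 0.5, seed=1)


def build_stores(repo, api_key="secret-key"):
    """Index a repository into a fresh (public, admin) store pair."""
    public_graph, all_graph = rdfgen.repository_to_rdf(repo)
    public = store.TripleStore(tier="public")
    public.index(public_graph)
    admin = store.TripleStore(tier="admin", api_key=api_key)
    all_graph.visibility = "public"  # the admin store takes everything
    admin.index(all_graph)
    return public, admin


@pytest.fixture(scope="session")
def seeded_stores(seeded_repo):
    return build_stores(seeded_repo)


@pytest.fixture(scope="session")
def worked_stores(worked_repo):
    return build_stores(worked_repo)


# --------------------------------------------------------------------------
# Oracle 1: object-model brute force for annotation queries


def preferred_uri(repo, ref):
    """The expanded preferred-equivalent URI of a term reference, or None."""
    if ref is None:
        return None
    term = repo.resolve(ref)
    if term is None or not term.equivalents:
        return None
    return expand_curie(term.equivalents[0], default_registry().prefix_table)


def oracle_experiments(repo, constraints, public_only=True):
    """Experiments with a biomaterial (reachable through some assay and
    replicate) satisfying ALL (attribute, allowed-class-URI-set) constraints
    simultaneously.  Returns sorted (experiment URI, title) pairs.
    """
    hits = []
    for exp in repo.experiments:
        if public_only and exp.visibility != "public":
            continue
        reachable = {rep.biomaterial for assay in exp.assays for rep in assay.replicates}
        for bm_id in reachable:
            bm = repo.biomaterials[bm_id]
            if all(
                preferred_uri(repo, getattr(bm, attr)) in allowed
                for attr, allowed in constraints
            ):
                uri = str(rdfgen.mint_uri(repo.base_uri, "experiment", exp.id))
                hits.append((uri, exp.title))
                break
    return sorted(hits)


# --------------------------------------------------------------------------
# Oracle 2: brute-force basic-graph-pattern matcher over a triple set


def bgp_solutions(triples, patterns, select):
    """All bindings of ``select`` for a conjunction of triple patterns.

    Patterns are (s, p, o) where a string starting with '?' is a variable
    and anything else must equal the rdflib term exactly.  Plain nested
    loops with unification; quadratic and proud of it.
    """
    rows = [{}]
    for pattern in patterns:
        new_rows = []
        for binding in rows:
            for triple in triples:
                b = dict(binding)
                ok = True
                for slot, term in zip(pattern, triple):
                    if isinstance(slot, str) and slot.startswith("?"):
                        if slot in b:
                            if b[slot] != term:
                                ok = False
                                break
                        else:
                            b[slot] = term
                    elif slot != term:
                        ok = False
                        break
                if ok:
                    new_rows.append(b)
        rows = new_rows
    return {tuple(b.get(v) for v in select) for b in rows}


def patterns_to_sparql(patterns, select):
    body = " .\n  ".join(
        " ".join(t if isinstance(t, str) and t.startswith("?") else t.n3() for t in p)
        for p in patterns
    )
    return f"SELECT DISTINCT {' '.join(select)} WHERE {{\n  {body} .\n}}"


def random_bgp(rng, triples):
    """A random 1-3 pattern BGP over a store's own constants."""
    triples = list(triples)
    n_patterns = rng.randint(1, 3)
    patterns = []
    var_counter = itertools.count()
    variables = []

    def fresh():
        v = f"?v{next(var_counter)}"
        variables.append(v)
        return v

    shared = fresh()
    for i in range(n_patterns):
        s, p, o = rng.choice(triples)
        slots = []
        # subject: the shared variable (always in the first pattern, so every
        # projected variable is bound somewhere) or a constant
        slots.append(shared if i == 0 or rng.random() < 0.7 else s)
        slots.append(p if rng.random() < 0.8 else fresh())
        slots.append(fresh() if rng.random() < 0.6 else o)
        patterns.append(tuple(slots))
    select = sorted(set(variables))[: rng.randint(1, max(1, len(set(variables))))]
    if not select:
        select = [shared]
    return patterns, select


# --------------------------------------------------------------------------
# Oracle 3: transitive closure by repeated edge relaxation


def closure_by_relaxation(edges, root, include_root=True):
    """Descendant set via fixed-point iteration over (child, parent) edges."""
    members = {root}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if parent in members and child not in members:
                members.add(child)
                changed = True
    if not include_root:
        members.discard(root)
    return members
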