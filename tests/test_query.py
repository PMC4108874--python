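"""High-level queries: annotation filters, subsumption expansion, traversal."""

import pytest

from conftest import build_stores, oracle_experiments, preferred_uri
from semexp import fixtures, rdfgen
from semexp.fixtures import HEMATOPOIETIC_STEM_CELL, MOUSE, MYELOID_CELL
from semexp.ontoload import index_ontology, subclass_closure
from semexp.query import (
    SAMPLE_TABLE_COLUMNS,
    describe_traverse,
    experiments_by_annotation,
    mouse_hsc_query,
    sample_table,
    sample_table_tsv,
)
from semexp.store import TripleStore, sparql_select


@pytest.fixture(scope="module")
def myeloid_snap(mini_cl):
    return mini_cl[1]


def test_unknown_attribute_error_lists_valid_attributes(seeded_stores):
    public, _ = seeded_stores
    with pytest.raises(KeyError, match="organism.*cell_type"):
        experiments_by_annotation(public, "flavour", MYELOID_CELL)


def test_unexpanded_query_matches_object_model_oracle(seeded_repo, seeded_stores):
    public, _ = seeded_stores
    got = experiments_by_annotation(public, "cell type", HEMATOPOIETIC_STEM_CELL)
    expected = oracle_experiments(seeded_repo, [("cell_type", {HEMATOPOIETIC_STEM_CELL})])
    assert got == expected and got  # non-trivially satisfiable


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_expanded_query_matches_oracle_across_seeds(seed, myeloid_snap):
    repo = fixtures.make_repository(15, 0.6, seed=seed)
    public, _ = build_stores(repo)
    closure = set(subclass_closure(myeloid_snap, MYELOID_CELL, include_root=True))
    got = experiments_by_annotation(public, "cell_type", MYELOID_CELL, expand=True, snap=myeloid_snap)
    assert got == oracle_experiments(repo, [("cell_type", closure)])


def test_expansion_equals_union_of_unexpanded_queries(seeded_stores, myeloid_snap):
    public, _ = seeded_stores
    expanded = experiments_by_annotation(public, "cell_type", MYELOID_CELL, expand=True, snap=myeloid_snap)
    union = set()
    for member in subclass_closure(myeloid_snap, MYELOID_CELL, include_root=True):
        union |= set(experiments_by_annotation(public, "cell_type", member))
    assert set(expanded) == union


def test_values_and_property_path_routes_agree(seeded_repo, myeloid_snap):
    public, _ = build_stores(seeded_repo)
    index_ontology(public, myeloid_snap)
    via_values = experiments_by_annotation(public, "cell_type", MYELOID_CELL, expand=True, snap=myeloid_snap)
    via_path = experiments_by_annotation(public, "cell_type", MYELOID_CELL, expand=True, method="path")
    assert via_values == via_path


def test_expand_false_with_unused_class_is_empty(seeded_stores):
    public, _ = seeded_stores
    assert experiments_by_annotation(public, "cell_type", "http://example.org/unused-class") == []


# ---- the canned mouse/HSC query -------------------------------------------


def test_mouse_hsc_query_text_is_stable_and_contains_key_patterns():
    text = mouse_hsc_query()
    assert text == mouse_hsc_query()
    assert "?organism ao:preferred_equivalent obo:NCBITaxon_10090" in text
    assert "?experiment a obo:OBI_0000066" in text
    assert "PREFIX foaf: <http://xmlns.com/foaf/0.1>" in text


def test_mouse_hsc_query_equals_composed_annotation_query(seeded_repo, seeded_stores):
    public, _ = seeded_stores
    _, rows = sparql_select(public, mouse_hsc_query())
    titles_from_sparql = sorted(str(r[0]) for r in rows)
    composed = experiments_by_annotation(
        public,
        "organism",
        MOUSE,
        extra=[("cell_type", HEMATOPOIETIC_STEM_CELL)],
    )
    assert titles_from_sparql == sorted(t for _, t in composed)
    assert titles_from_sparql  # the fixture makes the query non-trivially satisfiable


# ---- DESCRIBE traversal ----------------------------------------------------


def test_traversal_of_worked_example_has_six_assays(worked_stores):
    public, _ = worked_stores
    record = describe_traverse(public, "http://example.org/experiment/13610")
    assert len(record["assays"]) == 6
    assert record["title"] == "DNA methylation in K562, LiPS and H1 cell lines"


def test_traversal_of_unknown_uri_is_not_found(worked_stores):
    public, _ = worked_stores
    with pytest.raises(KeyError):
        describe_traverse(public, "http://example.org/experiment/ghost")


def test_traversal_of_assayless_experiment_has_empty_assay_list():
    from semexp.model import Experiment, Repository

    repo = Repository(base_uri="http://example.org")
    repo.experiments.append(Experiment(id="bare", title="No assays", visibility="public"))
    public, _ = build_stores(repo)
    record = describe_traverse(public, "http://example.org/experiment/bare")
    assert record["assays"] == []


def _project_experiment(repo, exp):
    """Direct object-model projection in the traversal record shape."""
    base = repo.base_uri

    def term_rec(ref):
        term = repo.resolve(ref)
        return {
            "uri": f"{base}/term/{term.id}",
            "label": term.label,
            "class_uri": preferred_uri(repo, ref) or "",
        }

    assays = []
    for assay in sorted(exp.assays, key=lambda a: f"{base}/bioassay/{a.id}"):
        replicates = []
        for rep in sorted(assay.replicates, key=lambda r: f"{base}/replicate/{r.id}"):
            bm = repo.biomaterials[rep.biomaterial]
            replicates.append(
                {
                    "uri": f"{base}/replicate/{rep.id}",
                    "replicate_type": rep.replicate_type,
                    "biomaterial": {
                        "uri": f"{base}/biomaterial/{bm.id}",
                        "name": bm.name,
                        "annotations": {attr: term_rec(ref) for attr, ref in bm.annotations()},
                    },
                }
            )
        assays.append(
            {
                "uri": f"{base}/bioassay/{assay.id}",
                "name": assay.name,
                "platform": assay.platform,
                "raw_data_files": sorted(assay.raw_data_files),
                "replicates": replicates,
            }
        )
    return {
        "uri": f"{base}/experiment/{exp.id}",
        "title": exp.title,
        "description": exp.description,
        "created": exp.created,
        "modified": exp.modified,
        "assays": assays,
    }


def test_traversal_equals_object_model_projection_for_every_fixture_experiment(seeded_repo):
    _, admin = build_stores(seeded_repo)
    for exp in seeded_repo.experiments:
        record = describe_traverse(admin, f"{seeded_repo.base_uri}/experiment/{exp.id}")
        assert record == _project_experiment(seeded_repo, exp)


def test_traversal_is_independent_of_insertion_order(worked_repo):
    graphs = rdfgen.repository_to_rdf(worked_repo)[1]
    forward = TripleStore(tier="public")
    backward = TripleStore(tier="public")
    triples = sorted(graphs.graph)
    forward.index_triples(triples)
    backward.index_triples(reversed(triples))
    uri = "http://example.org/experiment/13610"
    assert describe_traverse(forward, uri) == describe_traverse(backward, uri)


# ---- sample tables ----------------------------------------------------------


def test_sample_table_row_count_equals_replicate_count(seeded_repo):
    _, admin = build_stores(seeded_repo)
    exp = seeded_repo.experiments[0]
    record = describe_traverse(admin, f"{seeded_repo.base_uri}/experiment/{exp.id}")
    n_reps = sum(len(a.replicates) for a in exp.assays)
    df = sample_table(record)
    assert len(df) == n_reps
    assert list(df.columns) == SAMPLE_TABLE_COLUMNS


def test_k562_rows_carry_the_cell_line_class_uri(worked_stores):
    public, _ = worked_stores
    record = describe_traverse(public, "http://example.org/experiment/13610")
    df = sample_table(record)
    k562 = df[df["cell_line"] == "K562"]
    assert len(k562) == 2  # two passages
    assert set(k562["cell_line_uri"]) == {"http://purl.obolibrary.org/obo/CLO_0007060"}


def test_empty_record_yields_zero_rows_with_full_header():
    record = {"assays": []}
    df = sample_table(record)
    assert len(df) == 0 and list(df.columns) == SAMPLE_TABLE_COLUMNS
    tsv = sample_table_tsv(record)
    assert tsv == "\t".join(SAMPLE_TABLE_COLUMNS) + "\n"


def test_sample_table_tsv_matches_dataframe(worked_stores):
    public, _ = worked_stores
    record = describe_traverse(public, "http://example.org/experiment/13610")
    tsv = sample_table_tsv(record)
    df = sample_table(record)
    lines = tsv.splitlines()
    assert len(lines) == len(df) + 1
    assert lines[0].split("\t") == list(df.columns)
    assert lines[1].split("\t") == list(df.iloc[0])
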