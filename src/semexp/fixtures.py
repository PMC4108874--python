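"""Synthetic fixtures: a mini cell ontology, a worked-example experiment
and seeded random repositories.

Everything here is generated in code so the whole stack is testable with no
network and no external ontology downloads.  Identifiers printed in the
public record (NCBITaxon_9606, UBERON_0000178, CLO_0007060, EFO_0003042,
DOID_8692, CL_0000763, CL_0000037, NCBITaxon_10090) are used verbatim so
queries against them are meaningful; classes whose real identifiers are not
part of the packaged knowledge (the eight myeloid descendant cell types,
the LiPS cell line, the measurement-type class) carry synthetic identifiers
in reserved ``clx:``/``scx:`` namespaces, with their real labels.
"""

from __future__ import annotations

import random

from .model import (
    Bioassay,
    Biomaterial,
    Citation,
    Experiment,
    Person,
    Replicate,
    Repository,
    Term,
    TermRef,
)
from .ontoload import OntologySnapshot
from .vocab import CLX_NS

__all__ = [
    "make_mini_cl",
    "make_worked_example",
    "make_repository",
    "MYELOID_DESCENDANT_LABELS",
    "MYELOID_CELL",
    "HEMATOPOIETIC_STEM_CELL",
    "CELL_ROOT",
    "MOUSE",
    "HUMAN",
]

OBO = "http://purl.obolibrary.org/obo/"
CELL_ROOT = OBO + "CL_0000000"
HEMATOPOIETIC_STEM_CELL = OBO + "CL_0000037"
MYELOID_CELL = OBO + "CL_0000763"
FIBROBLAST = OBO + "CL_0000057"
HUMAN = OBO + "NCBITaxon_9606"
MOUSE = OBO + "NCBITaxon_10090"

#: The eight myeloid descendant cell types, labels as curated in the Cell
#: Ontology; identifiers are synthetic (clx namespace).
MYELOID_DESCENDANT_LABELS = [
    "granulocyte monocyte progenitor cell",
    "megakaryocyte-erythroid progenitor cell",
    "mast cell progenitor",
    "myeloblast",
    "monoblast",
    "metamyelocyte",
    "myelocyte",
    "promyelocyte",
]

MYELOID_DEFINITION = (
    "A cell of the monocyte, granulocyte, mast cell, megakaryocyte, or erythroid lineage."
)


def myeloid_descendant_uri(i: int) -> str:
    return f"{CLX_NS}CLX_{i + 1:07d}"


def make_mini_cl() -> tuple[str, OntologySnapshot]:
    """A small cell-type hierarchy: cell > hematopoietic stem cell > myeloid
    cell > eight myeloid descendant types.  Returns (turtle text, snapshot);
    the Turtle is byte-stable and re-loadable by :func:`~semexp.ontoload.load_ontology`.
    """
    snap = OntologySnapshot()

    def add(uri: str, label: str, parent: str | None, definition: str | None = None) -> None:
        snap.classes.add(uri)
        snap.labels[uri] = label
        if definition:
            snap.definitions[uri] = definition
        if parent:
            snap.subclass_edges.add((uri, parent))

    add(CELL_ROOT, "cell", None)
    add(HEMATOPOIETIC_STEM_CELL, "hematopoietic stem cell", CELL_ROOT)
    add(MYELOID_CELL, "myeloid cell", HEMATOPOIETIC_STEM_CELL, MYELOID_DEFINITION)
    for i, label in enumerate(MYELOID_DESCENDANT_LABELS):
        add(myeloid_descendant_uri(i), label, MYELOID_CELL)
    snap.validate()

    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix obo: <http://purl.obolibrary.org/obo/> .",
        "",
    ]
    parents = {c: p for c, p in snap.subclass_edges}
    for uri in sorted(snap.classes):
        lines.append(f"<{uri}> a owl:Class ;")
        body = [f'    rdfs:label "{snap.labels[uri]}"']
        if uri in snap.definitions:
            body.append(f'    obo:IAO_0000115 "{snap.definitions[uri]}"')
        if uri in parents:
            body.append(f"    rdfs:subClassOf <{parents[uri]}>")
        lines.append(" ;\n".join(body) + " .")
        lines.append("")
    return "\n".join(lines), snap


# --------------------------------------------------------------------------
# Shared vocabulary pool


def _standard_vocabularies() -> dict[str, list[Term]]:
    def t(tid: str, vocab: str, label: str, *equivalents: str) -> Term:
        return Term(id=tid, vocabulary=vocab, label=label, equivalents=list(equivalents))

    vocabularies = {
        "Organism": [
            t("org-human", "Organism", "Human", "obo:NCBITaxon_9606"),
            t("org-mouse", "Organism", "Mouse", "obo:NCBITaxon_10090"),
        ],
        "Tissue": [
            t("tis-blood", "Tissue", "Blood", "obo:UBERON_0000178"),
            t("tis-bone-marrow", "Tissue", "Bone Marrow", "obo:UBERON_0002371"),
        ],
        "Cell Type": [
            t("ct-hsc", "Cell Type", "hematopoietic stem cell", "obo:CL_0000037"),
            t("ct-myeloid", "Cell Type", "myeloid cell", "obo:CL_0000763"),
            t("ct-fibroblast", "Cell Type", "Fibroblast", "obo:CL_0000057"),
        ]
        + [
            t(f"ct-myeloid-{i + 1}", "Cell Type", label, f"clx:CLX_{i + 1:07d}")
            for i, label in enumerate(MYELOID_DESCENDANT_LABELS)
        ],
        "Cell Line": [
            t("cl-k562", "Cell Line", "K562", "obo:CLO_0007060"),
            t("cl-h1", "Cell Line", "H1 (hESC)", "efo:EFO_0003042"),
            t("cl-lips", "Cell Line", "LiPS", "scx:SCX_0000001"),
        ],
        "Disease State": [
            t("ds-aml", "Disease State", "Myeloid Leukemia", "obo:DOID_8692"),
            t("ds-normal", "Disease State", "Normal", "scx:SCX_0000002"),
        ],
        "Treatment": [
            t("tr-dexamethasone", "Treatment", "Dexamethasone", "obo:CHEBI_41879"),
            t("tr-none", "Treatment", "Untreated", "scx:SCX_0000003"),
        ],
        "Developmental Stage": [
            t("st-adult", "Developmental Stage", "Adult", "efo:EFO_0001272"),
            t("st-embryonic", "Developmental Stage", "Embryonic", "scx:SCX_0000004"),
        ],
        "Measurement Type": [
            t(
                "mt-dna-methylation",
                "Measurement Type",
                "DNA Methylation Profiling (Bisulphite Sequencing)",
                "scx:SCX_0000010",
            ),
            t("mt-transcription", "Measurement Type", "Transcription Profiling", "scx:SCX_0000011"),
        ],
    }
    return vocabularies


def make_worked_example(base_uri: str = "http://example.org") -> Repository:
    """The worked-example repository: one public DNA-methylation experiment.

    A next-generation sequencing experiment measuring DNA methylation (by
    bisulphite sequencing) in the leukemia cell line K562, reprogrammed
    leukemia cell lines (LiPS) and the human embryonic stem cell line H1 —
    six bioassays on the cell lines at various passages, one biological
    replicate each, biomaterials fully annotated (Human, Blood, the
    cell-line terms, Myeloid Leukemia for the leukemia-derived lines).
    """
    vocabularies = _standard_vocabularies()
    human = TermRef("Organism", "Human")
    blood = TermRef("Tissue", "Blood")
    aml = TermRef("Disease State", "Myeloid Leukemia")

    lines = [("k562", "K562", aml), ("lips", "LiPS", aml), ("h1", "H1 (hESC)", None)]
    biomaterials: dict[str, Biomaterial] = {}
    assays: list[Bioassay] = []
    n = 0
    for line_id, line_label, disease in lines:
        for passage in (4, 9):
            n += 1
            bm_id = f"bm-{line_id}-p{passage}"
            biomaterials[bm_id] = Biomaterial(
                id=bm_id,
                name=f"{line_label} passage {passage}",
                organism=human,
                tissue=blood,
                cell_line=TermRef("Cell Line", line_label),
                disease_state=disease,
                free_attributes={"passage number": str(passage)},
            )
            assays.append(
                Bioassay(
                    id=f"assay-{n}",
                    name=f"Bisulphite sequencing of {line_label} passage {passage}",
                    platform="Illumina HiSeq 2000",
                    replicates=[
                        Replicate(id=f"rep-{n}", replicate_type="biological", biomaterial=bm_id)
                    ],
                    raw_data_files=[f"{line_id}_p{passage}.fastq"],
                )
            )

    people = {
        "p-researcher": Person(
            id="p-researcher",
            name="A. Researcher",
            affiliation="Stem Cell Institute",
            email="researcher@example.org",
        )
    }
    citations = {
        "c-methylation": Citation(
            id="c-methylation",
            title="DNA methylation dynamics of reprogrammed leukemia cell lines",
            authors=["A. Researcher", "B. Collaborator"],
            journal="Genome Research",
            year=2013,
            doi="10.1000/example.13610",
        )
    }
    experiment = Experiment(
        id="13610",
        title="DNA methylation in K562, LiPS and H1 cell lines",
        description=(
            "Bisulphite sequencing of the leukemia cell line K562, reprogrammed "
            "leukemia cell lines (LiPS) and the human embryonic stem cell line H1 "
            "at various passages."
        ),
        contributors=["p-researcher"],
        measurement_type=TermRef("Measurement Type", "DNA Methylation Profiling (Bisulphite Sequencing)"),
        protocol_overview="Genomic DNA was bisulphite converted and sequenced.",
        experimental_factors=["cell-line"],
        citations=["c-methylation"],
        external_links=[("GEO", "http://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSE00000")],
        assays=assays,
        visibility="public",
        created="2013-05-01T00:00:00",
        modified="2013-06-15T00:00:00",
    )
    return Repository(
        base_uri=base_uri,
        vocabularies=vocabularies,
        people=people,
        citations=citations,
        biomaterials=biomaterials,
        experiments=[experiment],
    )


_FIRST_NAMES = ["Ada", "Ben", "Chen", "Dana", "Elif", "Femi", "Grace", "Hugo"]
_LAST_NAMES = ["Okafor", "Silva", "Tanaka", "Novak", "Haddad", "Larsen"]
_PLATFORMS = ["Illumina HiSeq 2000", "Affymetrix U133", "Illumina NextSeq 500"]
_TOPICS = [
    "hematopoiesis",
    "myeloid differentiation",
    "stem cell reprogramming",
    "leukemia progression",
    "methylation dynamics",
    "lineage commitment",
]


def make_repository(
    n_experiments: int,
    public_fraction: float = 0.5,
    seed: int = 0,
    base_uri: str = "http://example.org",
) -> Repository:
    """A seeded-deterministic random repository.

    Annotations are drawn from the standard vocabulary pool (which includes
    mouse, hematopoietic stem cell and all eight myeloid descendant types,
    so subsumption and mouse/HSC queries are non-trivially satisfiable).
    Assays mix technical and biological replicates;
    ``floor(n_experiments * public_fraction)`` experiments are public.
    """
    if n_experiments < 0:
        raise ValueError("n_experiments must be >= 0")
    if not 0.0 <= public_fraction <= 1.0:
        raise ValueError("public_fraction must be in [0, 1]")
    rng = random.Random(seed)
    vocabularies = _standard_vocabularies()

    people = {}
    for i in range(6):
        pid = f"person-{i + 1}"
        people[pid] = Person(
            id=pid,
            name=f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}",
            affiliation="Example Institute",
        )
    citations = {}
    for i in range(4):
        cid = f"cit-{i + 1}"
        citations[cid] = Citation(
            id=cid,
            title=f"A study of {rng.choice(_TOPICS)}",
            authors=[f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}"],
            journal="Journal of Example Biology",
            year=rng.randint(2008, 2014),
        )

    n_public = int(n_experiments * public_fraction)
    visibilities = ["public"] * n_public + ["private"] * (n_experiments - n_public)
    rng.shuffle(visibilities)

    def pick(vocab: str) -> TermRef:
        term = rng.choice(vocabularies[vocab])
        return TermRef(vocab, term.label)

    biomaterials: dict[str, Biomaterial] = {}
    experiments: list[Experiment] = []
    for e in range(n_experiments):
        eid = f"exp-{e + 1:03d}"
        assays = []
        for a in range(rng.randint(1, 3)):
            aid = f"{eid}-assay-{a + 1}"
            n_reps = rng.randint(1, 3)
            technical = rng.random() < 0.3
            reps = []
            if technical:
                bm_id = _make_biomaterial(rng, biomaterials, vocabularies, f"{aid}-bm-1", pick)
                for r in range(n_reps):
                    reps.append(Replicate(id=f"{aid}-rep-{r + 1}", replicate_type="technical", biomaterial=bm_id))
            else:
                for r in range(n_reps):
                    bm_id = _make_biomaterial(rng, biomaterials, vocabularies, f"{aid}-bm-{r + 1}", pick)
                    reps.append(Replicate(id=f"{aid}-rep-{r + 1}", replicate_type="biological", biomaterial=bm_id))
            assays.append(
                Bioassay(
                    id=aid,
                    name=f"Assay {a + 1} of {eid}",
                    platform=rng.choice(_PLATFORMS),
                    replicates=reps,
                    raw_data_files=[f"{aid}.fastq"],
                )
            )
        experiments.append(
            Experiment(
                id=eid,
                title=f"Experiment {e + 1:03d}: {rng.choice(_TOPICS)}",
                description=f"Synthetic experiment {e + 1} for offline testing.",
                contributors=[rng.choice(sorted(people))],
                measurement_type=pick("Measurement Type"),
                experimental_factors=rng.sample(["cell-line", "treatment", "time"], rng.randint(0, 2)),
                citations=[rng.choice(sorted(citations))] if rng.random() < 0.5 else [],
                external_links=[],
                assays=assays,
                visibility=visibilities[e],
                created=f"20{rng.randint(10, 14)}-0{rng.randint(1, 9)}-1{rng.randint(0, 9)}T00:00:00",
                modified="2014-06-03T00:00:00",
            )
        )

    return Repository(
        base_uri=base_uri,
        vocabularies=vocabularies,
        people=people,
        citations=citations,
        biomaterials=biomaterials,
        experiments=experiments,
    )


def _make_biomaterial(rng, biomaterials, vocabularies, bm_id, pick) -> str:
    kwargs = {}
    for attr, vocab, prob in [
        ("developmental_stage", "Developmental Stage", 0.5),
        ("tissue", "Tissue", 0.8),
        ("cell_type", "Cell Type", 0.9),
        ("cell_line", "Cell Line", 0.4),
        ("disease_state", "Disease State", 0.5),
        ("treatment", "Treatment", 0.5),
    ]:
        if rng.random() < prob:
            kwargs[attr] = pick(vocab)
    biomaterials[bm_id] = Biomaterial(
        id=bm_id,
        name=f"Sample {bm_id}",
        organism=pick("Organism"),
        free_attributes={"passage number": str(rng.randint(1, 20))} if rng.random() < 0.3 else {},
        **kwargs,
    )
    return bm_id
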