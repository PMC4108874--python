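"""In-memory model of a genomics-experiment repository.

The model follows the four-level experiment structure used by semantic
experiment repositories: an *experiment* (an OBI investigation) is composed
of *bioassays*; each bioassay is performed on one or more *replicates*
(technical or biological); each replicate references the *biomaterial* that
was assayed.  Biomaterials are deeply annotated with controlled-vocabulary
terms (organism, tissue, cell type, cell line, disease state, treatment,
developmental stage), and every vocabulary term is mapped to one or more
external ontology classes (NCBITaxon, UBERON/FMA, CL, CLO, EFO, DOID,
ChEBI, ...).

Identifiers are caller-supplied URL-safe slugs; URI minting happens in
:mod:`semexp.rdfgen`.  Visibility (public/private) is set per experiment and
inherited by all child resources.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterator

import yaml

__all__ = [
    "Person",
    "Citation",
    "Term",
    "TermRef",
    "Biomaterial",
    "Replicate",
    "Bioassay",
    "Experiment",
    "Repository",
    "ValidationIssue",
    "RepositoryParseError",
    "validate_repository",
    "load_repository",
    "loads_repository",
    "dump_repository",
    "BIOMATERIAL_ANNOTATION_FIELDS",
]

#: Ordered biomaterial annotation attributes (order is the canonical column
#: order used by RDF generation, ISA-Tab export and sample tables).
BIOMATERIAL_ANNOTATION_FIELDS = (
    "organism",
    "developmental_stage",
    "tissue",
    "cell_type",
    "cell_line",
    "disease_state",
    "treatment",
)

_SLUG_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.-]*$")


class RepositoryParseError(ValueError):
    """Raised when a repository document violates the schema.

    The message names the path to the offending field, e.g.
    ``experiments[0].assays[1].replicates[0].biomaterial``.
    """


@dataclass(frozen=True)
class TermRef:
    """Reference to a vocabulary term by (vocabulary, label)."""

    vocabulary: str
    label: str


@dataclass
class Person:
    id: str
    name: str
    affiliation: str | None = None
    email: str | None = None


@dataclass
class Citation:
    id: str
    title: str
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    year: int | None = None
    doi: str | None = None
    pmid: str | None = None


@dataclass
class Term:
    """A controlled-vocabulary entry mapped to external ontology classes.

    ``equivalents`` is an ordered list of CURIEs/URIs; the first one is the
    preferred equivalent emitted as ``ao:preferred_equivalent``.  A term with
    no equivalents is flagged "unmapped" by validation (warning, not error).
    """

    id: str
    vocabulary: str
    label: str
    equivalents: list[str] = field(default_factory=list)


@dataclass
class Biomaterial:
    id: str
    name: str
    organism: TermRef | None = None
    developmental_stage: TermRef | None = None
    tissue: TermRef | None = None
    cell_type: TermRef | None = None
    cell_line: TermRef | None = None
    disease_state: TermRef | None = None
    treatment: TermRef | None = None
    free_attributes: dict[str, str] = field(default_factory=dict)

    def annotations(self) -> Iterator[tuple[str, TermRef]]:
        """Yield populated (attribute, term reference) pairs in canonical order."""
        for attr in BIOMATERIAL_ANNOTATION_FIELDS:
            ref = getattr(self, attr)
            if ref is not None:
                yield attr, ref


@dataclass
class Replicate:
    id: str
    replicate_type: str  # "technical" | "biological"
    biomaterial: str  # biomaterial id


@dataclass
class Bioassay:
    id: str
    name: str
    platform: str = ""
    protocol: str | None = None
    replicates: list[Replicate] = field(default_factory=list)
    raw_data_files: list[str] = field(default_factory=list)


@dataclass
class Experiment:
    id: str
    title: str
    description: str = ""
    contributors: list[str] = field(default_factory=list)  # person ids
    measurement_type: TermRef | None = None
    protocol_overview: str = ""
    experimental_factors: list[str] = field(default_factory=list)
    citations: list[str] = field(default_factory=list)  # citation ids
    external_links: list[tuple[str, str]] = field(default_factory=list)
    assays: list[Bioassay] = field(default_factory=list)
    visibility: str = "private"  # "public" | "private"
    created: str = "1970-01-01T00:00:00"
    modified: str = "1970-01-01T00:00:00"


@dataclass
class Repository:
    base_uri: str
    vocabularies: dict[str, list[Term]] = field(default_factory=dict)
    people: dict[str, Person] = field(default_factory=dict)
    citations: dict[str, Citation] = field(default_factory=dict)
    biomaterials: dict[str, Biomaterial] = field(default_factory=dict)
    experiments: list[Experiment] = field(default_factory=list)

    def resolve(self, ref: TermRef) -> Term | None:
        """Exact, case-sensitive lookup of a term reference; None if absent."""
        for term in self.vocabularies.get(ref.vocabulary, []):
            if term.label == ref.label:
                return term
        return None

    def experiment(self, experiment_id: str) -> Experiment:
        for exp in self.experiments:
            if exp.id == experiment_id:
                return exp
        raise KeyError(experiment_id)


# --------------------------------------------------------------------------
# Validation

ValidationIssue = tuple[str, str, str]  # (severity, entity id, message)


def _check_id(issues: list[ValidationIssue], kind: str, entity_id: Any) -> None:
    if not isinstance(entity_id, str) or not _SLUG_RE.match(entity_id):
        issues.append(("error", str(entity_id), f"{kind} id is not a URL-safe slug"))


def validate_repository(repo: Repository) -> list[ValidationIssue]:
    """Check every structural invariant of the repository.

    Returns a deterministic report sorted by entity id: a list of
    ``(severity, entity_id, message)`` tuples.  An empty report means the
    repository is well-formed.  Malformed references are report entries, not
    exceptions.
    """
    issues: list[ValidationIssue] = []

    seen_by_kind: dict[str, set[str]] = {}

    def check_unique(kind: str, entity_id: str) -> None:
        seen = seen_by_kind.setdefault(kind, set())
        if entity_id in seen:
            issues.append(("error", entity_id, f"duplicate {kind} id"))
        seen.add(entity_id)

    for pid, person in repo.people.items():
        _check_id(issues, "person", pid)
        check_unique("person", pid)
        if not person.name:
            issues.append(("error", pid, "person name is empty"))

    for cid, cit in repo.citations.items():
        _check_id(issues, "citation", cid)
        check_unique("citation", cid)
        if not cit.title:
            issues.append(("error", cid, "citation title is empty"))

    for vocab_name, terms in repo.vocabularies.items():
        labels_seen: set[str] = set()
        for term in terms:
            _check_id(issues, "term", term.id)
            check_unique("term", term.id)
            if not term.label:
                issues.append(("error", term.id, "term label is empty"))
            if term.label in labels_seen:
                issues.append(
                    ("error", term.id, f"duplicate label {term.label!r} in vocabulary {vocab_name!r}")
                )
            labels_seen.add(term.label)
            if not term.equivalents:
                issues.append(("warning", term.id, "term is unmapped (no ontology equivalents)"))

    def check_ref(entity_id: str, attr: str, ref: TermRef) -> None:
        if ref.vocabulary not in repo.vocabularies:
            issues.append(("error", entity_id, f"{attr} references unknown vocabulary {ref.vocabulary!r}"))
        elif repo.resolve(ref) is None:
            issues.append(
                ("error", entity_id, f"{attr} references unknown term {ref.label!r} in vocabulary {ref.vocabulary!r}")
            )

    for bid, bm in repo.biomaterials.items():
        _check_id(issues, "biomaterial", bid)
        check_unique("biomaterial", bid)
        if bm.organism is None:
            issues.append(("error", bid, "biomaterial has no organism annotation"))
        for attr, ref in bm.annotations():
            check_ref(bid, attr, ref)

    for exp in repo.experiments:
        _check_id(issues, "experiment", exp.id)
        check_unique("experiment", exp.id)
        if not exp.title:
            issues.append(("error", exp.id, "experiment title is empty"))
        if exp.visibility not in ("public", "private"):
            issues.append(("error", exp.id, f"invalid visibility {exp.visibility!r}"))
        if exp.measurement_type is not None:
            check_ref(exp.id, "measurement_type", exp.measurement_type)
        for pid in exp.contributors:
            if pid not in repo.people:
                issues.append(("error", exp.id, f"contributor {pid!r} does not resolve"))
        for cid in exp.citations:
            if cid not in repo.citations:
                issues.append(("error", exp.id, f"citation {cid!r} does not resolve"))
        assay_ids_here: set[str] = set()
        for assay in exp.assays:
            _check_id(issues, "bioassay", assay.id)
            check_unique("bioassay", assay.id)
            if assay.id in assay_ids_here:
                issues.append(("error", exp.id, f"duplicate assay id {assay.id!r} within experiment"))
            assay_ids_here.add(assay.id)
            if not assay.replicates:
                issues.append(("error", assay.id, "bioassay has no replicates"))
            tech_mats: set[str] = set()
            bio_mats: list[str] = []
            for rep in assay.replicates:
                _check_id(issues, "replicate", rep.id)
                check_unique("replicate", rep.id)
                if rep.replicate_type not in ("technical", "biological"):
                    issues.append(("error", rep.id, f"invalid replicate type {rep.replicate_type!r}"))
                if rep.biomaterial not in repo.biomaterials:
                    issues.append(("error", rep.id, f"biomaterial {rep.biomaterial!r} does not resolve"))
                    continue
                if rep.replicate_type == "technical":
                    tech_mats.add(rep.biomaterial)
                elif rep.replicate_type == "biological":
                    bio_mats.append(rep.biomaterial)
            if len(tech_mats) > 1:
                issues.append(
                    ("error", assay.id, "technical replicates reference different biomaterials")
                )
            if len(bio_mats) != len(set(bio_mats)):
                issues.append(
                    ("error", assay.id, "biological replicates reference non-distinct biomaterials")
                )

    return sorted(issues)


# --------------------------------------------------------------------------
# Serialization (YAML/JSON document schema; see README for the schema)


def _ref_to_doc(ref: TermRef | None) -> dict[str, str] | None:
    if ref is None:
        return None
    return {"vocabulary": ref.vocabulary, "label": ref.label}


def _ref_from_doc(doc: Any, path: str, vocabularies: dict[str, list[Term]]) -> TermRef:
    if not isinstance(doc, dict) or "vocabulary" not in doc or "label" not in doc:
        raise RepositoryParseError(f"{path}: expected mapping with 'vocabulary' and 'label'")
    if doc["vocabulary"] not in vocabularies:
        raise RepositoryParseError(f"{path}: unknown vocabulary {doc['vocabulary']!r}")
    return TermRef(vocabulary=doc["vocabulary"], label=doc["label"])


def dump_repository(repo: Repository) -> str:
    """Serialize a repository to a canonical YAML document.

    The output is byte-stable: two dumps of equal repositories are identical,
    and ``load_repository(dump_repository(r))`` reproduces ``r`` field by
    field.
    """
    doc: dict[str, Any] = {"base_uri": repo.base_uri}
    doc["vocabularies"] = {
        name: [
            {"id": t.id, "label": t.label, "equivalents": list(t.equivalents)}
            for t in terms
        ]
        for name, terms in sorted(repo.vocabularies.items())
    }
    doc["people"] = [
        {
            "id": p.id,
            "name": p.name,
            **({"affiliation": p.affiliation} if p.affiliation else {}),
            **({"email": p.email} if p.email else {}),
        }
        for p in sorted(repo.people.values(), key=lambda p: p.id)
    ]
    doc["citations"] = [
        {
            "id": c.id,
            "title": c.title,
            "authors": list(c.authors),
            "journal": c.journal,
            **({"year": c.year} if c.year is not None else {}),
            **({"doi": c.doi} if c.doi else {}),
            **({"pmid": c.pmid} if c.pmid else {}),
        }
        for c in sorted(repo.citations.values(), key=lambda c: c.id)
    ]
    doc["biomaterials"] = [
        {
            "id": b.id,
            "name": b.name,
            **{attr: _ref_to_doc(ref) for attr, ref in b.annotations()},
            **({"free_attributes": dict(sorted(b.free_attributes.items()))} if b.free_attributes else {}),
        }
        for b in sorted(repo.biomaterials.values(), key=lambda b: b.id)
    ]
    doc["experiments"] = [
        {
            "id": e.id,
            "title": e.title,
            "description": e.description,
            "visibility": e.visibility,
            "created": e.created,
            "modified": e.modified,
            "contributors": list(e.contributors),
            **(
                {"measurement_type": _ref_to_doc(e.measurement_type)}
                if e.measurement_type is not None
                else {}
            ),
            "protocol_overview": e.protocol_overview,
            "experimental_factors": list(e.experimental_factors),
            "citations": list(e.citations),
            "external_links": [{"label": l, "url": u} for l, u in e.external_links],
            "assays": [
                {
                    "id": a.id,
                    "name": a.name,
                    "platform": a.platform,
                    **({"protocol": a.protocol} if a.protocol else {}),
                    "raw_data_files": list(a.raw_data_files),
                    "replicates": [
                        {
                            "id": r.id,
                            "replicate_type": r.replicate_type,
                            "biomaterial": r.biomaterial,
                        }
                        for r in a.replicates
                    ],
                }
                for a in e.assays
            ],
        }
        for e in repo.experiments
    ]
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, default_flow_style=False)


def _require(doc: dict, key: str, path: str) -> Any:
    if key not in doc:
        raise RepositoryParseError(f"{path}.{key}: missing required field")
    return doc[key]


def loads_repository(text: str) -> Repository:
    """Parse a repository from YAML (or JSON, a YAML subset) text."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough
        raise RepositoryParseError(f"document is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise RepositoryParseError("top level: expected a mapping")

    vocabularies: dict[str, list[Term]] = {}
    for name, entries in (doc.get("vocabularies") or {}).items():
        terms = []
        for i, t in enumerate(entries or []):
            path = f"vocabularies[{name!r}][{i}]"
            terms.append(
                Term(
                    id=_require(t, "id", path),
                    vocabulary=name,
                    label=_require(t, "label", path),
                    equivalents=list(t.get("equivalents") or []),
                )
            )
        vocabularies[name] = terms

    people = {}
    for i, p in enumerate(doc.get("people") or []):
        path = f"people[{i}]"
        people[_require(p, "id", path)] = Person(
            id=p["id"],
            name=_require(p, "name", path),
            affiliation=p.get("affiliation"),
            email=p.get("email"),
        )

    citations = {}
    for i, c in enumerate(doc.get("citations") or []):
        path = f"citations[{i}]"
        citations[_require(c, "id", path)] = Citation(
            id=c["id"],
            title=_require(c, "title", path),
            authors=list(c.get("authors") or []),
            journal=c.get("journal", ""),
            year=c.get("year"),
            doi=c.get("doi"),
            pmid=c.get("pmid"),
        )

    biomaterials = {}
    for i, b in enumerate(doc.get("biomaterials") or []):
        path = f"biomaterials[{i}]"
        kwargs: dict[str, Any] = {}
        for attr in BIOMATERIAL_ANNOTATION_FIELDS:
            if b.get(attr) is not None:
                kwargs[attr] = _ref_from_doc(b[attr], f"{path}.{attr}", vocabularies)
        biomaterials[_require(b, "id", path)] = Biomaterial(
            id=b["id"],
            name=_require(b, "name", path),
            free_attributes=dict(b.get("free_attributes") or {}),
            **kwargs,
        )

    experiments = []
    for i, e in enumerate(doc.get("experiments") or []):
        path = f"experiments[{i}]"
        assays = []
        for j, a in enumerate(e.get("assays") or []):
            apath = f"{path}.assays[{j}]"
            replicates = []
            for k, r in enumerate(a.get("replicates") or []):
                rpath = f"{apath}.replicates[{k}]"
                replicates.append(
                    Replicate(
                        id=_require(r, "id", rpath),
                        replicate_type=_require(r, "replicate_type", rpath),
                        biomaterial=_require(r, "biomaterial", rpath),
                    )
                )
            assays.append(
                Bioassay(
                    id=_require(a, "id", apath),
                    name=_require(a, "name", apath),
                    platform=a.get("platform", ""),
                    protocol=a.get("protocol"),
                    replicates=replicates,
                    raw_data_files=list(a.get("raw_data_files") or []),
                )
            )
        mt = e.get("measurement_type")
        experiments.append(
            Experiment(
                id=_require(e, "id", path),
                title=_require(e, "title", path),
                description=e.get("description", ""),
                visibility=_require(e, "visibility", path),
                created=str(e.get("created", "1970-01-01T00:00:00")),
                modified=str(e.get("modified", "1970-01-01T00:00:00")),
                contributors=list(e.get("contributors") or []),
                measurement_type=(
                    _ref_from_doc(mt, f"{path}.measurement_type", vocabularies)
                    if mt is not None
                    else None
                ),
                protocol_overview=e.get("protocol_overview", ""),
                experimental_factors=list(e.get("experimental_factors") or []),
                citations=list(e.get("citations") or []),
                external_links=[
                    (l["label"], l["url"]) for l in (e.get("external_links") or [])
                ],
                assays=assays,
            )
        )

    return Repository(
        base_uri=_require(doc, "base_uri", "top level"),
        vocabularies=vocabularies,
        people=people,
        citations=citations,
        biomaterials=biomaterials,
        experiments=experiments,
    )


def load_repository(source: str) -> Repository:
    """Load a repository document from a file path."""
    with open(source, encoding="utf-8") as fh:
        return loads_repository(fh.read())
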