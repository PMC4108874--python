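"""ISA-Tab export of experiments, plus a reader for round-trip checking.

The exporter writes the classic three-file ISA-Tab v1.0 layout:

* ``i_<experiment>.txt`` — investigation metadata: ontology sources (one
  per Term Source REF used anywhere in the export, with its namespace URI
  as the source file), study identifier/title/description, publications,
  per-assay measurement type + platform + file name columns, and contacts;
* ``s_<experiment>.txt`` — one row per distinct biomaterial, with a
  ``Characteristics[...]`` column per populated annotation attribute, each
  followed by ``Term Source REF`` and ``Term Accession Number`` columns
  (accession = local part of the external class URI, source = the
  ontology's identifier prefix, e.g. CLO for ``CLO_0007060``);
* ``a_<experiment>_<assay>.txt`` — one file per bioassay, one row per
  replicate, linking Sample Name → Assay Name → Raw Data File.

Files are tab-delimited UTF-8; fields containing tabs, quotes or newlines
are quoted CSV-style.  ``read_isatab`` re-loads an exported directory into
a partial :class:`~semexp.model.Repository` that re-exports byte-for-byte
identically — the round-trip oracle used by the tests.
"""

from __future__ import annotations

import csv
import io
import os
import re
from pathlib import Path

from .model import (
    BIOMATERIAL_ANNOTATION_FIELDS,
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
from .vocab import MappingRegistry, compress_uri, default_registry, expand_curie

__all__ = ["export_isatab", "read_isatab", "UnmappedTermError", "IsaTabParseError"]

ATTRIBUTE_TITLES = {
    "organism": "Organism",
    "developmental_stage": "Developmental Stage",
    "tissue": "Tissue",
    "cell_type": "Cell Type",
    "cell_line": "Cell Line",
    "disease_state": "Disease State",
    "treatment": "Treatment",
}
_TITLE_TO_ATTR = {v: k for k, v in ATTRIBUTE_TITLES.items()}


class UnmappedTermError(ValueError):
    """A mandatory term had no ontology equivalent while strict mode was on."""


class IsaTabParseError(ValueError):
    pass


def _term_fields(repo, ref: TermRef, registry: MappingRegistry, strict: bool) -> tuple[str, str, str, str]:
    """(label, source, accession, namespace) for a term reference."""
    term = repo.resolve(ref)
    if term is None:
        raise ValueError(f"unresolved term reference {ref!r}")
    if not term.equivalents:
        if strict:
            raise UnmappedTermError(
                f"term {term.label!r} in vocabulary {term.vocabulary!r} has no ontology mapping"
            )
        return term.label, "", "", ""
    uri = expand_curie(term.equivalents[0], registry.prefix_table)
    ns, _, local = uri.rpartition("/")
    if "#" in local:
        ns2, _, local = uri.rpartition("#")
        ns = ns2 + "#"
    else:
        ns = ns + "/"
    source = local.split("_")[0] if "_" in local else local.upper()
    return term.label, source, local, ns


def _write_rows(path: Path, rows: list[list[str]]) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerows(rows)
    path.write_text(buf.getvalue(), encoding="utf-8")


def export_isatab(
    exp: Experiment,
    repo: Repository,
    out_dir: str | os.PathLike,
    registry: MappingRegistry | None = None,
    strict: bool = True,
) -> list[str]:
    """Write i_/s_/a_ files for one experiment; returns the file paths."""
    registry = registry or default_registry()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # distinct biomaterials referenced by this experiment, sorted by id
    bm_ids = sorted({rep.biomaterial for assay in exp.assays for rep in assay.replicates})
    biomaterials = [repo.biomaterials[b] for b in bm_ids]

    # ontology sources used anywhere in the export
    sources: dict[str, str] = {}

    def register(ref: TermRef) -> tuple[str, str, str]:
        label, source, accession, ns = _term_fields(repo, ref, registry, strict)
        if source:
            sources[source] = ns
        return label, source, accession

    meas = register(exp.measurement_type) if exp.measurement_type is not None else ("", "", "")
    bm_cells: dict[str, dict[str, tuple[str, str, str]]] = {}
    used_attrs: list[str] = []
    for attr in BIOMATERIAL_ANNOTATION_FIELDS:
        if any(getattr(b, attr) is not None for b in biomaterials):
            used_attrs.append(attr)
    free_keys = sorted({k for b in biomaterials for k in b.free_attributes})
    for b in biomaterials:
        bm_cells[b.id] = {
            attr: register(getattr(b, attr)) for attr in used_attrs if getattr(b, attr) is not None
        }

    # ---- investigation file -------------------------------------------
    src_names = sorted(sources)
    assay_files = [f"a_{exp.id}_{assay.id}.txt" for assay in exp.assays]
    publications = [repo.citations[c] for c in exp.citations]
    contacts = [repo.people[p] for p in exp.contributors]
    irows: list[list[str]] = [
        ["ONTOLOGY SOURCE REFERENCE"],
        ["Term Source Name"] + src_names,
        ["Term Source File"] + [sources[s] for s in src_names],
        ["INVESTIGATION"],
        ["Investigation Identifier", exp.id],
        ["Investigation Title", exp.title],
        ["STUDY"],
        ["Study Identifier", exp.id],
        ["Study Title", exp.title],
        ["Study Description", exp.description],
        ["Study File Name", f"s_{exp.id}.txt"],
        ["STUDY PUBLICATIONS"],
        ["Study Publication Title"] + [c.title for c in publications],
        ["Study Publication Author List"] + [", ".join(c.authors) for c in publications],
        ["Study Publication DOI"] + [c.doi or "" for c in publications],
        ["STUDY ASSAYS"],
        ["Study Assay Measurement Type"] + [meas[0]] * len(exp.assays),
        ["Study Assay Measurement Type Term Source REF"] + [meas[1]] * len(exp.assays),
        ["Study Assay Measurement Type Term Accession Number"] + [meas[2]] * len(exp.assays),
        ["Study Assay Technology Platform"] + [a.platform for a in exp.assays],
        ["Study Assay File Name"] + assay_files,
        ["STUDY CONTACTS"],
        ["Study Person Name"] + [p.name for p in contacts],
        ["Study Person Affiliation"] + [p.affiliation or "" for p in contacts],
        ["Study Person Email"] + [p.email or "" for p in contacts],
    ]
    ipath = out / f"i_{exp.id}.txt"
    _write_rows(ipath, irows)

    # ---- study sample file --------------------------------------------
    header = ["Sample Name", "Comment[Material Name]"]
    for attr in used_attrs:
        header += [f"Characteristics[{ATTRIBUTE_TITLES[attr]}]", "Term Source REF", "Term Accession Number"]
    header += [f"Comment[{k}]" for k in free_keys]
    srows = [header]
    for b in biomaterials:
        row = [b.id, b.name]
        for attr in used_attrs:
            cell = bm_cells[b.id].get(attr)
            row += list(cell) if cell else ["", "", ""]
        row += [b.free_attributes.get(k, "") for k in free_keys]
        srows.append(row)
    spath = out / f"s_{exp.id}.txt"
    _write_rows(spath, srows)

    # ---- assay files ---------------------------------------------------
    paths = [str(ipath), str(spath)]
    for assay, fname in zip(exp.assays, assay_files):
        arows = [["Sample Name", "Comment[Replicate Name]", "Comment[Replicate Type]", "Assay Name", "Raw Data File"]]
        raw = ";".join(assay.raw_data_files)
        for rep in assay.replicates:
            arows.append([rep.biomaterial, rep.id, rep.replicate_type, assay.name, raw])
        apath = out / fname
        _write_rows(apath, arows)
        paths.append(str(apath))
    return paths


# --------------------------------------------------------------------------
# Reader


def _read_rows(path: Path) -> list[list[str]]:
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            return [row for row in csv.reader(fh, delimiter="\t")]
    except OSError as exc:
        raise IsaTabParseError(f"{path}: {exc}") from exc


def _sections(rows: list[list[str]]) -> dict[str, dict[str, list[str]]]:
    sections: dict[str, dict[str, list[str]]] = {}
    current: dict[str, list[str]] | None = None
    for row in rows:
        if not row:
            continue
        if len(row) == 1 and row[0].isupper():
            current = sections.setdefault(row[0], {})
        elif current is not None:
            current[row[0]] = row[1:]
        else:
            raise IsaTabParseError(f"row outside any section: {row!r}")
    return sections


def _slugify(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "-", text).strip("-").lower() or "x"


def read_isatab(directory: str | os.PathLike, registry: MappingRegistry | None = None) -> Repository:
    """Re-load an exported ISA-Tab directory into a partial repository.

    Only the information the exporter writes is reconstructed (titles,
    contacts, publications, assay/replicate structure and biomaterial
    annotations); identifiers not present in the files (vocabulary names,
    person/citation ids) are regenerated deterministically.  The result
    re-exports byte-identically.
    """
    registry = registry or default_registry()
    directory = Path(directory)
    ifiles = sorted(directory.glob("i_*.txt"))
    if not ifiles:
        raise IsaTabParseError(f"no investigation (i_*.txt) file in {directory}")
    sections = _sections(_read_rows(ifiles[0]))

    try:
        exp_id = sections["STUDY"]["Study Identifier"][0]
        title = sections["STUDY"]["Study Title"][0]
    except (KeyError, IndexError) as exc:
        raise IsaTabParseError(f"{ifiles[0]}: missing STUDY identifier/title") from exc
    desc_row = sections["STUDY"].get("Study Description", [])
    description = desc_row[0] if desc_row else ""

    src_section = sections.get("ONTOLOGY SOURCE REFERENCE", {})
    src_names = src_section.get("Term Source Name", [])
    src_files = src_section.get("Term Source File", [])
    namespaces = dict(zip(src_names, src_files))

    vocabularies: dict[str, list[Term]] = {}

    def make_ref(vocab: str, label: str, source: str, accession: str) -> TermRef:
        equivalents = []
        if accession:
            ns = namespaces.get(source, "http://purl.obolibrary.org/obo/")
            equivalents = [compress_uri(ns + accession, registry.prefix_table)]
        terms = vocabularies.setdefault(vocab, [])
        for t in terms:
            if t.label == label:
                return TermRef(vocab, label)
        terms.append(Term(id=f"{_slugify(vocab)}-{_slugify(label)}", vocabulary=vocab, label=label, equivalents=equivalents))
        return TermRef(vocab, label)

    # publications / contacts
    pubs = sections.get("STUDY PUBLICATIONS", {})
    citations: dict[str, Citation] = {}
    cit_ids = []
    for i, ptitle in enumerate(pubs.get("Study Publication Title", [])):
        cid = f"cit-{i + 1}"
        authors_field = pubs.get("Study Publication Author List", [])
        doi_field = pubs.get("Study Publication DOI", [])
        authors = [a for a in (authors_field[i].split(", ") if i < len(authors_field) and authors_field[i] else [])]
        citations[cid] = Citation(
            id=cid,
            title=ptitle,
            authors=authors,
            doi=(doi_field[i] or None) if i < len(doi_field) else None,
        )
        cit_ids.append(cid)

    contacts_sec = sections.get("STUDY CONTACTS", {})
    people: dict[str, Person] = {}
    person_ids = []
    for i, name in enumerate(contacts_sec.get("Study Person Name", [])):
        pid = f"person-{i + 1}"
        aff = contacts_sec.get("Study Person Affiliation", [])
        email = contacts_sec.get("Study Person Email", [])
        people[pid] = Person(
            id=pid,
            name=name,
            affiliation=(aff[i] or None) if i < len(aff) else None,
            email=(email[i] or None) if i < len(email) else None,
        )
        person_ids.append(pid)

    # measurement type
    assays_sec = sections.get("STUDY ASSAYS", {})
    meas_labels = assays_sec.get("Study Assay Measurement Type", [])
    measurement_type = None
    if meas_labels and meas_labels[0]:
        source = assays_sec.get("Study Assay Measurement Type Term Source REF", [""])[0]
        accession = assays_sec.get("Study Assay Measurement Type Term Accession Number", [""])[0]
        measurement_type = make_ref("Measurement Type", meas_labels[0], source, accession)

    # study sample table -> biomaterials
    srows = _read_rows(directory / f"s_{exp_id}.txt")
    if not srows:
        raise IsaTabParseError(f"empty study file s_{exp_id}.txt")
    header = srows[0]
    biomaterials: dict[str, Biomaterial] = {}
    for lineno, row in enumerate(srows[1:], start=2):
        row = row + [""] * (len(header) - len(row))
        bm_kwargs: dict[str, TermRef] = {}
        free: dict[str, str] = {}
        bm_id = row[header.index("Sample Name")]
        name = row[header.index("Comment[Material Name]")] if "Comment[Material Name]" in header else bm_id
        col = 0
        while col < len(header):
            h = header[col]
            m = re.match(r"^Characteristics\[(.+)\]$", h)
            if m:
                attr = _TITLE_TO_ATTR.get(m.group(1))
                if attr is None:
                    raise IsaTabParseError(f"s_{exp_id}.txt line {lineno}: unknown characteristic {m.group(1)!r}")
                label, source, accession = row[col], row[col + 1], row[col + 2]
                if label:
                    bm_kwargs[attr] = make_ref(m.group(1), label, source, accession)
                col += 3
                continue
            m = re.match(r"^Comment\[(.+)\]$", h)
            if m and m.group(1) != "Material Name" and row[col]:
                free[m.group(1)] = row[col]
            col += 1
        biomaterials[bm_id] = Biomaterial(id=bm_id, name=name, free_attributes=free, **bm_kwargs)

    # assay files -> bioassays + replicates
    assay_files = assays_sec.get("Study Assay File Name", [])
    platforms = assays_sec.get("Study Assay Technology Platform", [])
    assays: list[Bioassay] = []
    for i, fname in enumerate(assay_files):
        m = re.match(rf"^a_{re.escape(exp_id)}_(.+)\.txt$", fname)
        if not m:
            raise IsaTabParseError(f"unexpected assay file name {fname!r}")
        assay_id = m.group(1)
        arows = _read_rows(directory / fname)
        aheader = arows[0]
        replicates = []
        assay_name = assay_id
        raw_files: list[str] = []
        for row in arows[1:]:
            row = row + [""] * (len(aheader) - len(row))
            replicates.append(
                Replicate(
                    id=row[aheader.index("Comment[Replicate Name]")],
                    replicate_type=row[aheader.index("Comment[Replicate Type]")],
                    biomaterial=row[aheader.index("Sample Name")],
                )
            )
            assay_name = row[aheader.index("Assay Name")]
            raw = row[aheader.index("Raw Data File")]
            raw_files = [f for f in raw.split(";") if f]
        assays.append(
            Bioassay(
                id=assay_id,
                name=assay_name,
                platform=platforms[i] if i < len(platforms) else "",
                replicates=replicates,
                raw_data_files=raw_files,
            )
        )

    exp = Experiment(
        id=exp_id,
        title=title,
        description=description,
        contributors=person_ids,
        measurement_type=measurement_type,
        citations=cit_ids,
        assays=assays,
        visibility="private",
    )
    return Repository(
        base_uri="http://example.org",
        vocabularies=vocabularies,
        people=people,
        citations=citations,
        biomaterials=biomaterials,
        experiments=[exp],
    )
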