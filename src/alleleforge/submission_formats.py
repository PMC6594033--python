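"""Submission-grade artifact generation and auxiliary input parsing.

Writers for the three documents an allele submission needs — an
ENA-dialect EMBL flat-file record, the ENA project/submission XML
payloads, and the IPD submission text with its difference ("coherence
check") block — plus readers for the two inputs IPD submission requires:
the genotype CSV and the ENA accession email attachment.

All writers are pure functions of their inputs: two calls with the same
arguments produce byte-identical output (the zip packer pins timestamps
for the same reason).  No live network I/O happens here; transport to ENA
sits behind :class:`DryRunTransport`.
"""

from __future__ import annotations

import enum
import io
import os
import re
import zipfile
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import pandas as pd

from .differences import AlleleClass, AnnotatedAllele, Difference, DiffType
from .reference_db import FeatureKind, GeneModel, _sequence_block

__all__ = [
    "EnaRecordMeta",
    "GenotypeTable",
    "GenotypeVerdict",
    "IpdSubmissionMeta",
    "XmlKind",
    "ProjectXmlMeta",
    "SubmissionXmlMeta",
    "DryRunTransport",
    "write_embl_flatfile",
    "concatenate_flatfiles",
    "write_ena_submission_xml",
    "read_genotype_csv",
    "validate_genotypes",
    "parse_accession_attachment",
    "write_ipd_submission",
    "parse_ipd_document",
    "reconstruct_query_from_ipd",
    "package_submission",
    "IPD_TEMPLATE_VERSION",
]

REQUIRED_IPD_LOCI = ("HLA-A", "HLA-B", "HLA-DRB1")
IPD_TEMPLATE_VERSION = "IPD-SUBMISSION-TEMPLATE v1"


class ValidationError(ValueError):
    """A writer input fails validation; message names the field."""


def _require(obj, *names: str) -> None:
    for name in names:
        if not getattr(obj, name):
            raise ValidationError(f"missing mandatory field: {name}")


# ---------------------------------------------------------------------------
# EMBL flatfile (ENA dialect)


@dataclass
class EnaRecordMeta:
    """Record-level metadata of one ENA flatfile entry."""

    study_accession: str
    sample_id: str
    description: str
    gene: str
    allele_local_name: str
    molecule_type: str = "genomic DNA"


def _ft(key: str, payload: str) -> str:
    return f"FT   {key:<16}{payload}"


def _ft_qualifier(text: str) -> list[str]:
    # qualifier payload wrapped at 59 chars, EMBL-style continuation lines
    return [_ft("", text[i : i + 59]) for i in range(0, len(text), 59)] or [_ft("", text)]


def write_embl_flatfile(allele: AnnotatedAllele, meta: EnaRecordMeta) -> str:
    """One pre-accession ENA flatfile record for an annotated allele.

    Accession fields in the ID line carry the ``XXX`` placeholder (ENA
    convention before accessioning).  Null alleles get a ``/pseudo`` CDS
    with no ``/translation``; coding alleles carry the protein.  The
    record re-parses (via the reference parser) to the identical gene
    model and sequence.
    """
    _require(meta, "study_accession", "sample_id", "description", "gene", "allele_local_name")
    n = len(allele.sequence)
    model = allele.gene_model
    lines = [
        f"ID   XXX; XXX; linear; {meta.molecule_type}; XXX; XXX; {n} BP.",
        "XX",
        "AC   XXX;",
        "XX",
        f"DE   {meta.description}",
        "XX",
        _ft("source", f"1..{n}"),
        _ft("", '/organism="Homo sapiens"'),
        _ft("", f'/mol_type="{meta.molecule_type}"'),
        _ft("", f'/cell_line="{meta.sample_id}"'),
    ]
    spans = model.cds_spans
    joined = ",".join(f"{s}..{e}" for s, e in spans)
    loc = f"join({joined})" if len(spans) > 1 else joined
    lines.append(_ft("CDS", loc))
    lines.append(_ft("", f'/gene="{meta.gene}"'))
    lines.append(_ft("", f'/allele="{meta.allele_local_name}"'))
    if allele.is_null:
        lines.append(_ft("", "/pseudo"))
    else:
        lines.append(_ft("", "/codon_start=1"))
        lines.extend(_ft_qualifier(f'/translation="{allele.coding.protein}"'))
    for f in model.features:
        if f.kind is FeatureKind.UTR5:
            lines.append(_ft("5'UTR", f"{f.start}..{f.end}"))
        elif f.kind is FeatureKind.UTR3:
            lines.append(_ft("3'UTR", f"{f.start}..{f.end}"))
        else:
            lines.append(_ft(f.kind.value.lower(), f"{f.start}..{f.end}"))
            lines.append(_ft("", f"/number={f.ordinal}"))
            lines.append(_ft("", f'/gene="{meta.gene}"'))
            lines.append(_ft("", f'/allele="{meta.allele_local_name}"'))
    lines.append("XX")
    lines.append(f"SQ   Sequence {n} BP;")
    lines.extend(_sequence_block(allele.sequence))
    lines.append("//")
    return "\n".join(lines) + "\n"


def concatenate_flatfiles(records: list[str]) -> str:
    """Join records in input order into one multi-record submission file."""
    for i, rec in enumerate(records):
        if not rec.rstrip().endswith("//"):
            raise ValidationError(f"record {i + 1} is not terminated by '//'")
    return "".join(records)


# ---------------------------------------------------------------------------
# ENA XML payloads


class XmlKind(enum.Enum):
    PROJECT = "PROJECT"
    SEQUENCE_SUBMISSION = "SEQUENCE_SUBMISSION"


@dataclass
class ProjectXmlMeta:
    alias: str
    title: str
    description: str


@dataclass
class SubmissionXmlMeta:
    alias: str
    flatfile_name: str


def write_ena_submission_xml(kind: XmlKind, meta) -> str:
    """Deterministic ENA XML payload (PROJECT set or SUBMISSION ADD action)."""
    if kind is XmlKind.PROJECT:
        _require(meta, "alias", "title", "description")
        root = ET.Element("PROJECT_SET")
        proj = ET.SubElement(root, "PROJECT", alias=meta.alias)
        ET.SubElement(proj, "TITLE").text = meta.title
        ET.SubElement(proj, "DESCRIPTION").text = meta.description
        sub = ET.SubElement(proj, "SUBMISSION_PROJECT")
        ET.SubElement(sub, "SEQUENCING_PROJECT")
    elif kind is XmlKind.SEQUENCE_SUBMISSION:
        _require(meta, "alias", "flatfile_name")
        root = ET.Element("SUBMISSION", alias=meta.alias)
        actions = ET.SubElement(root, "ACTIONS")
        action = ET.SubElement(actions, "ACTION")
        ET.SubElement(action, "ADD", source=meta.flatfile_name, schema="flatfile")
    else:
        raise ValidationError(f"unknown payload kind {kind!r}")
    ET.indent(root, space="  ")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    ) + "\n"


class DryRunTransport:
    """Stand-in for the ENA REST transport: records payloads, returns
    deterministic fake identifiers, performs no network I/O."""

    def __init__(self) -> None:
        self.sent: list[tuple[str, str]] = []

    def submit_project(self, project_xml: str, submission_xml: str) -> tuple[str, str]:
        self.sent.append(("project", project_xml))
        n = sum(1 for k, _ in self.sent if k == "project")
        return f"ERA{n:06d}", f"PRJEB{n:05d}"

    def submit_sequences(self, flatfile: str, submission_xml: str) -> str:
        self.sent.append(("sequences", flatfile))
        n = sum(1 for k, _ in self.sent if k == "sequences")
        return f"ERA{n + 500000:06d}"


# ---------------------------------------------------------------------------
# genotype CSV


@dataclass
class GenotypeTable:
    """Per-sample genotyping results: locus -> (allele1, allele2)."""

    rows: dict[str, dict[str, tuple[str | None, str | None]]]
    extra_columns: dict[str, dict[str, str]] = field(default_factory=dict)

    def loci(self) -> set[str]:
        return {locus for row in self.rows.values() for locus in row}


@dataclass
class GenotypeVerdict:
    passed: bool
    missing: list[str]


def read_genotype_csv(text: str) -> GenotypeTable:
    """Parse the genotype CSV (header ``sample_id,<locus>_1,<locus>_2,...``).

    Empty cells mean "typing absent"; unknown non-paired columns are
    preserved verbatim; duplicate sample ids are an error.
    """
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError("malformed header: missing 'sample_id' column")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate sample_id: {', '.join(sorted(set(dupes)))}")
    locus_cols: dict[str, list[str]] = {}
    extra_cols: list[str] = []
    for col in df.columns:
        if col == "sample_id":
            continue
        m = re.fullmatch(r"(.+)_([12])", col)
        if m:
            locus_cols.setdefault(m.group(1), []).append(col)
        else:
            extra_cols.append(col)
    rows: dict[str, dict[str, tuple[str | None, str | None]]] = {}
    extras: dict[str, dict[str, str]] = {}
    for _, rec in df.iterrows():
        sid = rec["sample_id"]
        row: dict[str, tuple[str | None, str | None]] = {}
        for locus in locus_cols:
            a1 = rec.get(f"{locus}_1", "") or None
            a2 = rec.get(f"{locus}_2", "") or None
            row[locus] = (a1, a2)
        rows[sid] = row
        if extra_cols:
            extras[sid] = {c: rec[c] for c in extra_cols}
    return GenotypeTable(rows=rows, extra_columns=extras)


def validate_genotypes(
    table: GenotypeTable, sample_id: str, submitted_locus: str
) -> GenotypeVerdict:
    """IPD's minimum genotype requirement for one sample.

    Passes iff the sample row has complete typings (both alleles) for
    HLA-A, HLA-B and HLA-DRB1, and a non-empty second allele at the
    submitted locus.  The verdict lists every missing item.
    """
    if sample_id not in table.rows:
        raise ValidationError(f"sample_id {sample_id!r} not present in genotype table")
    row = table.rows[sample_id]
    missing: list[str] = []
    for locus in REQUIRED_IPD_LOCI:
        a1, a2 = row.get(locus, (None, None))
        if not (a1 and a2):
            missing.append(locus)
    partner = row.get(submitted_locus, (None, None))[1]
    if not partner:
        missing.append(f"{submitted_locus} (second allele)")
    return GenotypeVerdict(passed=not missing, missing=missing)


# ---------------------------------------------------------------------------
# ENA accession attachment


def parse_accession_attachment(text: str) -> dict[str, str]:
    """Parse the accession email attachment into local-name -> accession.

    Line format ``<local_name><TAB><accession>``; surrounding whitespace
    and ``#`` comment lines are tolerated (mail clients reformat).
    """
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t") if "\t" in stripped else stripped.split()
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise ValidationError(
                f"line {lineno}: cannot split into local name and accession: {line!r}"
            )
        name, acc = parts
        if name in mapping:
            raise ValidationError(f"line {lineno}: duplicate local name {name!r}")
        mapping[name] = acc
    return mapping


# ---------------------------------------------------------------------------
# IPD submission document


@dataclass
class IpdSubmissionMeta:
    """Submitter and methodology metadata for the IPD document."""

    submitter_id: str
    cell_line_id: str
    sequencing_platform: str
    primer_set: str
    read_depth: str
    ena_accession: str


def _feature_name(kind: FeatureKind, ordinal: int | None) -> str:
    return {
        FeatureKind.UTR5: "5'UTR",
        FeatureKind.UTR3: "3'UTR",
        FeatureKind.EXON: f"exon {ordinal}",
        FeatureKind.INTRON: f"intron {ordinal}",
    }[kind]


def _difference_line(d: Difference, model: GeneModel) -> str:
    """Render ``<feature> <ordinal> position <cds-or-feature position>: <ref>><query>``.

    Exonic positions are CDS positions; elsewhere the position is local to
    the feature.  For indels the position names the anchoring base (the
    base preceding the inserted/deleted run).
    """
    name = _feature_name(d.feature_kind, d.feature_ordinal)
    if d.feature_kind is FeatureKind.EXON:
        pos = d.cds_pos
    else:
        feat = next(
            f for f in model.features
            if f.kind is d.feature_kind and f.ordinal == d.feature_ordinal
        )
        anchor = d.query_pos - 1 if d.dtype is DiffType.INS else d.query_pos
        pos = anchor - feat.start + 1
    left = d.ref_bases or "-"
    right = d.query_bases or "-"
    return f"{name} position {pos}: {left}>{right}"


def write_ipd_submission(
    allele: AnnotatedAllele,
    meta: IpdSubmissionMeta,
    genotypes: GenotypeTable,
    sample_id: str,
) -> str:
    """The IPD submission text: metadata blocks, the coherence-check
    difference list, the projected feature table and the full sequence.

    Block order is fixed and the first line carries the template version,
    so the layout can be replaced wholesale when IPD's authoritative
    format changes.
    """
    _require(
        meta,
        "submitter_id",
        "cell_line_id",
        "sequencing_platform",
        "primer_set",
        "read_depth",
        "ena_accession",
    )
    if sample_id not in genotypes.rows:
        raise ValidationError(f"sample_id {sample_id!r} not present in genotype table")
    row = genotypes.rows[sample_id]
    lines = [
        IPD_TEMPLATE_VERSION,
        "[submitter]",
        f"submitter id: {meta.submitter_id}",
        "[sample]",
        f"sample id: {sample_id}",
        f"cell line: {meta.cell_line_id}",
        "[ena]",
        f"accession: {meta.ena_accession}",
        "[methodology]",
        f"platform: {meta.sequencing_platform}",
        f"primers: {meta.primer_set}",
        f"read depth: {meta.read_depth}",
        "[genotype context]",
    ]
    for locus in sorted(row):
        a1, a2 = row[locus]
        if a1 or a2:
            lines.append(f"{locus}: {a1 or '-'}, {a2 or '-'}")
    lines += [
        "[closest reference]",
        f"name: {allele.closest_reference_name}",
        f"identity: {allele.identity:.6f}",
        f"class: {allele.allele_class.value}",
        f"null allele: {'yes' if allele.is_null else 'no'}",
        "[differences]",
    ]
    if allele.allele_class is AlleleClass.CONFIRMATORY and not allele.differences:
        lines.append("count: 0 (confirmatory sequence, identical to reference)")
    else:
        lines.append(f"count: {len(allele.differences)}")
        for d in allele.differences:
            lines.append(_difference_line(d, allele.gene_model))
    lines.append("[features]")
    for f in allele.gene_model.features:
        lines.append(f"{_feature_name(f.kind, f.ordinal)} {f.start}..{f.end}")
    lines.append("[sequence]")
    for i in range(0, len(allele.sequence), 60):
        lines.append(allele.sequence[i : i + 60])
    return "\n".join(lines) + "\n"


_DIFF_LINE_RE = re.compile(
    r"^(?P<feat>5'UTR|3'UTR|exon \d+|intron \d+) position (?P<pos>-?\d+): "
    r"(?P<left>[ACGT]+|-)>(?P<right>[ACGT]+|-)$"
)


def parse_ipd_document(text: str) -> dict:
    """Parse back the blocks of a generated IPD document (coherence check)."""
    lines = text.splitlines()
    if not lines or lines[0] != IPD_TEMPLATE_VERSION:
        raise ValidationError("not an IPD submission document (missing template header)")
    blocks: dict[str, list[str]] = {}
    current = None
    for line in lines[1:]:
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line)

    features = []
    for line in blocks.get("features", []):
        m = re.fullmatch(r"(5'UTR|3'UTR|exon \d+|intron \d+) (\d+)\.\.(\d+)", line)
        if m:
            features.append((m.group(1), int(m.group(2)), int(m.group(3))))
    diffs = []
    for line in blocks.get("differences", []):
        if line.startswith("count:"):
            continue
        m = _DIFF_LINE_RE.fullmatch(line)
        if not m:
            raise ValidationError(f"unparseable difference line: {line!r}")
        diffs.append(
            {
                "feature": m.group("feat"),
                "pos": int(m.group("pos")),
                "ref": "" if m.group("left") == "-" else m.group("left"),
                "query": "" if m.group("right") == "-" else m.group("right"),
            }
        )
    sequence = "".join(blocks.get("sequence", []))
    return {"features": features, "differences": diffs, "sequence": sequence}


def reconstruct_query_from_ipd(document: str, ref_sequence: str) -> str:
    """Re-apply the document's difference block to the named reference.

    This is the IPD coherence check made executable: the result must equal
    the document's own sequence block.
    """
    doc = parse_ipd_document(document)
    features = doc["features"]
    exon_spans = [
        (s, e) for name, s, e in features if name.startswith("exon")
    ]

    def cds_to_query(cds_pos: int) -> int:
        off = 0
        for s, e in exon_spans:
            span = e - s + 1
            if cds_pos <= off + span:
                return s + (cds_pos - off - 1)
            off += span
        raise ValidationError(f"cds position {cds_pos} beyond exon spans")

    events = []  # (query_pos, kind, ref_bases, query_bases)
    for d in doc["differences"]:
        feat_start = next(s for name, s, e in features if name == d["feature"])
        if d["feature"].startswith("exon"):
            qpos = cds_to_query(d["pos"])
        else:
            qpos = feat_start + d["pos"] - 1
        if d["ref"] and d["query"]:
            events.append((qpos, "SUB", d["ref"], d["query"]))
        elif d["query"]:
            events.append((qpos, "INS", "", d["query"]))  # qpos = anchor base
        else:
            events.append((qpos, "DEL", d["ref"], ""))  # qpos = anchor base
    events.sort()

    out = []
    cursor = 1  # next ref position to copy
    offset = 0  # query length so far minus ref consumed
    for qpos, kind, ref_bases, query_bases in events:
        if kind == "SUB":
            rp = qpos - offset
            out.append(ref_sequence[cursor - 1 : rp - 1])
            out.append(query_bases)
            cursor = rp + 1
        elif kind == "INS":
            rp = qpos - offset  # anchor on reference
            out.append(ref_sequence[cursor - 1 : rp])
            out.append(query_bases)
            cursor = rp + 1
            offset += len(query_bases)
        else:
            rp = qpos - offset + 1  # first deleted ref base
            out.append(ref_sequence[cursor - 1 : rp - 1])
            cursor = rp + len(ref_bases)
            offset -= len(ref_bases)
    out.append(ref_sequence[cursor - 1 :])
    return "".join(out)


# ---------------------------------------------------------------------------
# packaging


def package_submission(files: list[str | os.PathLike]) -> bytes:
    """Zip exactly the listed files (deterministic: pinned timestamps)."""
    if not files:
        raise ValidationError("no files to package")
    for f in files:
        if not os.path.isfile(f):
            raise ValidationError(f"missing file: {f}")
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in files:
            with open(f, "rb") as fh:
                data = fh.read()
            info = zipfile.ZipInfo(os.path.basename(f), date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)
    return buf.getvalue()
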