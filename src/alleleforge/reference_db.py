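"""IPD-style EMBL flat-file reference databases.

The IPD distributions (``hla.dat``, ``KIR.dat``) ship every catalogued
allele as an EMBL flat-file record whose feature table carries the gene
model: 5'UTR, exons, introns, 3'UTR.  This module parses that dialect into
an in-memory :class:`ReferenceDatabase`, selects the full-length alleles
usable as annotation references, and writes the dialect back out
bit-exactly (which is what makes the parser round-trip testable).

Only the ``ID``, ``DE``, ``FT`` and ``SQ`` line types are consumed; the
coordinate convention is 1-based inclusive throughout, exactly as printed
in the flat file.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "FeatureKind",
    "Feature",
    "GeneModel",
    "ReferenceAllele",
    "ReferenceDatabase",
    "FlatFileParseError",
    "parse_reference_flatfile",
    "select_full_length",
    "write_reference_flatfile",
    "write_record",
]


class FeatureKind(enum.Enum):
    """The four gene-model feature kinds of a genomic allele sequence."""

    UTR5 = "UTR5"
    EXON = "EXON"
    INTRON = "INTRON"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class Feature:
    """One gene-model feature in allele-local 1-based inclusive coordinates.

    ``ordinal`` is present exactly for exons and introns (``/number=``
    qualifier in the flat file); UTRs carry none.
    """

    kind: FeatureKind
    start: int
    end: int
    ordinal: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid feature span {self.start}..{self.end}")
        has_ordinal = self.ordinal is not None
        needs_ordinal = self.kind in (FeatureKind.EXON, FeatureKind.INTRON)
        if has_ordinal != needs_ordinal:
            raise ValueError(
                f"ordinal must be present iff kind is EXON/INTRON; "
                f"got kind={self.kind.value} ordinal={self.ordinal}"
            )
        if has_ordinal and self.ordinal < 1:
            raise ValueError("ordinal must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def label(self) -> str:
        """Human-readable label, e.g. ``5'UTR``, ``exon 2``."""
        if self.kind is FeatureKind.UTR5:
            return "5'UTR"
        if self.kind is FeatureKind.UTR3:
            return "3'UTR"
        return f"{self.kind.value.lower()} {self.ordinal}"


@dataclass
class GeneModel:
    """Ordered partition of an allele sequence into UTRs, exons and introns.

    ``cds_spans`` are the exon spans in order; their concatenation is the
    coding sequence.
    """

    features: list[Feature]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.start)

    @property
    def cds_spans(self) -> list[tuple[int, int]]:
        return [(f.start, f.end) for f in self.exons]

    @property
    def exons(self) -> list[Feature]:
        return [f for f in self.features if f.kind is FeatureKind.EXON]

    @property
    def introns(self) -> list[Feature]:
        return [f for f in self.features if f.kind is FeatureKind.INTRON]

    def has_kind(self, kind: FeatureKind) -> bool:
        return any(f.kind is kind for f in self.features)

    @property
    def span(self) -> tuple[int, int]:
        return self.features[0].start, self.features[-1].end

    def feature_at(self, pos: int) -> Feature:
        """Feature containing position ``pos`` (1-based)."""
        for f in self.features:
            if f.start <= pos <= f.end:
                return f
        raise ValueError(f"position {pos} outside gene model span {self.span}")

    def validate(self, seq_length: int | None = None, full_length: bool = False) -> None:
        """Check tiling, alternation and ordinal invariants; raise ValueError."""
        if not self.features:
            raise ValueError("gene model has no features")
        for prev, nxt in zip(self.features, self.features[1:]):
            if nxt.start != prev.end + 1:
                raise ValueError(
                    f"features do not tile: {prev.label()} ends at {prev.end}, "
                    f"{nxt.label()} starts at {nxt.start}"
                )
        if seq_length is not None and self.features[-1].end > seq_length:
            raise ValueError(
                f"feature {self.features[-1].label()} ends at "
                f"{self.features[-1].end} beyond sequence length {seq_length}"
            )
        exon_ords = [f.ordinal for f in self.exons]
        intron_ords = [f.ordinal for f in self.introns]
        if exon_ords != list(range(1, len(exon_ords) + 1)):
            raise ValueError(f"exon ordinals not consecutive from 1: {exon_ords}")
        if intron_ords != list(range(1, len(intron_ords) + 1)):
            raise ValueError(f"intron ordinals not consecutive from 1: {intron_ords}")
        if full_length:
            if self.features[0].kind is not FeatureKind.UTR5:
                raise ValueError("full-length model must start with 5'UTR")
            if self.features[-1].kind is not FeatureKind.UTR3:
                raise ValueError("full-length model must end with 3'UTR")
            inner = self.features[1:-1]
            if not inner or inner[0].kind is not FeatureKind.EXON or inner[-1].kind is not FeatureKind.EXON:
                raise ValueError("exons and introns must alternate, starting/ending with an exon")
            for i, f in enumerate(inner):
                want = FeatureKind.EXON if i % 2 == 0 else FeatureKind.INTRON
                if f.kind is not want:
                    raise ValueError(f"feature {i + 2} should be {want.value}, got {f.kind.value}")
            if seq_length is not None:
                if self.features[0].start != 1 or self.features[-1].end != seq_length:
                    raise ValueError("full-length model must tile [1, sequence length]")


@dataclass
class ReferenceAllele:
    """A catalogued allele: sequence plus gene model.

    ``record_id`` is the flat-file accession (ID line); ``allele_name`` the
    DE-line allele designation, e.g. ``HLA-A*01:01:01:01``.
    """

    allele_name: str
    sequence: str
    gene_model: GeneModel
    record_id: str = ""
    sequence_version: int = 1

    @property
    def locus(self) -> str:
        return self.allele_name.split("*")[0]

    @property
    def source_db(self) -> str:
        return "KIR" if self.locus.upper().startswith("KIR") else "HLA"

    @property
    def is_full_length(self) -> bool:
        return self.gene_model.has_kind(FeatureKind.UTR5) and self.gene_model.has_kind(
            FeatureKind.UTR3
        )

    def validate(self) -> None:
        if not re.fullmatch(r"[ACGT]+", self.sequence):
            raise ValueError(f"{self.allele_name}: sequence has letters outside A/C/G/T")
        self.gene_model.validate(len(self.sequence), full_length=self.is_full_length)


@dataclass
class ReferenceDatabase:
    """Collection of reference alleles indexed by name and grouped by locus."""

    version: str = ""
    release_date: str = ""
    alleles: dict[str, ReferenceAllele] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, allele: ReferenceAllele) -> None:
        if allele.allele_name in self.alleles:
            raise ValueError(f"duplicate allele name {allele.allele_name}")
        self.alleles[allele.allele_name] = allele

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles.values())

    def __getitem__(self, name: str) -> ReferenceAllele:
        return self.alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def by_locus(self) -> dict[str, list[ReferenceAllele]]:
        grouped: dict[str, list[ReferenceAllele]] = {}
        for a in self:
            grouped.setdefault(a.locus, []).append(a)
        return grouped


class FlatFileParseError(ValueError):
    """Malformed flat-file record; message names the record and line."""


# ---------------------------------------------------------------------------
# parsing

_FT_KEY_MAP = {
    "UTR": "UTR",
    "5'UTR": "UTR5",
    "3'UTR": "UTR3",
    "exon": "EXON",
    "intron": "INTRON",
    "CDS": "CDS",
}

_LOC_RE = re.compile(r"^(?:<?(\d+)\.\.>?(\d+)|(\d+))$")


def _parse_location(loc: str) -> tuple[int, int]:
    m = _LOC_RE.match(loc.strip())
    if not m:
        raise ValueError(f"unsupported location {loc!r}")
    if m.group(3):
        p = int(m.group(3))
        return p, p
    return int(m.group(1)), int(m.group(2))


def _parse_join(loc: str) -> list[tuple[int, int]]:
    loc = loc.strip()
    if loc.startswith("join(") and loc.endswith(")"):
        parts = loc[5:-1].split(",")
    else:
        parts = [loc]
    return [_parse_location(p) for p in parts]


def parse_reference_flatfile(text: str) -> ReferenceDatabase:
    """Parse an IPD-dialect EMBL flat file into a :class:`ReferenceDatabase`.

    Records are terminated by ``//`` lines.  A record whose sequence contains
    letters outside A/C/G/T is skipped with a warning; structurally malformed
    records raise :class:`FlatFileParseError` naming the record and line.
    Records lacking either UTR are retained with ``is_full_length=False``.
    """
    db = ReferenceDatabase()
    lines = text.splitlines()
    i = 0
    # optional file-level header: CC lines before the first record
    while i < len(lines) and lines[i].startswith("CC"):
        payload = lines[i][2:].strip()
        if payload.startswith("version="):
            db.version = payload[len("version="):]
        elif payload.startswith("released="):
            db.release_date = payload[len("released="):]
        i += 1

    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        start_line = i
        record_lines: list[str] = []
        terminated = False
        while i < len(lines):
            if lines[i].rstrip() == "//":
                terminated = True
                i += 1
                break
            record_lines.append(lines[i])
            i += 1
        if not any(l.strip() for l in record_lines):
            continue
        if not terminated:
            raise FlatFileParseError(
                f"record starting at line {start_line + 1} is not terminated by '//'"
            )
        _parse_record(record_lines, start_line + 1, db)
    return db


def _parse_record(lines: list[str], first_lineno: int, db: ReferenceDatabase) -> None:
    record_id = ""
    sequence_version = 1
    declared_length: int | None = None
    allele_name = ""
    raw_features: list[tuple[str, str, int]] = []  # (key, location, lineno)
    qualifiers: list[dict[str, str]] = []
    cds_spans: list[tuple[int, int]] | None = None
    seq_parts: list[str] = []
    in_sq = False
    current_feature: int | None = None  # index into raw_features

    for off, line in enumerate(lines):
        lineno = first_lineno + off
        tag = line[:2]
        if in_sq:
            seq_parts.append(re.sub(r"[\d\s]", "", line))
            continue
        if tag == "ID":
            m = re.match(r"ID\s+([^;]+);(?:\s*SV\s+(\d+);)?.*?(\d+)\s+BP\.?\s*$", line)
            if not m:
                raise FlatFileParseError(f"line {lineno}: unparseable ID line {line!r}")
            record_id = m.group(1).strip()
            if m.group(2):
                sequence_version = int(m.group(2))
            declared_length = int(m.group(3))
        elif tag == "DE":
            if not allele_name:
                allele_name = line[2:].strip()
        elif tag == "FT":
            key = line[5:21].strip()
            rest = line[21:].strip()
            if key:
                if key in _FT_KEY_MAP and key != "CDS":
                    try:
                        raw_features.append((key, rest, lineno))
                        qualifiers.append({})
                        current_feature = len(raw_features) - 1
                    except ValueError as e:
                        raise FlatFileParseError(f"line {lineno}: {e}") from e
                elif key == "CDS":
                    try:
                        cds_spans = _parse_join(rest)
                    except ValueError as e:
                        raise FlatFileParseError(f"line {lineno}: {e}") from e
                    current_feature = None
                else:
                    current_feature = None  # e.g. source; qualifiers skipped
            elif current_feature is not None and rest.startswith("/"):
                if "=" in rest:
                    k, v = rest[1:].split("=", 1)
                    qualifiers[current_feature][k] = v.strip('"')
        elif tag == "SQ":
            in_sq = True
        # other line types (AC, XX, CC, ...) are ignored

    rec_name = allele_name or record_id or f"record at line {first_lineno}"
    if not record_id:
        raise FlatFileParseError(f"{rec_name}: missing ID line")
    if not in_sq:
        raise FlatFileParseError(f"{rec_name}: missing SQ block")
    sequence = "".join(seq_parts).upper()
    if not sequence:
        raise FlatFileParseError(f"{rec_name}: empty sequence")
    if declared_length is not None and len(sequence) != declared_length:
        raise FlatFileParseError(
            f"{rec_name}: ID line declares {declared_length} BP but "
            f"sequence block has {len(sequence)}"
        )
    if not re.fullmatch(r"[ACGT]+", sequence):
        bad = sorted(set(sequence) - set("ACGT"))
        db.warnings.append(
            f"{rec_name}: skipped (sequence letters outside A/C/G/T: {','.join(bad)})"
        )
        return

    # materialise features; bare UTR keys disambiguated by position
    parsed: list[tuple[str, int, int, dict[str, str], int]] = []
    for (key, loc, lineno), quals in zip(raw_features, qualifiers):
        try:
            s, e = _parse_location(loc)
        except ValueError as exc:
            raise FlatFileParseError(f"{rec_name}: line {lineno}: {exc}") from exc
        if e > len(sequence):
            raise FlatFileParseError(
                f"{rec_name}: line {lineno}: feature span {s}..{e} exceeds "
                f"sequence length {len(sequence)}"
            )
        parsed.append((key, s, e, quals, lineno))

    first_exon_start = min(
        (s for key, s, _e, _q, _l in parsed if _FT_KEY_MAP[key] == "EXON"),
        default=None,
    )
    features: list[Feature] = []
    for key, s, e, quals, lineno in parsed:
        kind_name = _FT_KEY_MAP[key]
        if kind_name == "UTR":
            if first_exon_start is None:
                kind_name = "UTR5" if s == 1 else "UTR3"
            else:
                kind_name = "UTR5" if s < first_exon_start else "UTR3"
        kind = FeatureKind[kind_name]
        ordinal = None
        if kind in (FeatureKind.EXON, FeatureKind.INTRON):
            try:
                ordinal = int(quals.get("number", "0")) or None
            except ValueError:
                ordinal = None
            if ordinal is None:
                raise FlatFileParseError(
                    f"{rec_name}: line {lineno}: {kind.value.lower()} feature "
                    f"lacks a /number qualifier"
                )
        try:
            features.append(Feature(kind=kind, start=s, end=e, ordinal=ordinal))
        except ValueError as exc:
            raise FlatFileParseError(f"{rec_name}: line {lineno}: {exc}") from exc

    model = GeneModel(features=features)
    allele = ReferenceAllele(
        allele_name=allele_name or record_id,
        sequence=sequence,
        gene_model=model,
        record_id=record_id,
        sequence_version=sequence_version,
    )
    try:
        model.validate(len(sequence), full_length=allele.is_full_length)
    except ValueError as exc:
        raise FlatFileParseError(f"{rec_name}: {exc}") from exc
    if cds_spans is not None and features and cds_spans != model.cds_spans:
        db.warnings.append(
            f"{rec_name}: CDS join() disagrees with exon features; exon features win"
        )
    db.add(allele)


# ---------------------------------------------------------------------------
# writing


def select_full_length(db: ReferenceDatabase) -> ReferenceDatabase:
    """Sub-database of alleles usable as projection references (both UTRs)."""
    out = ReferenceDatabase(version=db.version, release_date=db.release_date)
    for a in db:
        if a.is_full_length:
            out.add(a)
    return out


def _format_ft_line(key: str, payload: str) -> str:
    return f"FT   {key:<16}{payload}"


def _sequence_block(sequence: str) -> list[str]:
    lines = []
    seq = sequence.lower()
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        pos = min(i + 60, len(seq))
        lines.append(f"     {groups:<65}{pos:>10}")
    return lines


def write_record(allele: ReferenceAllele) -> str:
    """One flat-file record, bit-exact per the dialect (terminated by ``//``)."""
    allele.validate()
    n = len(allele.sequence)
    rid = allele.record_id or allele.allele_name
    lines = [
        f"ID   {rid}; SV {allele.sequence_version}; standard; DNA; HUM; {n} BP.",
        f"DE   {allele.allele_name}",
    ]
    for f in allele.gene_model.features:
        if f.kind in (FeatureKind.UTR5, FeatureKind.UTR3):
            lines.append(_format_ft_line("UTR", f"{f.start}..{f.end}"))
        else:
            lines.append(_format_ft_line(f.kind.value.lower(), f"{f.start}..{f.end}"))
            lines.append(_format_ft_line("", f"/number={f.ordinal}"))
    spans = allele.gene_model.cds_spans
    if spans:
        joined = ",".join(f"{s}..{e}" for s, e in spans)
        loc = f"join({joined})" if len(spans) > 1 else joined
        lines.append(_format_ft_line("CDS", loc))
    lines.append(f"SQ   Sequence {n} BP;")
    lines.extend(_sequence_block(allele.sequence))
    lines.append("//")
    return "\n".join(lines) + "\n"


def write_reference_flatfile(db: ReferenceDatabase) -> str:
    """Write a whole database; ``parse(write(db))`` reproduces ``db`` exactly."""
    parts = []
    if db.version:
        parts.append(f"CC   version={db.version}\n")
    if db.release_date:
        parts.append(f"CC   released={db.release_date}\n")
    for allele in db:
        parts.append(write_record(allele))
    return "".join(parts)
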