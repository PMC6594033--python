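"""Difference elucidation, coding report and allele classification.

IPD requires each submission to enumerate its differences from a closely
related catalogued allele as a coherence check.  This module walks the
query/reference alignment, reports one record per substituted column and
per maximal gap run (with feature and codon context), translates the
query coding sequence, flags null alleles (frameshift or premature stop
codon), and classifies the submission as novel, confirmatory or an
extension of a partially known allele.

Indels are left-normalised (shifted to their 5'-most equivalent placement)
so the emitted difference list is a deterministic function of the two
sequences rather than of aligner tie-breaking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from Bio.Seq import Seq

from .annotation import (
    AlignmentMap,
    AnnotationConfig,
    ClosestHit,
    NoReferenceError,
    NoSuitableReferenceError,
    check_full_length,
    find_closest_reference,
    project_features,
)
from .reference_db import FeatureKind, GeneModel, ReferenceDatabase

__all__ = [
    "DiffType",
    "Consequence",
    "AlleleClass",
    "Difference",
    "CodingReport",
    "AnnotatedAllele",
    "AnnotationRejected",
    "enumerate_differences",
    "extract_cds",
    "translate_cds",
    "classify_allele",
    "annotate_allele",
]


class DiffType(enum.Enum):
    SUB = "SUB"
    INS = "INS"
    DEL = "DEL"


class Consequence(enum.Enum):
    NONCODING = "NONCODING"
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    INFRAME_INDEL = "INFRAME_INDEL"


class AlleleClass(enum.Enum):
    NOVEL = "NOVEL"
    CONFIRMATORY = "CONFIRMATORY"
    EXTENSION = "EXTENSION"


@dataclass
class Difference:
    """One sequence change with feature and codon context.

    Conventions (1-based):

    * SUB — ``query_pos``/``ref_pos`` are the substituted base.
    * INS — ``query_pos`` is the first inserted base; ``ref_pos`` the
      reference base preceding the insertion; ``ref_bases`` is empty.
    * DEL — ``ref_pos`` is the first deleted reference base; ``query_pos``
      the query base preceding the deletion; ``query_bases`` is empty.

    ``cds_pos`` (position within the query coding sequence) and
    ``codon_index`` are present exactly for exonic differences; for INS
    and DEL they refer to the anchoring base.
    """

    dtype: DiffType
    query_pos: int
    ref_pos: int
    ref_bases: str
    query_bases: str
    feature_kind: FeatureKind
    feature_ordinal: int | None
    consequence: Consequence
    cds_pos: int | None = None
    codon_index: int | None = None

    @property
    def feature_context(self) -> tuple[FeatureKind, int | None]:
        return (self.feature_kind, self.feature_ordinal)

    @property
    def length(self) -> int:
        return max(len(self.ref_bases), len(self.query_bases))


@dataclass
class CodingReport:
    """Translation outcome of the query coding sequence.

    ``is_null`` marks alleles whose CDS cannot encode a functional
    product: a frameshift (CDS length not divisible by 3) or a premature
    stop codon (a stop before the final complete codon).
    """

    cds: str
    protein: str
    has_premature_stop: bool
    has_frameshift: bool
    stop_codon_index: int | None

    @property
    def is_null(self) -> bool:
        return self.has_premature_stop or self.has_frameshift


@dataclass
class AnnotatedAllele:
    """A novel sequence with projected gene model, diffs and coding report.

    ``sequence`` is stored in the annotated (forward) orientation
    regardless of the input strand.
    """

    label: str
    sequence: str
    locus: str
    gene_model: GeneModel
    closest: ClosestHit
    differences: list[Difference]
    coding: CodingReport
    allele_class: AlleleClass

    @property
    def closest_reference_name(self) -> str:
        return self.closest.reference.allele_name

    @property
    def identity(self) -> float:
        return self.closest.identity

    @property
    def is_null(self) -> bool:
        return self.coding.is_null


class AnnotationRejected(ValueError):
    """Structured rejection with a machine-readable reason code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


# ---------------------------------------------------------------------------
# CDS handling

_STOPS = {"TAA", "TAG", "TGA"}


def extract_cds(sequence: str, model: GeneModel) -> str:
    """Concatenation of the exon spans, in order."""
    spans = model.cds_spans
    if not spans:
        raise ValueError("gene model has no exons")
    return "".join(sequence[s - 1 : e] for s, e in spans)


def translate_cds(cds: str) -> CodingReport:
    """Translate from position 1 under the standard nuclear code.

    A stop codon at any index before the final complete codon is
    premature; a CDS length not divisible by 3 is a frameshift.  The
    protein runs up to (and excluding) the first stop.
    """
    if not cds:
        raise ValueError("empty CDS")
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: 3 * n_codons]).translate())
    stop_idx = aa.find("*")
    stop_codon_index = stop_idx + 1 if stop_idx >= 0 else None
    protein = aa if stop_idx < 0 else aa[:stop_idx]
    return CodingReport(
        cds=cds,
        protein=protein,
        has_premature_stop=stop_codon_index is not None and stop_codon_index < n_codons,
        has_frameshift=len(cds) % 3 != 0,
        stop_codon_index=stop_codon_index,
    )


# ---------------------------------------------------------------------------
# difference enumeration


def _left_normalize_ins(
    ref_seq: str, query_seq: str, anchor: int, bases: str, query_pos: int
):
    """Shift an insertion to its 5'-most equivalent placement.

    A shift step absorbs the preceding aligned column, so it is taken only
    when that column is a match (otherwise the insertion would collide
    with a substitution record there).
    """
    while (
        anchor >= 1
        and bases[-1] == ref_seq[anchor - 1]
        and query_pos >= 2
        and query_seq[query_pos - 2] == ref_seq[anchor - 1]
    ):
        bases = bases[-1] + bases[:-1]
        anchor -= 1
        query_pos -= 1
    return anchor, bases, query_pos


def _left_normalize_del(
    ref_seq: str, query_seq: str, start: int, bases: str, query_anchor: int
):
    """Shift a deletion to its 5'-most equivalent placement.

    Same match-column guard as for insertions.
    """
    end = start + len(bases) - 1
    while (
        start >= 2
        and ref_seq[start - 2] == ref_seq[end - 1]
        and query_anchor >= 1
        and query_seq[query_anchor - 1] == ref_seq[start - 2]
    ):
        start -= 1
        end -= 1
        query_anchor -= 1
        bases = ref_seq[start - 1 : end]
    return start, bases, query_anchor


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _canonicalize_ops(
    ops: list[tuple], ref_seq: str, query_seq: str
) -> list[tuple]:
    """Recombine split indel fragments and left-normalise every indel.

    An optimal unit-cost alignment may represent one multi-base indel as
    several gap runs separated by match columns (equivalent placements).
    For each cluster of same-type fragments with nothing but matches
    between them, the spanned region is tested for a single-run
    representation (possible iff the common prefix and suffix of the two
    segment versions cover the shorter one); if it exists its 5'-most
    placement is taken, otherwise the fragments are kept and
    left-normalised individually.
    """
    cur = sorted(ops, key=lambda t: (t[2], t[1]))
    while True:
        def blocked(lo: int, hi: int, dtype) -> bool:
            # a substitution or opposite-type indel strictly inside
            # (lo, hi) breaks the all-match corridor between fragments
            return any(lo < op[2] < hi for op in cur if op[0] is not dtype)

        merged_ops: list[tuple] = []
        for op in cur:
            if (
                merged_ops
                and op[0] is not DiffType.SUB
                and merged_ops[-1][0] is op[0]
                and not blocked(merged_ops[-1][2], op[2], op[0])
            ):
                merged = _combine_cluster([merged_ops[-1], op], ref_seq, query_seq)
                if merged is not None:
                    merged_ops[-1] = merged
                    continue
            merged_ops.append(op)

        normed: list[tuple] = []
        for dtype, q_pos, r_pos, ref_bases, query_bases in merged_ops:
            if dtype is DiffType.DEL:
                r_pos, ref_bases, q_pos = _left_normalize_del(
                    ref_seq, query_seq, r_pos, ref_bases, q_pos
                )
            elif dtype is DiffType.INS:
                r_pos, query_bases, q_pos = _left_normalize_ins(
                    ref_seq, query_seq, r_pos, query_bases, q_pos
                )
            normed.append((dtype, q_pos, r_pos, ref_bases, query_bases))
        normed.sort(key=lambda t: (t[2], t[1]))
        if normed == cur:
            return cur
        cur = normed


def _combine_cluster(cluster: list[tuple], ref_seq: str, query_seq: str):
    """Single-run representation of a fragment cluster, or None."""
    dtype = cluster[0][0]
    if dtype is DiffType.INS:
        a1, q1 = cluster[0][2], cluster[0][1]
        ak = cluster[-1][2]
        total = sum(len(c[4]) for c in cluster)
        region_r = ref_seq[a1:ak]  # matched bases between/after fragments
        q_end = cluster[-1][1] + len(cluster[-1][4]) - 1
        region_q = query_seq[q1 - 1 : q_end]
        if len(region_q) != len(region_r) + total:
            return None
        p, s = _lcp(region_r, region_q), _lcs(region_r, region_q)
        if p + s < len(region_r):
            return None
        i0 = max(0, len(region_r) - s)
        bases = region_q[i0 : i0 + total]
        return (DiffType.INS, q1 + i0, a1 + i0, "", bases)
    if dtype is DiffType.DEL:
        s1, qa1 = cluster[0][2], cluster[0][1]
        ek = cluster[-1][2] + len(cluster[-1][3]) - 1
        total = sum(len(c[3]) for c in cluster)
        region_r = ref_seq[s1 - 1 : ek]
        qak = cluster[-1][1]
        region_q = query_seq[qa1:qak]  # surviving query bases between fragments
        if len(region_r) != len(region_q) + total:
            return None
        p, s = _lcp(region_r, region_q), _lcs(region_r, region_q)
        if p + s < len(region_q):
            return None
        i0 = max(0, len(region_q) - s)
        bases = region_r[i0 : i0 + total]
        return (DiffType.DEL, qa1 + i0, s1 + i0, bases, "")
    return None


def _cds_position(model: GeneModel, pos: int) -> int | None:
    """Position of ``pos`` within the coding sequence, if exonic."""
    offset = 0
    for s, e in model.cds_spans:
        if s <= pos <= e:
            return offset + (pos - s + 1)
        offset += e - s + 1
    return None


def enumerate_differences(
    alignment: AlignmentMap,
    ref_model: GeneModel,
    query_model: GeneModel,
) -> list[Difference]:
    """All differences between query and reference, sorted by query position.

    One record per substituted column and per maximal gap run.  Feature
    context comes from the query gene model; codon context is computed on
    the query coding sequence, so it stays well defined even downstream of
    indels.
    """
    qs, rs = alignment.query_seq, alignment.ref_seq
    raw: list[tuple[DiffType, int, int, str, str]] = []  # dtype, query_pos, ref_pos, ref_bases, query_bases

    for blk in alignment.blocks:
        for i in range(blk.query_end - blk.query_start + 1):
            qb = qs[blk.query_start - 1 + i]
            rb = rs[blk.ref_start - 1 + i]
            if qb != rb:
                raw.append((DiffType.SUB, blk.query_start + i, blk.ref_start + i, rb, qb))

    # gap runs: reconstruct both coordinates from block adjacency
    prev_q = prev_r = 0
    boundaries = []
    for blk in alignment.blocks:
        boundaries.append((prev_q, prev_r, blk.query_start, blk.ref_start))
        prev_q, prev_r = blk.query_end, blk.ref_end
    boundaries.append((prev_q, prev_r, len(qs) + 1, len(rs) + 1))
    for pq, pr, nq, nr in boundaries:
        ins_len = nq - pq - 1
        del_len = nr - pr - 1
        # between two blocks edlib emits either an insertion or a deletion
        # run (adjacent I/D would merge into mismatches), but handle both
        # defensively in sequence: deletion first, then insertion.
        if del_len > 0:
            raw.append((DiffType.DEL, pq, pr + 1, rs[pr : pr + del_len], ""))
        if ins_len > 0:
            raw.append((DiffType.INS, pq + 1, pr, "", qs[pq : pq + ins_len]))
    raw = _canonicalize_ops(raw, rs, qs)

    diffs: list[Difference] = []
    for dtype, q_pos, r_pos, ref_bases, query_bases in raw:
        context_pos = q_pos if q_pos >= 1 else 1
        feat = query_model.feature_at(context_pos)
        cds_pos = codon_index = None
        consequence = Consequence.NONCODING
        if feat.kind is FeatureKind.EXON:
            anchor_pos = q_pos - 1 if dtype is DiffType.INS else q_pos
            cds_pos = _cds_position(query_model, max(anchor_pos, 1))
            if cds_pos is not None:
                codon_index = (cds_pos - 1) // 3 + 1
            if dtype is DiffType.SUB:
                consequence = _sub_consequence(qs, query_model, cds_pos, ref_bases)
            else:
                indel_len = len(ref_bases) or len(query_bases)
                consequence = (
                    Consequence.INFRAME_INDEL
                    if indel_len % 3 == 0
                    else Consequence.FRAMESHIFT
                )
        diffs.append(
            Difference(
                dtype=dtype,
                query_pos=q_pos,
                ref_pos=r_pos,
                ref_bases=ref_bases,
                query_bases=query_bases,
                feature_kind=feat.kind,
                feature_ordinal=feat.ordinal,
                consequence=consequence,
                cds_pos=cds_pos,
                codon_index=codon_index,
            )
        )
    diffs.sort(key=lambda d: (d.query_pos, d.dtype.value))
    return diffs


def _sub_consequence(
    query_seq: str, query_model: GeneModel, cds_pos: int | None, ref_base: str
) -> Consequence:
    """Consequence of an exonic substitution, judged on the query codon."""
    if cds_pos is None:
        return Consequence.NONCODING
    cds = extract_cds(query_seq, query_model)
    codon_start = (cds_pos - 1) // 3 * 3
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        return Consequence.MISSENSE  # incomplete terminal codon (frameshifted CDS)
    within = (cds_pos - 1) % 3
    ref_codon = codon[:within] + ref_base + codon[within + 1 :]
    aa_q = str(Seq(codon).translate())
    aa_r = str(Seq(ref_codon).translate())
    if aa_q == aa_r:
        return Consequence.SYNONYMOUS
    if aa_q == "*":
        return Consequence.NONSENSE
    return Consequence.MISSENSE


# ---------------------------------------------------------------------------
# classification and orchestration


def classify_allele(
    query: str, hit: ClosestHit, db: ReferenceDatabase
) -> AlleleClass:
    """Partition accepted queries into CONFIRMATORY / EXTENSION / NOVEL.

    Confirmatory: base-identical to a catalogued full-length allele.
    Extension: the query strictly contains, base-identically, the known
    span of a catalogued partial allele.  Everything else is novel.
    """
    for allele in db:
        if allele.is_full_length and allele.sequence == query:
            return AlleleClass.CONFIRMATORY
    for allele in db:
        if (
            not allele.is_full_length
            and len(allele.sequence) < len(query)
            and allele.sequence in query
        ):
            return AlleleClass.EXTENSION
    return AlleleClass.NOVEL


def annotate_allele(
    record,
    db: ReferenceDatabase,
    config: AnnotationConfig | None = None,
) -> AnnotatedAllele:
    """Full annotation pipeline for one FASTA record.

    ``record`` is anything with ``.id`` and ``.seq`` (a Bio.SeqRecord) or a
    ``(label, sequence)`` pair.  Raises :class:`AnnotationRejected` with a
    machine-readable reason code (``ambiguous_bases``, ``no_reference``,
    ``low_identity``, ``not_full_length``) on rejection.
    """
    config = config or AnnotationConfig()
    if hasattr(record, "seq"):
        label, seq = record.id, str(record.seq)
    else:
        label, seq = record
    seq = seq.upper()
    if not seq:
        raise AnnotationRejected("empty_sequence", f"{label}: empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise AnnotationRejected(
            "ambiguous_bases",
            f"{label}: sequence contains letters outside A/C/G/T: "
            f"{','.join(sorted(bad))}",
        )
    try:
        hit = find_closest_reference(seq, db, config)
    except NoReferenceError as e:
        raise AnnotationRejected("no_reference", str(e)) from e
    except NoSuitableReferenceError as e:
        raise AnnotationRejected("low_identity", str(e)) from e

    verdict = check_full_length(hit)
    if not verdict.accepted:
        spans = ", ".join(f"{s}..{e}" for s, e in verdict.uncovered_ref_spans)
        raise AnnotationRejected(
            "not_full_length",
            f"{label}: not full length; uncovered reference span(s) {spans} "
            f"of {hit.reference.allele_name}",
        )
    oriented = hit.alignment.query_seq  # forward-orientation sequence
    model = project_features(hit)
    diffs = enumerate_differences(hit.alignment, hit.reference.gene_model, model)
    coding = translate_cds(extract_cds(oriented, model))
    allele_class = classify_allele(oriented, hit, db)
    return AnnotatedAllele(
        label=label,
        sequence=oriented,
        locus=hit.reference.locus,
        gene_model=model,
        closest=hit,
        differences=diffs,
        coding=coding,
        allele_class=allele_class,
    )
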