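"""Closest-reference search and annotation projection.

A novel full-length allele is annotated by (1) ranking the full-length
reference alleles by shared k-mer count (both query orientations are
screened), (2) globally aligning the query against the top candidates and
keeping the identity-maximal hit, (3) checking that the query covers the
complete reference gene including both UTRs, and (4) mapping every
reference feature boundary through the alignment onto query coordinates.

The aligner is edlib's global (Needleman-Wunsch) mode under unit edit
costs; for intra-locus HLA/KIR comparisons (>90 % identity, indels of a
few bases) the edit-distance-optimal alignment is the "closest in sequence
space" contract made concrete, and it is deterministic for fixed input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import edlib

from .reference_db import Feature, GeneModel, ReferenceAllele, ReferenceDatabase

__all__ = [
    "Orientation",
    "AlignedBlock",
    "GapEvent",
    "AlignmentMap",
    "ClosestHit",
    "Candidate",
    "FullLengthVerdict",
    "AnnotationConfig",
    "NoReferenceError",
    "NoSuitableReferenceError",
    "ProjectionError",
    "reverse_complement",
    "kmer_prescreen",
    "align_pairwise",
    "find_closest_reference",
    "check_full_length",
    "project_features",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Orientation(enum.Enum):
    FORWARD = "FORWARD"
    REVERSE_COMPLEMENT = "REVERSE_COMPLEMENT"


class GapSide(enum.Enum):
    QUERY = "QUERY"  # bases present only in the query (insertion)
    REF = "REF"      # bases present only in the reference (deletion)


@dataclass(frozen=True)
class AlignedBlock:
    """Ungapped aligned stretch; 1-based inclusive on both sequences."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.ref_end - self.ref_start:
            raise ValueError("aligned block has unequal lengths")
        if self.query_end < self.query_start:
            raise ValueError("empty aligned block")


@dataclass(frozen=True)
class GapEvent:
    """One maximal gap run.

    ``side`` names the sequence holding the extra bases; ``anchor`` is the
    position on the *other* sequence immediately before the gap (0 if the
    gap precedes position 1).
    """

    side: GapSide
    anchor: int
    length: int


@dataclass
class AlignmentMap:
    """Block-structured coordinate correspondence of one global alignment.

    ``identity`` is matches / (match + mismatch columns); gap columns do
    not enter the denominator.  ``ref_coverage`` and ``query_coverage``
    are span coverages: the fraction of positions lying between the first
    and last aligned position of that sequence, so internal indels do not
    reduce them but terminal truncations do.
    """

    blocks: list[AlignedBlock]
    gaps: list[GapEvent]
    identity: float
    ref_coverage: float
    query_coverage: float
    orientation: Orientation
    matches: int
    mismatches: int
    query_seq: str
    ref_seq: str
    edit_distance: int

    @property
    def gap_events(self) -> int:
        return len(self.gaps)

    def uncovered_ref_spans(
        self, min_anchor: int = 6, tolerance: int = 5
    ) -> list[tuple[int, int]]:
        """Terminal reference spans not genuinely covered by the query.

        A truncated query can still produce a few chance-matched columns
        inside the missing terminal region (optimal-alignment ties), while
        a genuine small indel near a sequence end fragments the terminal
        aligned block.  Both are handled by anchoring the covered span at
        the first/last block of at least ``min_anchor`` reference bases
        and then counting the reference bases actually deleted outside the
        anchors: a terminal region is uncovered only if more than
        ``tolerance`` bases are missing from it.
        """
        if not self.blocks:
            return [(1, len(self.ref_seq))]

        def length(b: AlignedBlock) -> int:
            return b.ref_end - b.ref_start + 1

        anchored = [b for b in self.blocks if length(b) >= min_anchor]
        if not anchored:
            anchored = [max(self.blocks, key=length)]
        first, last = anchored[0].ref_start, anchored[-1].ref_end
        spans = []
        if first > 1:
            covered = sum(length(b) for b in self.blocks if b.ref_end < first)
            if (first - 1) - covered > tolerance:
                spans.append((1, first - 1))
        if last < len(self.ref_seq):
            covered = sum(length(b) for b in self.blocks if b.ref_start > last)
            if (len(self.ref_seq) - last) - covered > tolerance:
                spans.append((last + 1, len(self.ref_seq)))
        return spans


@dataclass
class Candidate:
    reference: ReferenceAllele
    orientation: Orientation
    shared_kmers: int


@dataclass
class ClosestHit:
    reference: ReferenceAllele
    alignment: AlignmentMap

    @property
    def mismatches(self) -> int:
        return self.alignment.mismatches

    @property
    def gap_events(self) -> int:
        return self.alignment.gap_events

    @property
    def identity(self) -> float:
        return self.alignment.identity


@dataclass
class FullLengthVerdict:
    accepted: bool
    uncovered_ref_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AnnotationConfig:
    """Tunables of the closest-reference search.

    ``min_identity`` guards against annotating a sequence from an
    unsupported locus with the wrong gene's reference.
    """

    min_identity: float = 0.90
    kmer_size: int = 11
    prescreen_top_n: int = 10


class NoReferenceError(ValueError):
    """The database holds no full-length reference allele."""


class NoSuitableReferenceError(ValueError):
    """Best candidate falls below the identity threshold."""

    def __init__(self, best_name: str, best_identity: float, min_identity: float):
        self.best_name = best_name
        self.best_identity = best_identity
        super().__init__(
            f"no suitable reference: best candidate {best_name} has identity "
            f"{best_identity:.4f} < min_identity {min_identity}"
        )


class ProjectionError(ValueError):
    """A reference feature could not be projected onto the query."""


# ---------------------------------------------------------------------------
# prescreen


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_prescreen(
    query: str,
    db: ReferenceDatabase,
    k: int = 11,
    top_n: int = 10,
) -> list[Candidate]:
    """Rank full-length references by shared k-mer count with the query.

    Both orientations of the query are screened; each candidate is tagged
    with its better orientation (ties prefer FORWARD).  Ranking ties are
    broken by allele name ascending, making the ordering deterministic.
    """
    refs = [a for a in db if a.is_full_length]
    if not refs:
        raise NoReferenceError("no full-length reference available in database")
    if len(query) < k:
        raise ValueError(f"query shorter than k-mer size {k}")
    fwd = _kmer_set(query, k)
    rev = _kmer_set(reverse_complement(query), k)
    scored: list[Candidate] = []
    for ref in refs:
        rset = _kmer_set(ref.sequence, k)
        nf, nr = len(fwd & rset), len(rev & rset)
        if nr > nf:
            scored.append(Candidate(ref, Orientation.REVERSE_COMPLEMENT, nr))
        else:
            scored.append(Candidate(ref, Orientation.FORWARD, nf))
    scored.sort(key=lambda c: (-c.shared_kmers, c.reference.allele_name))
    return scored[:top_n]


# ---------------------------------------------------------------------------
# pairwise alignment


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def align_pairwise(
    query: str,
    ref: ReferenceAllele | str,
    orientation: Orientation = Orientation.FORWARD,
) -> AlignmentMap:
    """Global end-to-end alignment of the (oriented) query against a reference.

    Deterministic for fixed inputs.  The returned map's query coordinates
    refer to the oriented query sequence.
    """
    ref_seq = ref.sequence if isinstance(ref, ReferenceAllele) else ref
    if not query or not ref_seq:
        raise ValueError("both sequences must be non-empty")
    oriented = query if orientation is Orientation.FORWARD else reverse_complement(query)
    res = edlib.align(oriented, ref_seq, mode="NW", task="path")
    ops = _parse_cigar(res["cigar"])

    blocks: list[AlignedBlock] = []
    gaps: list[GapEvent] = []
    q = r = 0  # consumed counts (0-based)
    matches = mismatches = 0
    block_q = block_r = None
    for length, op in ops:
        if op in ("=", "X"):
            if block_q is None:
                block_q, block_r = q + 1, r + 1
            if op == "=":
                matches += length
            else:
                mismatches += length
            q += length
            r += length
        else:
            if block_q is not None:
                blocks.append(AlignedBlock(block_q, q, block_r, r))
                block_q = block_r = None
            if op == "I":  # extra bases in query
                gaps.append(GapEvent(GapSide.QUERY, anchor=r, length=length))
                q += length
            elif op == "D":  # extra bases in reference
                gaps.append(GapEvent(GapSide.REF, anchor=q, length=length))
                r += length
            else:
                raise ValueError(f"unexpected CIGAR op {op!r}")
    if block_q is not None:
        blocks.append(AlignedBlock(block_q, q, block_r, r))
    assert q == len(oriented) and r == len(ref_seq)

    aligned_cols = matches + mismatches
    identity = matches / aligned_cols if aligned_cols else 0.0
    if blocks:
        ref_cov = (blocks[-1].ref_end - blocks[0].ref_start + 1) / len(ref_seq)
        query_cov = (blocks[-1].query_end - blocks[0].query_start + 1) / len(oriented)
    else:
        ref_cov = query_cov = 0.0
    return AlignmentMap(
        blocks=blocks,
        gaps=gaps,
        identity=identity,
        ref_coverage=ref_cov,
        query_coverage=query_cov,
        orientation=orientation,
        matches=matches,
        mismatches=mismatches,
        query_seq=oriented,
        ref_seq=ref_seq,
        edit_distance=res["editDistance"],
    )


def find_closest_reference(
    query: str,
    db: ReferenceDatabase,
    config: AnnotationConfig | None = None,
) -> ClosestHit:
    """Identity-maximal hit among the prescreened full-length references.

    Ties are broken by fewer gap events, then allele name ascending.  If
    the best identity falls below ``config.min_identity`` the query is
    presumed to come from an unsupported locus and
    :class:`NoSuitableReferenceError` is raised.
    """
    config = config or AnnotationConfig()
    candidates = kmer_prescreen(
        query, db, k=config.kmer_size, top_n=config.prescreen_top_n
    )
    best: ClosestHit | None = None
    for cand in candidates:
        amap = align_pairwise(query, cand.reference, cand.orientation)
        hit = ClosestHit(cand.reference, amap)
        if best is None or _hit_key(hit) < _hit_key(best):
            best = hit
    assert best is not None
    if best.identity < config.min_identity:
        raise NoSuitableReferenceError(
            best.reference.allele_name, best.identity, config.min_identity
        )
    return best


def _hit_key(hit: ClosestHit) -> tuple:
    return (-hit.identity, hit.gap_events, hit.reference.allele_name)


# ---------------------------------------------------------------------------
# full-length gate and projection


def check_full_length(hit: ClosestHit) -> FullLengthVerdict:
    """Accept iff the query spans the complete reference gene, both UTRs included.

    Query-side insertions are permitted anywhere; what rejects a sequence
    is a terminal reference span (e.g. a missing UTR end) aligned to
    nothing in the query.
    """
    uncovered = hit.alignment.uncovered_ref_spans()
    return FullLengthVerdict(accepted=not uncovered, uncovered_ref_spans=uncovered)


def project_features(hit: ClosestHit) -> GeneModel:
    """Project the reference gene model onto the query through the alignment.

    A reference boundary inside an aligned block maps directly; query-side
    insertions attach to the upstream (left) feature; reference-side
    deletions shrink the containing feature.  The projected model tiles
    [1, query length].
    """
    amap = hit.alignment
    blocks = amap.blocks
    if not blocks:
        raise ProjectionError("empty alignment")
    ref_model = hit.reference.gene_model
    qlen = len(amap.query_seq)

    def query_end_for(ref_boundary: int) -> int:
        """Largest query position attributable to reference <= ref_boundary."""
        blk = None
        for b in blocks:
            if b.ref_start <= ref_boundary:
                blk = b
            else:
                nxt = b
                break
        else:
            nxt = None
        if blk is None:
            # boundary precedes the first aligned reference base
            return 0
        if ref_boundary < blk.ref_end:
            return blk.query_start + (ref_boundary - blk.ref_start)
        # boundary at block end or inside a reference-side deletion:
        # everything up to the next block's start belongs left
        return nxt.query_start - 1 if nxt is not None else qlen

    projected: list[Feature] = []
    start = 1
    for f in ref_model.features:
        end = qlen if f is ref_model.features[-1] else query_end_for(f.end)
        if end < start:
            raise ProjectionError(
                f"feature {f.label()} (reference {f.start}..{f.end}) is "
                f"entirely deleted in the query"
            )
        projected.append(Feature(kind=f.kind, start=start, end=end, ordinal=f.ordinal))
        start = end + 1
    model = GeneModel(features=projected)
    model.validate(qlen, full_length=True)
    return model
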