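"""Synthetic reference databases, mutated queries and brute-force oracles.

Real IPD reference distributions are large downloads; everything the test
suite and the acceptance checks need is generated here instead, with
ground truth attached.  Generated full-length alleles have a well-formed
CDS (starts ATG, ends with a stop, no internal stop, length divisible
by 3); mutated queries come with an edit script from which the expected
projected gene model, difference list and null status are computed
analytically — independently of the alignment pipeline they are used to
check.

All generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .annotation import align_pairwise, Orientation
from .differences import _left_normalize_del, _left_normalize_ins
from .reference_db import (
    Feature,
    FeatureKind,
    GeneModel,
    ReferenceAllele,
    ReferenceDatabase,
    write_reference_flatfile,
)

__all__ = [
    "LocusSpec",
    "Edit",
    "EditScript",
    "MutationResult",
    "ExpectedDifference",
    "default_specs",
    "generate_reference_db",
    "apply_edit_script",
    "random_edit_script",
    "mutate_allele",
    "brute_force_closest",
    "make_mutation_panel",
    "PANEL_KINDS",
    "translate_oracle",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# hand-rolled standard nuclear code; kept independent of Biopython's
# translation so it can serve as the oracle for the coding report
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> tuple[str, bool, bool]:
    """(protein, has_premature_stop, has_frameshift) by direct table lookup."""
    n = len(cds) // 3
    aas = [_CODON_TABLE[cds[3 * i : 3 * i + 3]] for i in range(n)]
    stop = aas.index("*") + 1 if "*" in aas else None
    protein = "".join(aas[: (stop - 1) if stop else n])
    return protein, stop is not None and stop < n, len(cds) % 3 != 0


# ---------------------------------------------------------------------------
# reference database generation


@dataclass
class LocusSpec:
    """Shape of one synthetic locus.

    Lengths are drawn uniformly from the given inclusive ranges;
    ``substitution_rate`` is the per-base divergence between alleles of
    the locus; ``partial_fraction`` adds that fraction (of ``n_alleles``)
    of extra UTR-stripped partial records for extension tests.
    """

    name: str
    n_alleles: int = 10
    n_exons: int = 4
    utr5_range: tuple[int, int] = (150, 300)
    utr3_range: tuple[int, int] = (150, 300)
    exon_range: tuple[int, int] = (120, 350)
    intron_range: tuple[int, int] = (90, 250)
    substitution_rate: float = 0.01
    partial_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("n_exons must be >= 2")
        for rng_ in (self.utr5_range, self.utr3_range, self.exon_range, self.intron_range):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid length range {rng_}")


def default_specs(n_alleles: int = 10) -> list[LocusSpec]:
    """Three synthetic loci: two HLA-like, one KIR-like."""
    return [
        LocusSpec("HLA-A", n_alleles=n_alleles, n_exons=4),
        LocusSpec("HLA-B", n_alleles=n_alleles, n_exons=3, exon_range=(150, 400)),
        LocusSpec(
            "KIR2DL1",
            n_alleles=n_alleles,
            n_exons=5,
            exon_range=(100, 300),
            intron_range=(120, 300),
        ),
    ]


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _random_cds(rng: random.Random, n_codons: int) -> str:
    codons = ["ATG"]
    sense = [c for c in _CODON_TABLE if _CODON_TABLE[c] != "*"]
    sense.sort()
    for _ in range(n_codons - 2):
        codons.append(rng.choice(sense))
    codons.append(rng.choice(sorted(_STOPS)))
    return "".join(codons)


def _build_base_allele(rng: random.Random, spec: LocusSpec) -> tuple[str, GeneModel]:
    exon_lens = [rng.randint(*spec.exon_range) for _ in range(spec.n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] += (3 - total % 3) % 3
    cds = _random_cds(rng, sum(exon_lens) // 3)
    intron_lens = [rng.randint(*spec.intron_range) for _ in range(spec.n_exons - 1)]
    utr5 = _random_seq(rng, rng.randint(*spec.utr5_range))
    utr3 = _random_seq(rng, rng.randint(*spec.utr3_range))

    parts = [utr5]
    features = [Feature(FeatureKind.UTR5, 1, len(utr5))]
    pos = len(utr5)
    cds_off = 0
    for i, elen in enumerate(exon_lens):
        parts.append(cds[cds_off : cds_off + elen])
        features.append(Feature(FeatureKind.EXON, pos + 1, pos + elen, ordinal=i + 1))
        pos += elen
        cds_off += elen
        if i < len(intron_lens):
            intron = _random_seq(rng, intron_lens[i])
            parts.append(intron)
            features.append(
                Feature(FeatureKind.INTRON, pos + 1, pos + len(intron), ordinal=i + 1)
            )
            pos += len(intron)
    features.append(Feature(FeatureKind.UTR3, pos + 1, pos + len(utr3)))
    parts.append(utr3)
    return "".join(parts), GeneModel(features=features)


def _cds_index(model: GeneModel, pos: int) -> int | None:
    off = 0
    for s, e in model.cds_spans:
        if s <= pos <= e:
            return off + (pos - s + 1)
        off += e - s + 1
    return None


def _diverge(
    rng: random.Random, sequence: str, model: GeneModel, rate: float
) -> str:
    """Substitute bases at ``rate``, never creating a stop codon or
    touching the start/stop codons themselves."""
    seq = list(sequence)
    n_cds = sum(e - s + 1 for s, e in model.cds_spans)
    for pos in range(1, len(seq) + 1):
        if rng.random() >= rate:
            continue
        ci = _cds_index(model, pos)
        if ci is not None and (ci <= 3 or ci > n_cds - 3):
            continue  # keep ATG and terminal stop intact
        choices = [b for b in _BASES if b != seq[pos - 1]]
        rng.shuffle(choices)
        for b in choices:
            old = seq[pos - 1]
            seq[pos - 1] = b
            if ci is None:
                break
            # recompute the codon through the CDS (codons may straddle exons)
            cds = "".join(
                "".join(seq[s - 1 : e]) for s, e in model.cds_spans
            )
            codon_i = (ci - 1) // 3
            if cds[3 * codon_i : 3 * codon_i + 3] not in _STOPS:
                break
            seq[pos - 1] = old
    return "".join(seq)


def _strip_utrs(sequence: str, model: GeneModel) -> tuple[str, GeneModel]:
    inner = [f for f in model.features if f.kind in (FeatureKind.EXON, FeatureKind.INTRON)]
    shift = inner[0].start - 1
    feats = [replace(f, start=f.start - shift, end=f.end - shift) for f in inner]
    seq = sequence[inner[0].start - 1 : inner[-1].end]
    return seq, GeneModel(features=feats)


def generate_reference_db(
    specs: list[LocusSpec] | None = None,
    seed: int = 0,
    version: str | None = None,
) -> tuple[str, ReferenceDatabase, dict[str, GeneModel]]:
    """Synthetic flat-file text, parsed-equivalent database and truth models.

    Deterministic for a fixed seed.  Every full-length allele satisfies
    the gene-model invariants and encodes a stop-free, in-frame protein;
    ``partial_fraction`` of extra alleles per locus are stored UTR-stripped
    (their full-length donors are *not* catalogued, so a query equal to a
    donor is an extension case, not confirmatory).
    """
    specs = specs if specs is not None else default_specs()
    rng = random.Random(seed)
    db = ReferenceDatabase(
        version=version or f"synthetic-{seed}",
        release_date="2019-03-25",
    )
    truth: dict[str, GeneModel] = {}
    counter = 0
    for spec in specs:
        base_seq, model = _build_base_allele(rng, spec)
        seen = set()
        n_partial = round(spec.partial_fraction * spec.n_alleles)
        for i in range(spec.n_alleles + n_partial):
            if i == 0:
                seq = base_seq
            else:
                for _ in range(20):
                    seq = _diverge(rng, base_seq, model, spec.substitution_rate)
                    if seq not in seen:
                        break
                else:
                    raise ValueError(
                        f"{spec.name}: could not generate distinct allele "
                        f"(substitution_rate too low?)"
                    )
            seen.add(seq)
            counter += 1
            name = f"{spec.name}*{i + 1:02d}:01"
            if i < spec.n_alleles:
                allele = ReferenceAllele(
                    allele_name=name,
                    sequence=seq,
                    gene_model=GeneModel(features=list(model.features)),
                    record_id=f"SYN{counter:05d}",
                )
            else:
                pseq, pmodel = _strip_utrs(seq, model)
                allele = ReferenceAllele(
                    allele_name=name,
                    sequence=pseq,
                    gene_model=pmodel,
                    record_id=f"SYN{counter:05d}",
                )
            allele.validate()
            db.add(allele)
            truth[name] = allele.gene_model
    return write_reference_flatfile(db), db, truth


# ---------------------------------------------------------------------------
# edit scripts


@dataclass(frozen=True)
class Edit:
    """One edit on reference coordinates.

    SUB: replace the base at ``ref_pos`` with ``bases`` (length 1).
    INS: insert ``bases`` after ``ref_pos`` (0 allowed: before position 1).
    DEL: delete ``bases`` starting at ``ref_pos`` (``bases`` must equal the
    reference there).
    """

    kind: str  # SUB | INS | DEL
    ref_pos: int
    bases: str

    @property
    def ref_span(self) -> tuple[int, int]:
        if self.kind == "SUB":
            return (self.ref_pos, self.ref_pos)
        if self.kind == "DEL":
            return (self.ref_pos, self.ref_pos + len(self.bases) - 1)
        return (self.ref_pos, self.ref_pos)  # INS anchors on ref_pos


@dataclass
class EditScript:
    edits: list[Edit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edits = sorted(self.edits, key=lambda e: (e.ref_pos, e.kind))
        prev_end = 0
        for e in self.edits:
            s, end = e.ref_span
            if s <= prev_end and not (e.kind == "INS" and s == prev_end):
                raise ValueError(f"overlapping or unsorted edits at ref {s}")
            prev_end = end

    def __iter__(self):
        return iter(self.edits)

    def __len__(self) -> int:
        return len(self.edits)


def apply_edit_script(sequence: str, script: EditScript) -> str:
    """Independent applier: build the mutated sequence left to right."""
    out = []
    cursor = 1  # next reference position to copy
    for e in script:
        if e.kind == "SUB":
            out.append(sequence[cursor - 1 : e.ref_pos - 1])
            if sequence[e.ref_pos - 1] == e.bases:
                raise ValueError(f"SUB at {e.ref_pos} does not change the base")
            out.append(e.bases)
            cursor = e.ref_pos + 1
        elif e.kind == "INS":
            out.append(sequence[cursor - 1 : e.ref_pos])
            out.append(e.bases)
            cursor = e.ref_pos + 1
        elif e.kind == "DEL":
            if sequence[e.ref_pos - 1 : e.ref_pos - 1 + len(e.bases)] != e.bases:
                raise ValueError(f"DEL at {e.ref_pos} does not match reference")
            out.append(sequence[cursor - 1 : e.ref_pos - 1])
            cursor = e.ref_pos + len(e.bases)
        else:
            raise ValueError(f"unknown edit kind {e.kind}")
    out.append(sequence[cursor - 1 :])
    return "".join(out)


@dataclass(frozen=True)
class ExpectedDifference:
    dtype: str
    query_pos: int
    ref_pos: int
    ref_bases: str
    query_bases: str


@dataclass
class MutationResult:
    query: str
    script: EditScript
    expected_model: GeneModel
    expected_differences: list[ExpectedDifference]
    expected_is_null: bool
    expected_protein: str


def _boundary_zones(model: GeneModel, buffer: int) -> list[tuple[int, int]]:
    zones = []
    for f in model.features:
        zones.append((f.start - buffer, f.start + buffer))
        zones.append((f.end - buffer, f.end + buffer))
    return zones


def _in_zones(pos: int, zones: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in zones)


def _ins_shift_range(ref: str, anchor: int, bases: str) -> tuple[int, int]:
    """(leftmost, rightmost) equivalent anchors of an insertion."""
    a, b = anchor, bases
    while a >= 1 and b[-1] == ref[a - 1]:
        b = b[-1] + b[:-1]
        a -= 1
    left = a
    a, b = anchor, bases
    while a < len(ref) and b[0] == ref[a]:
        b = b[1:] + b[0]
        a += 1
    return left, a


def _del_shift_range(ref: str, start: int, length: int) -> tuple[int, int]:
    """(leftmost start, rightmost end) of equivalent deletion placements."""
    s, e = start, start + length - 1
    while s >= 2 and ref[s - 2] == ref[e - 1]:
        s -= 1
        e -= 1
    left = s
    s, e = start, start + length - 1
    while e < len(ref) and ref[s - 1] == ref[e]:
        s += 1
        e += 1
    return left, e


def random_edit_script(
    ref: ReferenceAllele,
    rng: random.Random,
    sub_rate: float = 0.005,
    n_indels: tuple[int, int] = (0, 3),
    indel_len: tuple[int, int] = (1, 3),
    boundary_buffer: int = 4,
    min_spacing: int = 10,
) -> EditScript:
    """Random, well-posed edit script for annotation-recovery tests.

    Edits stay clear of feature boundaries: an indel is only accepted if
    its whole shift-ambiguity range (the equivalent placements any optimal
    alignment may choose) lies inside one feature with the boundary buffer
    respected, so the analytically expected projection is achieved by
    every optimal alignment.
    """
    seq, model = ref.sequence, ref.gene_model
    zones = _boundary_zones(model, boundary_buffer)
    occupied: list[tuple[int, int]] = []

    def free(s: int, e: int) -> bool:
        return all(
            e < os - min_spacing or s > oe + min_spacing for os, oe in occupied
        )

    edits: list[Edit] = []
    n_ind = rng.randint(*n_indels)
    attempts = 0
    while len([e for e in edits if e.kind != "SUB"]) < n_ind and attempts < 500:
        attempts += 1
        length = rng.randint(*indel_len)
        kind = rng.choice(["INS", "DEL"])
        if kind == "INS":
            anchor = rng.randint(1, len(seq) - 1)
            bases = _random_seq(rng, length)
            lo, hi = _ins_shift_range(seq, anchor, bases)
            span_ok = not _in_zones(lo, zones) and not _in_zones(hi + 1, zones)
            feat_ok = model.feature_at(max(lo, 1)) is model.feature_at(min(hi + 1, len(seq)))
            if span_ok and feat_ok and free(lo, hi + 1):
                edits.append(Edit("INS", anchor, bases))
                occupied.append((lo, hi + 1))
        else:
            start = rng.randint(2, len(seq) - indel_len[1] - 1)
            bases = seq[start - 1 : start - 1 + length]
            lo, hi = _del_shift_range(seq, start, length)
            span_ok = not _in_zones(lo - 1, zones) and not _in_zones(hi + 1, zones)
            feat_ok = model.feature_at(max(lo - 1, 1)) is model.feature_at(min(hi + 1, len(seq)))
            if span_ok and feat_ok and free(lo - 1, hi + 1):
                edits.append(Edit("DEL", start, bases))
                occupied.append((lo - 1, hi + 1))

    for pos in range(1, len(seq) + 1):
        if rng.random() >= sub_rate:
            continue
        if _in_zones(pos, zones) or not free(pos, pos):
            continue
        new = rng.choice([b for b in _BASES if b != seq[pos - 1]])
        edits.append(Edit("SUB", pos, new))
        occupied.append((pos, pos))
    return EditScript(edits=edits)


def mutate_allele(
    ref: ReferenceAllele,
    script: EditScript | None = None,
    seed: int | None = None,
    **script_kwargs,
) -> MutationResult:
    """Apply an edit script (or a random one) and compute the expected truth.

    Expected boundaries shift by the cumulative net indel length upstream;
    the expected difference list is the left-normalised script; the
    expected null status comes from direct table translation of the
    mutated CDS.
    """
    if script is None:
        rng = random.Random(seed)
        script = random_edit_script(ref, rng, **script_kwargs)
    seq, model = ref.sequence, ref.gene_model
    query = apply_edit_script(seq, script)

    def offset_at(boundary: int) -> int:
        off = 0
        for e in script:
            if e.kind == "INS" and e.ref_pos <= boundary:
                off += len(e.bases)
            elif e.kind == "DEL" and e.ref_pos + len(e.bases) - 1 <= boundary:
                off -= len(e.bases)
        return off

    feats = []
    start = 1
    for f in model.features:
        end = len(query) if f is model.features[-1] else f.end + offset_at(f.end)
        feats.append(Feature(kind=f.kind, start=start, end=end, ordinal=f.ordinal))
        start = end + 1
    expected_model = GeneModel(features=feats)
    expected_model.validate(len(query), full_length=ref.is_full_length)

    expected: list[ExpectedDifference] = []
    running = 0
    for e in script:
        if e.kind == "SUB":
            expected.append(
                ExpectedDifference(
                    "SUB", e.ref_pos + running, e.ref_pos, seq[e.ref_pos - 1], e.bases
                )
            )
        elif e.kind == "INS":
            anchor, bases, q_pos = _left_normalize_ins(
                seq, query, e.ref_pos, e.bases, e.ref_pos + running + 1
            )
            expected.append(ExpectedDifference("INS", q_pos, anchor, "", bases))
            running += len(e.bases)
        else:
            s, bases, q_anchor = _left_normalize_del(
                seq, query, e.ref_pos, e.bases, e.ref_pos - 1 + running
            )
            expected.append(ExpectedDifference("DEL", q_anchor, s, bases, ""))
            running -= len(e.bases)
    expected.sort(key=lambda d: (d.query_pos, d.dtype))

    cds = "".join(query[s - 1 : e] for s, e in expected_model.cds_spans)
    protein, premature, frameshift = translate_oracle(cds)
    return MutationResult(
        query=query,
        script=script,
        expected_model=expected_model,
        expected_differences=expected,
        expected_is_null=premature or frameshift,
        expected_protein=protein,
    )


# ---------------------------------------------------------------------------
# oracles


def brute_force_closest(query: str, db: ReferenceDatabase, top_choice_only: bool = True):
    """Exhaustive closest-reference search: align the query in both
    orientations against every full-length allele, no prescreen."""
    best = None
    for ref in db:
        if not ref.is_full_length:
            continue
        for orient in (Orientation.FORWARD, Orientation.REVERSE_COMPLEMENT):
            amap = align_pairwise(query, ref, orient)
            key = (-amap.identity, len(amap.gaps), ref.allele_name)
            if best is None or key < best[0]:
                best = (key, ref.allele_name)
    if best is None:
        raise ValueError("no full-length allele in database")
    return best[1]


# ---------------------------------------------------------------------------
# mutation panels for the null-allele truth table

PANEL_KINDS = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
)


def _genome_pos(model: GeneModel, cds_pos: int) -> int:
    off = 0
    for s, e in model.cds_spans:
        span = e - s + 1
        if cds_pos <= off + span:
            return s + (cds_pos - off - 1)
        off += span
    raise ValueError(f"cds position {cds_pos} beyond CDS")


def _single_sub_candidates(cds: str, codon_index: int):
    """All (within, new_base, new_codon) single-base variants of a codon."""
    codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    for within in range(3):
        for b in _BASES:
            if b == codon[within]:
                continue
            yield within, b, codon[:within] + b + codon[within + 1 :]


def make_mutation_panel(
    ref: ReferenceAllele, kind: str, n: int, rng: random.Random
) -> list[MutationResult]:
    """``n`` single-edit mutants of a given consequence class.

    ``synonymous``/``missense``/``nonsense`` are exonic substitutions;
    ``frameshift_indel`` inserts or deletes 1-2 bases in an exon;
    ``inframe_indel`` 3 bases.  Expected null status always comes from the
    translation oracle (an in-frame indel can still create a stop codon).
    """
    if kind not in PANEL_KINDS:
        raise ValueError(f"unknown panel kind {kind!r}")
    seq, model = ref.sequence, ref.gene_model
    cds = "".join(seq[s - 1 : e] for s, e in model.cds_spans)
    n_codons = len(cds) // 3
    zones = _boundary_zones(model, 4)
    results: list[MutationResult] = []
    attempts = 0
    while len(results) < n and attempts < n * 200:
        attempts += 1
        if kind in ("synonymous", "missense", "nonsense"):
            ci = rng.randint(2, n_codons - 1)
            cands = list(_single_sub_candidates(cds, ci))
            rng.shuffle(cands)
            chosen = None
            old_aa = _CODON_TABLE[cds[3 * (ci - 1) : 3 * ci]]
            for within, b, new_codon in cands:
                new_aa = _CODON_TABLE[new_codon]
                if kind == "synonymous" and new_aa == old_aa:
                    chosen = (within, b)
                elif kind == "missense" and new_aa not in (old_aa, "*"):
                    chosen = (within, b)
                elif kind == "nonsense" and new_aa == "*" and old_aa != "*":
                    chosen = (within, b)
                if chosen:
                    break
            if not chosen:
                continue
            pos = _genome_pos(model, 3 * (ci - 1) + chosen[0] + 1)
            if _in_zones(pos, zones):
                continue
            script = EditScript([Edit("SUB", pos, chosen[1])])
        else:
            length = rng.choice([1, 2]) if kind == "frameshift_indel" else 3
            exon = rng.choice(model.exons)
            if exon.end - exon.start < 20:
                continue
            if rng.random() < 0.5:
                anchor = rng.randint(exon.start + 5, exon.end - 6)
                bases = _random_seq(rng, length)
                lo, hi = _ins_shift_range(seq, anchor, bases)
                if _in_zones(lo, zones) or _in_zones(hi + 1, zones):
                    continue
                if not (exon.start <= lo and hi + 1 <= exon.end):
                    continue
                script = EditScript([Edit("INS", anchor, bases)])
            else:
                start = rng.randint(exon.start + 5, exon.end - 6 - length)
                bases = seq[start - 1 : start - 1 + length]
                lo, hi = _del_shift_range(seq, start, length)
                if _in_zones(lo - 1, zones) or _in_zones(hi + 1, zones):
                    continue
                if not (exon.start <= lo - 1 and hi + 1 <= exon.end):
                    continue
                script = EditScript([Edit("DEL", start, bases)])
        results.append(mutate_allele(ref, script=script))
    if len(results) < n:
        raise ValueError(f"could not build {n} mutants of kind {kind}")
    return results
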