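# Methods

This note documents the models, conventions and numerical choices behind
`alleleforge`, what the synthetic data emulates, and the known
limitations.

## Reference model

An allele is a genomic sequence partitioned into an ordered gene model:
5'UTR, exon 1, intron 1, ..., exon *n*, 3'UTR, in 1-based inclusive
coordinates exactly as printed in the IPD flat files (no internal 0-based
layer — one convention everywhere eliminates off-by-one translation
bugs). The coding sequence is the concatenation of the exon spans. An
allele is *full length* iff its model contains both UTRs; only
full-length alleles serve as annotation references. Parsing consumes only
the `ID`, `DE`, `FT` and `SQ` line types; the bare `UTR` key used by the
IPD distributions is disambiguated by position relative to the first
exon. A `CDS join(...)` line, when present, is cross-checked against the
exon spans; on mismatch the exon features win and a warning is recorded,
because the exon features are the projection substrate. A record whose
sequence contains letters outside A/C/G/T is skipped with a warning
rather than aborting the database load. The writer is bit-exact for the
dialect, which makes `parse ∘ write` the identity and `write ∘ parse ∘
write` a byte fixed point — the property the parser tests lean on.

## Closest-reference search

Candidates are ranked by shared *k*-mer count (*k* = 11) between the
query and each full-length reference; both query orientations are
screened and each candidate is tagged with its better strand, so
sequencer output strand never matters (the stored and submitted sequence
is always the annotated forward orientation). The top 10 candidates are
aligned globally and the identity-maximal hit wins; ties break by fewer
gap events, then allele name. Within an HLA/KIR locus alleles are >90 %
identical, so the shared-*k*-mer filter is safe; the test suite and the
acceptance run quantify this by comparing against a brute-force
oracle that aligns the query to every reference (agreement 100/100 at
the default `top_n`, and by construction exact when `top_n` equals the
database size). A hit below `min_identity` = 0.90 raises instead of
returning: a query that far from every reference is presumed to come
from an unsupported locus, and annotating it with the wrong gene's model
would be worse than failing.

Alignment uses edlib's global (Needleman–Wunsch) mode under unit edit
costs (match 0, mismatch/indel 1, minimised). For the intra-locus
comparisons this tool performs — >95 % identity, indels of a few bases —
the edit-distance-optimal alignment realises the "closest in sequence
space" contract, is deterministic for fixed input, and runs in about a
millisecond for a 3.5 kb pair, which is what lets the acceptance checks
align thousands of pairs in seconds. A quadratic-space textbook DP under
the same costs is kept in the test suite as an independent score oracle.

## Full-length gate

A query is accepted iff it covers the complete reference gene including
both UTR ends. Coverage is measured as span coverage of the reference:
internal deletions do not reject (they shrink the containing feature
during projection), terminal truncations do. Two alignment artefacts
have to be neutralised here: equivalent optimal alignments of a
truncated query can scatter a few chance-matched columns into the
missing terminal region (hiding the terminal gap), and a genuine small
indel near a sequence end fragments the terminal aligned block (faking
one). The gate therefore anchors the covered span at the outermost
aligned block of at least 6 reference bases and then counts the
reference bases actually deleted outside the anchors; a terminal region
is uncovered only when more than 5 bases are missing from it.
Consequence: the gate is exact for the biologically relevant case (a
missing or substantially incomplete UTR) and deliberately not a
guarantee about ±5 bp of UTR length. Sequences with partially known
UTRs are out of scope and rejected.

## Annotation projection

Each reference feature boundary maps through the alignment: a boundary
inside an aligned block maps directly; query-side insertions attach to
the upstream (left) feature — the deterministic convention "boundary =
last reference base"; reference-side deletions shrink the containing
feature. The projected model provably tiles [1, query length], and a
feature whose reference span is entirely deleted raises a projection
error rather than emitting an empty feature. Projecting a reference onto
itself returns its own model exactly, and annotating the reverse
complement of a query yields the identical model (orientation
invariance) — both are tested.

## Difference list and canonical indels

One record is emitted per substituted column and per maximal gap run,
sorted by query position, each with feature context (from the query
model) and, for exonic records, the coding-sequence position and codon
index (for indels these refer to the anchoring base — the reference base
preceding the run). Indel placement within a repeat is ambiguous, and an
optimal unit-cost alignment may even split one multi-base indel into
fragments separated by match columns. The difference list is therefore
canonicalised: fragments of the same type with nothing but matches
between them are recombined whenever the spanned region admits a
single-run representation (decided by a common-prefix/suffix test), and
every indel is shifted to its 5'-most equivalent placement, VCF-style,
with a guard that never shifts across a mismatch column. This makes the
emitted list a deterministic function of the two sequences, byte-exactly
invertible (reference + differences reconstructs the query — the IPD
"coherence check" made executable), and equal to the generating edit
script on the synthetic fixtures.

Consequences are judged on the query codon containing the change, using
the query coding sequence — well defined even downstream of indels, and
what the repository curator sees. An exonic substitution is SYNONYMOUS /
MISSENSE / NONSENSE by comparing the query codon with that codon with
the substituted base reverted; an exonic indel is FRAMESHIFT iff its
length is not divisible by 3, else INFRAME_INDEL. Start-codon loss is
reported as MISSENSE at codon 1 and does not by itself set the null
flag: only frameshifts and premature stops define a null allele here.
Stop codons are TAA/TAG/TGA (standard nuclear code); a premature stop is
a stop at any codon index before the final complete codon.

## Classification

CONFIRMATORY: base-identical to a catalogued full-length allele.
EXTENSION: not confirmatory, but the query strictly contains,
base-identically, the known span of a catalogued partial allele —
implemented as exact substring containment, which is equivalent to
aligner-based anchoring for an exact match and cheaper. Otherwise NOVEL.
The three classes partition all accepted queries.

## Submission artifacts

All writers are pure functions of their inputs (the zip packer pins
timestamps), so artifacts are reproducible byte for byte. The EMBL
record uses the `XXX` placeholder in the accession fields of the ID line
(the pre-accession convention), writes the CDS as the join of exon
spans, and for null alleles emits `/pseudo` with no `/translation` —
repositories do not accept translations through premature stops. The
exact production layout of the IPD bulk-submission file is maintained by
IPD and not reproduced here; the shipped document is a versioned
re-implementation (header `IPD-SUBMISSION-TEMPLATE v1`) with fixed block
order, isolated so it can be replaced wholesale. Its difference lines
use coding-sequence positions for exonic records and feature-local
positions elsewhere, and the document parser + re-applier in the same
module turn the coherence check into a test. The genotype CSV uses the
minimal unambiguous header (`sample_id`, then `<locus>_1,<locus>_2`
pairs); the accession attachment is `<name><TAB><accession>` with
comment lines tolerated. No network I/O exists anywhere; the ENA
transport is an interface with a dry-run implementation that records
payloads and returns deterministic identifiers.

## Workdesk

Persistence is a single-file SQLite store. Statuses are per repository
with categories FINISHED/PENDING/TODO/ERROR; the transition machine is
ENA: TODO → PENDING → FINISHED (accessions recorded atomically —
all-or-nothing, because partially registered accessions create
irrecoverable mixed states), any → ERROR, ERROR → TODO (retry); IPD is
gated on ENA FINISHED plus passed genotype validation, then TODO →
PENDING → FINISHED (manual entry of the IPD response). Exhaustive
replay of all action sequences up to depth 5 confirms IPD FINISHED is
unreachable without ENA FINISHED. Project ids follow
`<user>_<YYYYMMDD>_<counter>`; local allele names
`<locus>_<sample>_<counter>`; the cell-line id defaults to a
deterministic function of user and sample and can be overridden — these
naming schemes are artifact conventions, not repository requirements.

## Synthetic data and what the tests show

The generator builds three loci (two HLA-like, one KIR-like; 2–4 kb
genes, 3–5 exons, 10 alleles each by default) whose full-length alleles
always carry a well-formed CDS: starts ATG, ends with a stop, no
internal stop, length divisible by 3. Alleles within a locus differ by
~1 % substitutions (stop-creating substitutions are resampled); a
fraction of extra records are stored UTR-stripped as partial alleles for
extension tests, their full-length donors deliberately uncatalogued.
Mutated queries apply seeded edit scripts (default 0.5 % substitutions
and 0–3 indels of 1–3 bp, the regime of a novel intra-locus allele);
the expected projected model, difference list and null status are
computed analytically from the script, independently of the alignment
pipeline — translation truth uses a hand-rolled codon table, not the
Biopython call the pipeline uses. Random indels are rejected if their
shift-ambiguity range (the set of equivalent placements any optimal
alignment may choose) touches a 4 bp buffer around a feature boundary,
which is what makes boundary recovery a well-posed 100 %-or-bug check;
boundary-touching edits are exactly the convention-dependent cases the
left-attachment rule decides.

What passing does **not** show about real data: real HLA/KIR sequences
carry homopolymers, repeats and paralogous exons that make indel
placement more ambiguous than in uniform-random sequence; real queries
may be chimeric, contain ambiguity codes (rejected here by design), or
sit at larger distances from the nearest reference. The
sizes (30-allele databases, 200-query panels, 50 mutants per null
class) were chosen to exercise every code path in seconds; they do not
emulate the >20 000 records of a real IPD release.

## Known limitations

* Unit-cost alignment has no affine gap model; for the short indels of
  intra-locus comparisons this is immaterial, but distant queries with
  long gaps would be better served by affine scoring.
* A deletion spanning a feature boundary is classified by the feature of
  its anchoring base and its total length; fixtures avoid this case and
  real occurrences deserve manual review.
* The full-length gate cannot distinguish a query missing ~≤5 bp of UTR
  end from one with an internal deletion near the end (see above).
* Differences inside query-only UTR overhangs are reported as insertions
  anchored at the adjacent UTR position.
* Multi-gene queries, chimera detection, HGVS strings and official
  allele-name proposal are out of scope; IPD assigns names.
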