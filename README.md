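# alleleforge

Annotation and submission tooling for full-length novel HLA and KIR
alleles.

High-throughput immunogenetic typing keeps discovering alleles of the HLA
and killer-cell immunoglobulin-like receptor (KIR) genes that are not yet
catalogued in the IPD-IMGT/HLA and IPD-KIR databases. Depositing such an
allele is a two-step process — first the annotated genomic sequence goes
to a general archive (EMBL-ENA), then the sequence, its accession number
and a delineation of its differences from a closely related catalogued
allele go to IPD — and both steps demand strictly formatted files that
are tedious and error-prone to prepare by hand. `alleleforge` automates
the computational core of that workflow:

* **Reference handling** — a parser/writer for the IPD flat-file dialect
  (EMBL-style `ID`/`DE`/`FT`/`SQ` records, as in `hla.dat` / `KIR.dat`),
  selecting the full-length reference alleles usable for annotation.
* **Annotation** — given a novel full-length sequence, find the closest
  catalogued reference (shared *k*-mer prescreen over both strands, then
  global alignment; identity-maximal hit wins), check that the query
  covers the complete gene including both untranslated regions, and
  project the reference's 5'UTR/exon/intron/3'UTR model onto the query
  through the alignment coordinate map.
* **Difference elucidation** — enumerate every substitution and indel
  (left-normalised, one record per maximal run) with feature and codon
  context, translate the coding sequence, flag **null alleles**
  (frameshift or premature stop codon), and classify the submission as
  novel, confirmatory, or an extension of a partially known allele.
* **Submission artifacts** — bit-controlled ENA-dialect EMBL flat files
  (`/pseudo` for null alleles, `/translation` otherwise), ENA
  project/submission XML payloads, the IPD submission document whose
  difference block is an executable coherence check, genotype-CSV
  validation (IPD minimally requires HLA-A, HLA-B, HLA-DRB1 and the
  partner allele at the submitted locus), and accession-attachment
  parsing.
* **Workdesk** — a single-file SQLite store tracking projects, alleles,
  statuses (to-do / pending / finished / error per repository),
  accessions and artifacts, with a status machine that gates IPD
  submission on a recorded ENA accession; exposed both as a library and
  as the `alleleforge` command-line tool.

A synthetic-data module (`alleleforge.fixtures`) generates reference
databases and mutated query alleles with analytic ground truth (expected
gene model, difference list and null status computed directly from the
edit script), so the whole pipeline is testable without downloading any
reference distribution.

## Worked example

```python
from alleleforge.fixtures import generate_reference_db, mutate_allele, default_specs
from alleleforge.differences import annotate_allele

text, db, _ = generate_reference_db(default_specs(10), seed=1)   # 3 loci x 10 alleles
ref = db["HLA-A*01:01"]
res = mutate_allele(ref, seed=42, sub_rate=0.005, n_indels=(1, 3))
allele = annotate_allele(("sample1_HLA-A", res.query), db)

print(f"closest reference : {allele.closest_reference_name} (identity {allele.identity:.4f})")
print(f"classification    : {allele.allele_class.value}")
print(f"null allele       : {allele.is_null}")
print(f"differences       : {len(allele.differences)}")
```

prints

```
closest reference : HLA-A*01:01 (identity 0.9968)
classification    : NOVEL
null allele       : True
differences       : 9
```

The query differs from its closest reference at 9 positions; one of them
is a single-base exonic insertion, so the coding frame is shifted and the
allele is flagged null (its difference records carry `FRAMESHIFT` and,
downstream, `NONSENSE` consequences). `write_embl_flatfile` and
`write_ipd_submission` turn this object into the ENA and IPD artifacts;
the shell workflow is:

```bash
alleleforge init --user lab --data-path data --reference-db refs.dat ...
alleleforge project new --title "Novel HLA"
alleleforge allele add --project lab_20190325_001 --sample-id S1 --fasta novel.fasta
alleleforge submit ena --project lab_20190325_001
alleleforge accessions record --project lab_20190325_001 --file accessions.txt
alleleforge submit ipd --project lab_20190325_001 --genotypes geno.csv --accessions accessions.txt
alleleforge export --project lab_20190325_001 --zip submission.zip
```

## Layout

```
src/alleleforge/
  reference_db.py        IPD flat-file dialect: parse, validate, write
  annotation.py          prescreen, global alignment, projection
  differences.py         diff enumeration, translation, null detection
  submission_formats.py  EMBL/XML/IPD writers, genotype & accession parsing
  workdesk.py            SQLite workflow store and status machine
  cli.py                 command-line interface
  fixtures.py            synthetic data generation and oracles
docs/methods.md          models, conventions and limitations
```
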