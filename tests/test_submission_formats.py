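"""Submission artifact writers and auxiliary input parsers."""

import io
import xml.etree.ElementTree as ET
import zipfile

import pytest

from alleleforge.differences import (
    AlleleClass,
    AnnotatedAllele,
    CodingReport,
    annotate_allele,
)
from alleleforge.fixtures import mutate_allele
from alleleforge.reference_db import Feature, FeatureKind, GeneModel, parse_reference_flatfile
from alleleforge.submission_formats import (
    DryRunTransport,
    EnaRecordMeta,
    IpdSubmissionMeta,
    ProjectXmlMeta,
    SubmissionXmlMeta,
    ValidationError,
    XmlKind,
    concatenate_flatfiles,
    package_submission,
    parse_accession_attachment,
    read_genotype_csv,
    reconstruct_query_from_ipd,
    validate_genotypes,
    write_embl_flatfile,
    write_ena_submission_xml,
    write_ipd_submission,
)

META = EnaRecordMeta(
    study_accession="PRJEB00001",
    sample_id="CL-1",
    description="Homo sapiens HLA-A gene, novel allele",
    gene="HLA-A",
    allele_local_name="HLA-A_S1_001",
)

IPD_META = IpdSubmissionMeta(
    submitter_id="SUB0001",
    cell_line_id="CL-1",
    sequencing_platform="ONT PromethION",
    primer_set="panel-v2",
    read_depth="500x",
    ena_accession="LR000001",
)

GENO_CSV = (
    "sample_id,HLA-A_1,HLA-A_2,HLA-B_1,HLA-B_2,HLA-DRB1_1,HLA-DRB1_2\n"
    "S1,01:01,02:01,07:02,08:01,15:01,03:01\n"
)


@pytest.fixture(scope="session")
def annotated(synthetic_db):
    _, db, _ = synthetic_db
    ref = next(a for a in db if a.is_full_length)
    res = mutate_allele(ref, seed=21, sub_rate=0.005, n_indels=(1, 2))
    return annotate_allele(("q1", res.query), db), ref


def tiny_allele(null=False):
    """Hand-built 65 bp annotated allele for layout-detail checks."""
    seq = "ACGTACGTTT" + "ATGAAACCCGGGTTTACCTAA" + "CCCCCCCCCCGGGGGGGGGGACGTACGTACGTAC"
    model = GeneModel(
        features=[
            Feature(FeatureKind.UTR5, 1, 10),
            Feature(FeatureKind.EXON, 11, 31, ordinal=1),
            Feature(FeatureKind.UTR3, 32, 65),
        ]
    )
    coding = CodingReport(
        cds=seq[10:31],
        protein="MKPGFT",
        has_premature_stop=null,
        has_frameshift=False,
        stop_codon_index=3 if null else 7,
    )
    return AnnotatedAllele(
        label="tiny",
        sequence=seq,
        locus="HLA-A",
        gene_model=model,
        closest=None,
        differences=[],
        coding=coding,
        allele_class=AlleleClass.NOVEL,
    )


class TestEmblWriter:
    def test_sixty_five_bp_sequence_block_layout(self):
        record = write_embl_flatfile(tiny_allele(), META)
        seq_lines = [l for l in record.splitlines() if l.startswith("     ") and l[5].islower()]
        assert len(seq_lines) == 2
        assert seq_lines[0].rstrip().endswith("60")
        assert seq_lines[1].rstrip().endswith("65")
        assert record.rstrip().endswith("//")
        assert "ID   XXX; XXX; linear; genomic DNA; XXX; XXX; 65 BP." in record

    def test_null_allele_gets_pseudo_and_no_translation(self):
        record = write_embl_flatfile(tiny_allele(null=True), META)
        assert "/pseudo" in record and "/translation" not in record
        coding = write_embl_flatfile(tiny_allele(), META)
        assert "/translation" in coding and "/pseudo" not in coding

    def test_record_reparses_to_same_model_and_sequence(self, annotated):
        ann, _ = annotated
        record = write_embl_flatfile(ann, META)
        db = parse_reference_flatfile(record)
        back = next(iter(db))
        assert back.sequence == ann.sequence
        assert back.gene_model.features == ann.gene_model.features

    def test_writers_are_deterministic(self, annotated):
        ann, _ = annotated
        assert write_embl_flatfile(ann, META) == write_embl_flatfile(ann, META)

    def test_missing_meta_field_rejected(self):
        bad = EnaRecordMeta("", "CL-1", "d", "HLA-A", "x")
        with pytest.raises(ValidationError, match="study_accession"):
            write_embl_flatfile(tiny_allele(), bad)


class TestConcatenate:
    def test_records_parse_in_order(self, annotated):
        ann, _ = annotated
        names = ["a_001", "b_002", "c_003"]
        records = []
        for n in names:
            m = EnaRecordMeta("PRJEB1", "CL-1", f"allele {n}", "HLA-A", n)
            records.append(write_embl_flatfile(ann, m))
        multi = concatenate_flatfiles(records)
        assert len(parse_reference_flatfile(multi)) == 3
        assert len(multi) == sum(len(r) for r in records)

    def test_empty_input_gives_empty_file(self):
        assert concatenate_flatfiles([]) == ""

    def test_unterminated_record_rejected(self):
        with pytest.raises(ValidationError, match="record 1"):
            concatenate_flatfiles(["ID   X\n"])


class TestEnaXml:
    def test_project_payload_embeds_fields(self):
        xml = write_ena_submission_xml(XmlKind.PROJECT, ProjectXmlMeta("ali", "Title", "Desc"))
        root = ET.fromstring(xml)
        assert root.tag == "PROJECT_SET"
        proj = root.find("PROJECT")
        assert proj.get("alias") == "ali"
        assert proj.findtext("TITLE") == "Title"
        assert proj.findtext("DESCRIPTION") == "Desc"

    def test_submission_payload_references_flatfile(self):
        xml = write_ena_submission_xml(
            XmlKind.SEQUENCE_SUBMISSION, SubmissionXmlMeta("ali", "batch.embl")
        )
        root = ET.fromstring(xml)
        add = root.find("ACTIONS/ACTION/ADD")
        assert add.get("source") == "batch.embl" and add.get("schema") == "flatfile"

    def test_missing_field_names_the_field(self):
        with pytest.raises(ValidationError, match="description"):
            write_ena_submission_xml(XmlKind.PROJECT, ProjectXmlMeta("a", "t", ""))

    def test_dry_run_transport_is_deterministic(self):
        t = DryRunTransport()
        assert t.submit_project("<x/>", "<y/>") == ("ERA000001", "PRJEB00001")
        assert t.submit_sequences("ID", "<y/>").startswith("ERA")
        assert [k for k, _ in t.sent] == ["project", "sequences"]


class TestGenotypeCsv:
    def test_two_sample_table(self):
        table = read_genotype_csv(GENO_CSV + "S2,03:01,11:01,44:02,51:01,04:01,13:02\n")
        assert set(table.rows) == {"S1", "S2"}
        assert table.rows["S1"]["HLA-A"] == ("01:01", "02:01")

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValidationError, match="duplicate sample_id"):
            read_genotype_csv(GENO_CSV + GENO_CSV.splitlines()[1] + "\n")

    def test_extra_kir_columns_retained(self):
        text = (
            "sample_id,HLA-A_1,HLA-A_2,KIR2DL1_1,KIR2DL1_2,comment\n"
            "S1,01:01,02:01,001,002,checked\n"
        )
        table = read_genotype_csv(text)
        assert table.rows["S1"]["KIR2DL1"] == ("001", "002")
        assert table.extra_columns["S1"]["comment"] == "checked"

    def test_missing_header_rejected(self):
        with pytest.raises(ValidationError, match="sample_id"):
            read_genotype_csv("id,HLA-A_1\nS1,01:01\n")

    @pytest.mark.parametrize(
        "drop, expect_missing",
        [
            ("HLA-DRB1_1", ["HLA-DRB1"]),
            ("HLA-B_2", ["HLA-B"]),
        ],
    )
    def test_missing_required_locus_fails(self, drop, expect_missing):
        header, row = GENO_CSV.strip().splitlines()
        cols = header.split(",")
        vals = row.split(",")
        vals[cols.index(drop)] = ""
        table = read_genotype_csv(header + "\n" + ",".join(vals) + "\n")
        verdict = validate_genotypes(table, "S1", "HLA-A")
        assert not verdict.passed
        assert verdict.missing == expect_missing

    def test_missing_partner_allele_fails(self):
        text = GENO_CSV.replace(",03:01\n", ",\n")  # drop HLA-DRB1_2? no: last col
        table = read_genotype_csv(text)
        verdict = validate_genotypes(table, "S1", "HLA-DRB1")
        assert not verdict.passed
        assert "HLA-DRB1 (second allele)" in verdict.missing

    def test_complete_row_passes(self):
        table = read_genotype_csv(GENO_CSV)
        verdict = validate_genotypes(table, "S1", "HLA-B")
        assert verdict.passed and verdict.missing == []

    def test_unknown_sample_is_error(self):
        with pytest.raises(ValidationError, match="S9"):
            validate_genotypes(read_genotype_csv(GENO_CSV), "S9", "HLA-A")


class TestAccessionAttachment:
    def test_three_line_attachment(self):
        text = "# assigned accessions\nA_001\tLR1\nA_002\tLR2\n\nA_003  LR3\n"
        mapping = parse_accession_attachment(text)
        assert mapping == {"A_001": "LR1", "A_002": "LR2", "A_003": "LR3"}

    def test_duplicate_name_rejected_with_line(self):
        with pytest.raises(ValidationError, match="line 2"):
            parse_accession_attachment("A\tLR1\nA\tLR2\n")

    def test_unsplittable_line_rejected_with_line(self):
        with pytest.raises(ValidationError, match="line 1"):
            parse_accession_attachment("justonefield\n")

    def test_empty_file_gives_empty_map(self):
        assert parse_accession_attachment("") == {}


class TestIpdDocument:
    def test_single_intronic_substitution_renders_one_line(self, synthetic_db):
        from alleleforge.fixtures import Edit, EditScript, apply_edit_script

        _, db, _ = synthetic_db
        ref = next(a for a in db if a.is_full_length)
        intron = ref.gene_model.introns[0]
        pos = (intron.start + intron.end) // 2
        new = "A" if ref.sequence[pos - 1] != "A" else "C"
        query = apply_edit_script(ref.sequence, EditScript([Edit("SUB", pos, new)]))
        ann = annotate_allele(("q", query), db)
        table = read_genotype_csv(GENO_CSV)
        doc = write_ipd_submission(ann, IPD_META, table, "S1")
        diff_lines = [
            l for l in doc.splitlines() if l.startswith(("intron", "exon", "5'UTR", "3'UTR"))
            and ">" in l
        ]
        assert len(diff_lines) == 1
        assert diff_lines[0].startswith("intron 1 position ")
        assert doc.count("count: 1") == 1

    def test_confirmatory_document_states_zero_differences(self, synthetic_db):
        _, db, _ = synthetic_db
        ref = next(a for a in db if a.is_full_length)
        ann = annotate_allele(("q", ref.sequence), db)
        doc = write_ipd_submission(ann, IPD_META, read_genotype_csv(GENO_CSV), "S1")
        assert "count: 0 (confirmatory" in doc
        assert "class: CONFIRMATORY" in doc

    def test_difference_block_reapplies_to_the_query(self, annotated):
        ann, ref = annotated
        doc = write_ipd_submission(ann, IPD_META, read_genotype_csv(GENO_CSV), "S1")
        assert reconstruct_query_from_ipd(doc, ref.sequence) == ann.sequence

    def test_missing_meta_field_rejected(self, annotated):
        ann, _ = annotated
        meta = IpdSubmissionMeta("SUB1", "CL-1", "ONT", "p", "500x", "")
        with pytest.raises(ValidationError, match="ena_accession"):
            write_ipd_submission(ann, meta, read_genotype_csv(GENO_CSV), "S1")


class TestPackaging:
    def test_zip_round_trip(self, tmp_path):
        files = []
        for name, payload in [("a.txt", b"alpha"), ("b.txt", b"beta")]:
            p = tmp_path / name
            p.write_bytes(payload)
            files.append(p)
        blob = package_submission(files)
        zf = zipfile.ZipFile(io.BytesIO(blob))
        assert zf.namelist() == ["a.txt", "b.txt"]
        assert zf.read("a.txt") == b"alpha" and zf.read("b.txt") == b"beta"
        assert package_submission(files) == blob  # deterministic

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            package_submission([])

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="missing"):
            package_submission([tmp_path / "nope.txt"])
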