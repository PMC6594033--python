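"""Workflow store: project/allele records, status machine, persistence."""

import itertools

import pytest

from alleleforge.fixtures import mutate_allele
from alleleforge.workdesk import (
    AlleleRecord,
    ENA_READY,
    IPD_TODO,
    StatusValue,
    Workdesk,
    WorkflowError,
)


@pytest.fixture
def desk(tmp_path):
    d = Workdesk(
        tmp_path / "store.sqlite",
        tmp_path / "data",
        user="lab",
        now=lambda: "2019-03-25T12:00:00",
    )
    yield d
    d.close()


@pytest.fixture(scope="module")
def query_fasta_factory(tmp_path_factory):
    """Writes mutated-query FASTA files derived from the session database."""
    base = tmp_path_factory.mktemp("fastas")
    counter = itertools.count()

    def make(db, *, seed, truncate_utr3=False):
        ref = next(a for a in db if a.is_full_length)
        res = mutate_allele(ref, seed=seed, sub_rate=0.004, n_indels=(0, 1))
        seq = res.query
        if truncate_utr3:
            seq = seq[: res.expected_model.features[-1].start - 1]
        path = base / f"q{next(counter)}.fasta"
        path.write_text(f">query seed={seed}\n{seq}\n")
        return path

    return make


class TestProjects:
    def test_project_id_pattern_and_counter(self, desk):
        first = desk.create_project("KIR novel alleles")
        second = desk.create_project("KIR novel alleles")  # same title, same day
        assert first.project_id == "lab_20190325_001"
        assert second.project_id == "lab_20190325_002"
        assert first.status == "OPEN"
        assert desk.project_dir(first.project_id).is_dir()

    def test_empty_title_rejected(self, desk):
        with pytest.raises(WorkflowError):
            desk.create_project("")


class TestAddAllele:
    def test_valid_allele_becomes_ena_ready_with_artifact(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        fasta = query_fasta_factory(db, seed=101)
        rec = desk.add_allele(p.project_id, fasta, "S1", db)
        assert rec.ena_status == ENA_READY
        assert rec.allele_status.category == "TODO"
        assert rec.local_name.endswith("_S1_001")
        artifact = rec.file_paths["ena_flatfile"]
        assert artifact and open(artifact).read().rstrip().endswith("//")

    def test_missing_utr_recorded_as_error(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        fasta = query_fasta_factory(db, seed=102, truncate_utr3=True)
        rec = desk.add_allele(p.project_id, fasta, "S1", db)
        assert rec.ena_status.category == "ERROR"
        assert rec.error_reason and "not full length" in rec.error_reason

    def test_same_file_twice_increments_counter(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        fasta = query_fasta_factory(db, seed=103)
        r1 = desk.add_allele(p.project_id, fasta, "S1", db)
        r2 = desk.add_allele(p.project_id, fasta, "S1", db)
        assert r1.local_name.endswith("_001") and r2.local_name.endswith("_002")

    def test_closed_project_rejects_ingestion(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        desk.set_project_status(p.project_id, "CLOSED")
        fasta = query_fasta_factory(db, seed=104)
        with pytest.raises(WorkflowError, match="CLOSED"):
            desk.add_allele(p.project_id, fasta, "S1", db)

    def test_bulk_add_isolates_failures_and_keeps_order(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        items = [(query_fasta_factory(db, seed=110 + i), f"S{i}") for i in range(4)]
        items.insert(2, (query_fasta_factory(db, seed=120, truncate_utr3=True), "SX"))
        records, summary = desk.bulk_add(p.project_id, items, db)
        assert summary == {"ok": 4, "error": 1}
        assert [r.sample_id for r in records] == ["S0", "S1", "SX", "S2", "S3"]
        assert records[2].ena_status.category == "ERROR"


def seed_allele(desk, project_id, name="HLA-A_S1_001"):
    """Insert a minimal ENA-ready allele record directly."""
    rec = AlleleRecord(
        allele_id=f"{project_id}:{name}",
        project_id=project_id,
        sample_id="S1",
        cell_line_id="CL-1",
        local_name=name,
        ena_status=ENA_READY,
        ipd_status=IPD_TODO,
        lab_status=StatusValue("FINISHED", "sequence finalised"),
    )
    desk._insert_allele(rec)
    return rec


class TestStatusMachine:
    def test_ena_happy_path(self, desk):
        p = desk.create_project("t")
        rec = seed_allele(desk, p.project_id)
        desk.mark_submission(p.project_id, [rec.local_name], "ENA")
        assert desk.get_allele(p.project_id, rec.local_name).ena_status.category == "PENDING"
        desk.record_accessions(p.project_id, {rec.local_name: "LR1"})
        after = desk.get_allele(p.project_id, rec.local_name)
        assert after.ena_status.category == "FINISHED"
        assert after.ena_accession == "LR1"

    def test_ipd_requires_ena_accession(self, desk):
        p = desk.create_project("t")
        rec = seed_allele(desk, p.project_id)
        with pytest.raises(WorkflowError, match="ENA"):
            desk.mark_submission(p.project_id, [rec.local_name], "IPD", genotypes_validated=True)

    def test_ipd_requires_genotype_validation(self, desk):
        p = desk.create_project("t")
        rec = seed_allele(desk, p.project_id)
        desk.mark_submission(p.project_id, [rec.local_name], "ENA")
        desk.record_accessions(p.project_id, {rec.local_name: "LR1"})
        with pytest.raises(WorkflowError, match="genotype"):
            desk.mark_submission(p.project_id, [rec.local_name], "IPD")

    def test_record_accessions_is_atomic(self, desk):
        p = desk.create_project("t")
        rec = seed_allele(desk, p.project_id)
        desk.mark_submission(p.project_id, [rec.local_name], "ENA")
        with pytest.raises(WorkflowError, match="ghost"):
            desk.record_accessions(p.project_id, {rec.local_name: "LR1", "ghost": "LR2"})
        assert desk.get_allele(p.project_id, rec.local_name).ena_accession is None

    def test_empty_accession_map_updates_nothing(self, desk):
        p = desk.create_project("t")
        assert desk.record_accessions(p.project_id, {}) == 0

    def test_ipd_finished_unreachable_without_ena_finished(self, tmp_path, synthetic_db):
        """Exhaustive exploration of the status machine.

        Every action sequence up to depth 5 is replayed on a fresh store;
        whenever IPD reaches FINISHED, the history must contain an ENA
        FINISHED state and a recorded accession first.
        """
        actions = ["mark_ena", "record_acc", "mark_ipd", "ipd_result", "retry"]

        def replay(sequence, idx):
            desk = Workdesk(
                ":memory:", tmp_path / "explore",
                user="lab", now=lambda: "2019-03-25T12:00:00",
            )
            p = desk.create_project("t")
            rec = seed_allele(desk, p.project_id)
            name = rec.local_name
            history = []
            for action in sequence:
                try:
                    if action == "mark_ena":
                        desk.mark_submission(p.project_id, [name], "ENA")
                    elif action == "record_acc":
                        desk.record_accessions(p.project_id, {name: "LR1"})
                    elif action == "mark_ipd":
                        desk.mark_submission(p.project_id, [name], "IPD", genotypes_validated=True)
                    elif action == "ipd_result":
                        desk.record_ipd_result(p.project_id, name, "HWS1", "HLA-A*99:01")
                    elif action == "retry":
                        desk.retry_allele(p.project_id, name)
                except WorkflowError:
                    pass
                cur = desk.get_allele(p.project_id, name)
                history.append(
                    (cur.ena_status.category, cur.ipd_status.category, cur.ena_accession)
                )
            desk.close()
            return history

        reached_ipd_finished = 0
        for idx, seq in enumerate(itertools.product(actions, repeat=5)):
            history = replay(seq, idx)
            for step, (ena, ipd, acc) in enumerate(history):
                if ipd == "FINISHED":
                    reached_ipd_finished += 1
                    assert ena == "FINISHED" and acc is not None
                    assert any(h[0] == "FINISHED" for h in history[: step + 1])
                    break
        assert reached_ipd_finished > 0  # the goal state is reachable at all


class TestPersistenceAndViews:
    def test_store_survives_close_and_reopen(self, tmp_path, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        store = tmp_path / "store.sqlite"
        desk = Workdesk(store, tmp_path / "data", user="lab", now=lambda: "2019-03-25T12:00:00")
        p = desk.create_project("t", description="d")
        rec = desk.add_allele(p.project_id, query_fasta_factory(db, seed=130), "S1", db)
        desk.close()

        desk2 = Workdesk(store, tmp_path / "data", user="lab")
        assert desk2.get_project(p.project_id) == p
        assert desk2.get_allele(p.project_id, rec.local_name) == rec
        desk2.close()

    def test_closed_projects_hidden_by_default(self, desk):
        a = desk.create_project("open one")
        b = desk.create_project("open two")
        c = desk.create_project("finished work")
        desk.set_project_status(c.project_id, "CLOSED")
        assert list(desk.list_view("projects")["project_id"]) == [a.project_id, b.project_id]
        assert len(desk.list_view("projects", include_closed=True)) == 3

    def test_filter_alleles_by_status(self, desk, synthetic_db, query_fasta_factory):
        _, db, _ = synthetic_db
        p = desk.create_project("t")
        desk.add_allele(p.project_id, query_fasta_factory(db, seed=140), "S1", db)
        desk.add_allele(p.project_id, query_fasta_factory(db, seed=141, truncate_utr3=True), "S2", db)
        errors = desk.list_view("alleles", filters={"ena_status_category": "ERROR"})
        assert len(errors) == 1 and errors.loc[0, "sample_id"] == "S2"

    def test_unknown_filter_column_rejected(self, desk):
        with pytest.raises(WorkflowError, match="unknown filter column"):
            desk.list_view("projects", filters={"nope": "x"})
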