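"""Persistent project/allele workflow store.

A single-file SQLite database tracks every processed allele — sample ids,
local names, closest reference, statuses, accession numbers, artifact
paths and per-step timestamps — so the package can serve as a minimal
LIMS for full-length allele submissions.

Statuses are per target with four categories (FINISHED, PENDING, TODO,
ERROR).  The transition machine: ENA goes TODO -> PENDING -> FINISHED
(accessions recorded), any state may drop to ERROR, ERROR may retry to
TODO; the IPD track is gated on ENA FINISHED and then follows
TODO -> PENDING -> FINISHED.  An allele can therefore never reach IPD
FINISHED without having passed ENA FINISHED.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotation import AnnotationConfig
from .differences import AnnotationRejected, annotate_allele
from .reference_db import ReferenceDatabase
from .submission_formats import EnaRecordMeta, write_embl_flatfile

__all__ = [
    "StatusValue",
    "ProjectRecord",
    "AlleleRecord",
    "Workdesk",
    "WorkflowError",
    "default_cell_line_id",
]


class WorkflowError(ValueError):
    """Illegal workflow operation; message names the current state."""


@dataclass(frozen=True)
class StatusValue:
    category: str  # FINISHED | PENDING | TODO | ERROR
    label: str

    def __post_init__(self) -> None:
        if self.category not in ("FINISHED", "PENDING", "TODO", "ERROR"):
            raise ValueError(f"unknown status category {self.category}")


ENA_READY = StatusValue("TODO", "ENA-ready")
ENA_PENDING = StatusValue("PENDING", "ENA submitted")
ENA_FINISHED = StatusValue("FINISHED", "ENA accession received")
IPD_TODO = StatusValue("TODO", "IPD not started")
IPD_PENDING = StatusValue("PENDING", "IPD submitted")
IPD_FINISHED = StatusValue("FINISHED", "IPD allele name received")


@dataclass
class ProjectRecord:
    project_id: str
    title: str
    description: str
    user: str
    status: str  # OPEN | CLOSED
    created_at: str
    ena_submission_id: str | None = None
    ena_project_accession: str | None = None


@dataclass
class AlleleRecord:
    allele_id: str
    project_id: str
    sample_id: str
    cell_line_id: str
    local_name: str
    ena_status: StatusValue
    ipd_status: StatusValue
    lab_status: StatusValue
    closest_reference: str | None = None
    identity: float | None = None
    is_null: bool | None = None
    allele_class: str | None = None
    ena_accession: str | None = None
    ipd_accession: str | None = None
    ipd_allele_name: str | None = None
    error_reason: str | None = None
    timestamps: dict[str, str] = field(default_factory=dict)
    file_paths: dict[str, str] = field(default_factory=dict)

    @property
    def allele_status(self) -> StatusValue:
        """Overall workflow state derived from the per-target statuses."""
        if "ERROR" in (self.ena_status.category, self.ipd_status.category):
            err = self.ena_status if self.ena_status.category == "ERROR" else self.ipd_status
            return err
        if self.ipd_status.category == "FINISHED":
            return StatusValue("FINISHED", "submission complete")
        if "PENDING" in (self.ena_status.category, self.ipd_status.category):
            return StatusValue("PENDING", "awaiting repository response")
        return StatusValue("TODO", "user action needed")


def default_cell_line_id(user: str, sample_id: str) -> str:
    """Deterministic cell-line identifier; overrideable at ingestion."""
    return f"{user.upper()}-CL-{sample_id}"


_SCHEMA = """
CREATE TABLE IF NOT EXISTS projects (
    project_id TEXT PRIMARY KEY,
    title TEXT NOT NULL,
    description TEXT,
    user TEXT NOT NULL,
    status TEXT NOT NULL DEFAULT 'OPEN',
    created_at TEXT NOT NULL,
    ena_submission_id TEXT,
    ena_project_accession TEXT
);
CREATE TABLE IF NOT EXISTS alleles (
    allele_id TEXT PRIMARY KEY,
    project_id TEXT NOT NULL REFERENCES projects(project_id),
    sample_id TEXT NOT NULL,
    cell_line_id TEXT NOT NULL,
    local_name TEXT NOT NULL,
    ena_status_category TEXT NOT NULL,
    ena_status_label TEXT NOT NULL,
    ipd_status_category TEXT NOT NULL,
    ipd_status_label TEXT NOT NULL,
    lab_status_category TEXT NOT NULL,
    lab_status_label TEXT NOT NULL,
    closest_reference TEXT,
    identity REAL,
    is_null INTEGER,
    allele_class TEXT,
    ena_accession TEXT,
    ipd_accession TEXT,
    ipd_allele_name TEXT,
    error_reason TEXT,
    timestamps TEXT NOT NULL DEFAULT '{}',
    file_paths TEXT NOT NULL DEFAULT '{}',
    UNIQUE (project_id, local_name)
);
"""

_PROJECT_COLUMNS = [
    "project_id", "title", "description", "user", "status", "created_at",
    "ena_submission_id", "ena_project_accession",
]
_ALLELE_COLUMNS = [
    "allele_id", "project_id", "sample_id", "cell_line_id", "local_name",
    "ena_status_category", "ena_status_label", "ipd_status_category",
    "ipd_status_label", "lab_status_category", "lab_status_label",
    "closest_reference", "identity", "is_null", "allele_class",
    "ena_accession", "ipd_accession", "ipd_allele_name", "error_reason",
]


class Workdesk:
    """The persistent workdesk: one SQLite file plus a data directory.

    ``now`` is injectable for reproducible tests; it must return an
    ISO-8601 timestamp string.
    """

    def __init__(
        self,
        store_path: str | os.PathLike,
        data_root: str | os.PathLike,
        user: str = "lab",
        now=None,
    ) -> None:
        self.store_path = str(store_path)
        self.data_root = Path(data_root)
        self.user = user
        self._now = now or (lambda: _dt.datetime.now().isoformat(timespec="seconds"))
        self.data_root.mkdir(parents=True, exist_ok=True)
        self.conn = sqlite3.connect(self.store_path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Workdesk":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- projects ----------------------------------------------------------

    def create_project(
        self, title: str, description: str = "", user: str | None = None,
        date: str | None = None,
    ) -> ProjectRecord:
        """Create and persist a project; id pattern ``<user>_<YYYYMMDD>_<NNN>``."""
        if not title:
            raise WorkflowError("project title must be non-empty")
        user = user or self.user
        date = date or self._now()[:10].replace("-", "")
        prefix = f"{user}_{date}_"
        cur = self.conn.execute(
            "SELECT project_id FROM projects WHERE project_id LIKE ?", (prefix + "%",)
        )
        counters = [
            int(row["project_id"].rsplit("_", 1)[1]) for row in cur.fetchall()
        ]
        project_id = f"{prefix}{(max(counters) + 1 if counters else 1):03d}"
        rec = ProjectRecord(
            project_id=project_id,
            title=title,
            description=description,
            user=user,
            status="OPEN",
            created_at=self._now(),
        )
        self.conn.execute(
            "INSERT INTO projects (project_id, title, description, user, status, created_at) "
            "VALUES (?, ?, ?, ?, ?, ?)",
            (rec.project_id, rec.title, rec.description, rec.user, rec.status, rec.created_at),
        )
        self.conn.commit()
        self.project_dir(project_id).mkdir(parents=True, exist_ok=True)
        return rec

    def project_dir(self, project_id: str) -> Path:
        return self.data_root / "projects" / project_id

    def get_project(self, project_id: str) -> ProjectRecord:
        row = self.conn.execute(
            "SELECT * FROM projects WHERE project_id = ?", (project_id,)
        ).fetchone()
        if row is None:
            raise WorkflowError(f"unknown project {project_id}")
        return ProjectRecord(**{k: row[k] for k in _PROJECT_COLUMNS})

    def set_project_status(self, project_id: str, status: str) -> ProjectRecord:
        if status not in ("OPEN", "CLOSED"):
            raise WorkflowError(f"invalid project status {status}")
        self.get_project(project_id)
        self.conn.execute(
            "UPDATE projects SET status = ? WHERE project_id = ?", (status, project_id)
        )
        self.conn.commit()
        return self.get_project(project_id)

    def set_project_ena_ids(
        self, project_id: str, submission_id: str, accession: str
    ) -> None:
        self.get_project(project_id)
        self.conn.execute(
            "UPDATE projects SET ena_submission_id = ?, ena_project_accession = ? "
            "WHERE project_id = ?",
            (submission_id, accession, project_id),
        )
        self.conn.commit()

    # -- alleles -----------------------------------------------------------

    def _row_to_allele(self, row: sqlite3.Row) -> AlleleRecord:
        return AlleleRecord(
            allele_id=row["allele_id"],
            project_id=row["project_id"],
            sample_id=row["sample_id"],
            cell_line_id=row["cell_line_id"],
            local_name=row["local_name"],
            ena_status=StatusValue(row["ena_status_category"], row["ena_status_label"]),
            ipd_status=StatusValue(row["ipd_status_category"], row["ipd_status_label"]),
            lab_status=StatusValue(row["lab_status_category"], row["lab_status_label"]),
            closest_reference=row["closest_reference"],
            identity=row["identity"],
            is_null=bool(row["is_null"]) if row["is_null"] is not None else None,
            allele_class=row["allele_class"],
            ena_accession=row["ena_accession"],
            ipd_accession=row["ipd_accession"],
            ipd_allele_name=row["ipd_allele_name"],
            error_reason=row["error_reason"],
            timestamps=json.loads(row["timestamps"]),
            file_paths=json.loads(row["file_paths"]),
        )

    def get_allele(self, project_id: str, local_name: str) -> AlleleRecord:
        row = self.conn.execute(
            "SELECT * FROM alleles WHERE project_id = ? AND local_name = ?",
            (project_id, local_name),
        ).fetchone()
        if row is None:
            raise WorkflowError(f"unknown allele {local_name} in project {project_id}")
        return self._row_to_allele(row)

    def project_alleles(self, project_id: str) -> list[AlleleRecord]:
        rows = self.conn.execute(
            "SELECT * FROM alleles WHERE project_id = ? ORDER BY allele_id", (project_id,)
        ).fetchall()
        return [self._row_to_allele(r) for r in rows]

    def _next_local_name(self, project_id: str, locus: str, sample_id: str) -> str:
        n = self.conn.execute(
            "SELECT COUNT(*) FROM alleles WHERE project_id = ?", (project_id,)
        ).fetchone()[0]
        return f"{locus}_{sample_id}_{n + 1:03d}"

    def add_allele(
        self,
        project_id: str,
        fasta_path: str | os.PathLike,
        sample_id: str,
        db: ReferenceDatabase,
        config: AnnotationConfig | None = None,
        cell_line_id: str | None = None,
    ) -> AlleleRecord:
        """Ingest one FASTA file: annotate, persist, write the ENA flatfile.

        A rejected sequence is persisted with ERROR status and the
        rejection reason; an unreadable file or closed project raises
        without persisting anything.
        """
        project = self.get_project(project_id)
        if project.status != "OPEN":
            raise WorkflowError(f"project {project_id} is CLOSED")
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise WorkflowError(f"{fasta_path}: no FASTA record found")
        cell_line = cell_line_id or default_cell_line_id(project.user, sample_id)
        try:
            annotated = annotate_allele(records[0], db, config)
        except AnnotationRejected as rej:
            local_name = self._next_local_name(project_id, "unknown", sample_id)
            rec = AlleleRecord(
                allele_id=f"{project_id}:{local_name}",
                project_id=project_id,
                sample_id=sample_id,
                cell_line_id=cell_line,
                local_name=local_name,
                ena_status=StatusValue("ERROR", rej.reason),
                ipd_status=IPD_TODO,
                lab_status=StatusValue("TODO", "lab review"),
                error_reason=str(rej),
                timestamps={"added": self._now()},
            )
            self._insert_allele(rec)
            return rec

        local_name = self._next_local_name(project_id, annotated.locus, sample_id)
        meta = EnaRecordMeta(
            study_accession=project.ena_project_accession or "XXX",
            sample_id=cell_line,
            description=(
                f"Homo sapiens {annotated.locus} gene for novel allele, "
                f"cell line {cell_line}"
            ),
            gene=annotated.locus,
            allele_local_name=local_name,
        )
        flatfile = write_embl_flatfile(annotated, meta)
        artifact = self.project_dir(project_id) / f"{local_name}.embl"
        artifact.parent.mkdir(parents=True, exist_ok=True)
        artifact.write_text(flatfile)
        rec = AlleleRecord(
            allele_id=f"{project_id}:{local_name}",
            project_id=project_id,
            sample_id=sample_id,
            cell_line_id=cell_line,
            local_name=local_name,
            ena_status=ENA_READY,
            ipd_status=IPD_TODO,
            lab_status=StatusValue("FINISHED", "sequence finalised"),
            closest_reference=annotated.closest_reference_name,
            identity=annotated.identity,
            is_null=annotated.is_null,
            allele_class=annotated.allele_class.value,
            timestamps={"added": self._now()},
            file_paths={"ena_flatfile": str(artifact)},
        )
        self._insert_allele(rec)
        return rec

    def _insert_allele(self, rec: AlleleRecord) -> None:
        self.conn.execute(
            f"INSERT INTO alleles ({', '.join(_ALLELE_COLUMNS)}, timestamps, file_paths) "
            f"VALUES ({', '.join('?' * (len(_ALLELE_COLUMNS) + 2))})",
            (
                rec.allele_id, rec.project_id, rec.sample_id, rec.cell_line_id,
                rec.local_name,
                rec.ena_status.category, rec.ena_status.label,
                rec.ipd_status.category, rec.ipd_status.label,
                rec.lab_status.category, rec.lab_status.label,
                rec.closest_reference, rec.identity,
                int(rec.is_null) if rec.is_null is not None else None,
                rec.allele_class, rec.ena_accession, rec.ipd_accession,
                rec.ipd_allele_name, rec.error_reason,
                json.dumps(rec.timestamps), json.dumps(rec.file_paths),
            ),
        )
        self.conn.commit()

    def bulk_add(
        self,
        project_id: str,
        items: list[tuple[str | os.PathLike, str]],
        db: ReferenceDatabase,
        config: AnnotationConfig | None = None,
    ) -> tuple[list[AlleleRecord], dict[str, int]]:
        """Add many (fasta_path, sample_id) pairs; one failure never aborts
        the batch.  Results keep input order; the summary counts outcomes."""
        self.get_project(project_id)  # closed projects rejected per item below
        results: list[AlleleRecord] = []
        summary = {"ok": 0, "error": 0}
        for fasta_path, sample_id in items:
            rec = self.add_allele(project_id, fasta_path, sample_id, db, config)
            results.append(rec)
            if rec.ena_status.category == "ERROR":
                summary["error"] += 1
            else:
                summary["ok"] += 1
        return results, summary

    # -- status workflow ---------------------------------------------------

    def _update_status(self, rec: AlleleRecord, target: str, status: StatusValue) -> None:
        col = "ena_status" if target == "ENA" else "ipd_status"
        self.conn.execute(
            f"UPDATE alleles SET {col}_category = ?, {col}_label = ?, timestamps = ? "
            "WHERE allele_id = ?",
            (
                status.category,
                status.label,
                json.dumps({**rec.timestamps, f"{target.lower()}_{status.category.lower()}": self._now()}),
                rec.allele_id,
            ),
        )

    def mark_submission(
        self,
        project_id: str,
        local_names: list[str],
        target: str,
        genotypes_validated: bool = False,
    ) -> list[AlleleRecord]:
        """Advance alleles to PENDING for a submission target.

        ENA requires the allele to be ENA-ready (TODO); IPD additionally
        requires a recorded ENA accession and passed genotype validation.
        """
        if target not in ("ENA", "IPD"):
            raise WorkflowError(f"unknown submission target {target}")
        records = [self.get_allele(project_id, n) for n in local_names]
        for rec in records:
            if target == "ENA":
                if rec.ena_status.category != "TODO":
                    raise WorkflowError(
                        f"{rec.local_name}: cannot submit to ENA from state "
                        f"{rec.ena_status.category}/{rec.ena_status.label}"
                    )
            else:
                if rec.ena_status.category != "FINISHED" or not rec.ena_accession:
                    raise WorkflowError(
                        f"{rec.local_name}: cannot submit to IPD without an ENA "
                        f"accession (ENA state {rec.ena_status.category})"
                    )
                if not genotypes_validated:
                    raise WorkflowError(
                        f"{rec.local_name}: genotype validation has not passed"
                    )
                if rec.ipd_status.category not in ("TODO",):
                    raise WorkflowError(
                        f"{rec.local_name}: cannot submit to IPD from state "
                        f"{rec.ipd_status.category}/{rec.ipd_status.label}"
                    )
        for rec in records:
            self._update_status(
                rec, target, ENA_PENDING if target == "ENA" else IPD_PENDING
            )
        self.conn.commit()
        return [self.get_allele(project_id, n) for n in local_names]

    def record_accessions(self, project_id: str, mapping: dict[str, str]) -> int:
        """Register ENA accessions; atomic (all names must match)."""
        known = {r.local_name: r for r in self.project_alleles(project_id)}
        unmatched = sorted(set(mapping) - set(known))
        if unmatched:
            raise WorkflowError(
                f"unknown local name(s) in accession map: {', '.join(unmatched)}"
            )
        for name in mapping:
            if known[name].ena_status.category != "PENDING":
                raise WorkflowError(
                    f"{name}: accession received but ENA state is "
                    f"{known[name].ena_status.category}, expected PENDING"
                )
        for name, acc in mapping.items():
            rec = known[name]
            self.conn.execute(
                "UPDATE alleles SET ena_accession = ? WHERE allele_id = ?",
                (acc, rec.allele_id),
            )
            self._update_status(rec, "ENA", ENA_FINISHED)
        self.conn.commit()
        return len(mapping)

    def record_ipd_result(
        self, project_id: str, local_name: str, ipd_accession: str, ipd_allele_name: str
    ) -> AlleleRecord:
        """Manually enter the IPD response (accession + official name)."""
        rec = self.get_allele(project_id, local_name)
        if rec.ipd_status.category != "PENDING":
            raise WorkflowError(
                f"{local_name}: IPD result entered but IPD state is "
                f"{rec.ipd_status.category}, expected PENDING"
            )
        self.conn.execute(
            "UPDATE alleles SET ipd_accession = ?, ipd_allele_name = ? WHERE allele_id = ?",
            (ipd_accession, ipd_allele_name, rec.allele_id),
        )
        self._update_status(rec, "IPD", IPD_FINISHED)
        self.conn.commit()
        return self.get_allele(project_id, local_name)

    def retry_allele(self, project_id: str, local_name: str) -> AlleleRecord:
        """ERROR -> TODO retry transition on the ENA track."""
        rec = self.get_allele(project_id, local_name)
        if rec.ena_status.category != "ERROR":
            raise WorkflowError(
                f"{local_name}: retry only applies to ERROR state, "
                f"current {rec.ena_status.category}"
            )
        self._update_status(rec, "ENA", ENA_READY)
        self.conn.commit()
        return self.get_allele(project_id, local_name)

    # -- views -------------------------------------------------------------

    def list_view(
        self,
        scope: str,
        filters: dict[str, str] | None = None,
        include_closed: bool = False,
        sort_by: str | None = None,
    ) -> pd.DataFrame:
        """Tabular overview of projects or alleles.

        CLOSED projects (and their alleles) are hidden unless
        ``include_closed`` is set; any column can be filtered on equality
        or used as the sort key.
        """
        if scope == "projects":
            df = pd.read_sql_query("SELECT * FROM projects ORDER BY project_id", self.conn)
            if not include_closed:
                df = df[df["status"] != "CLOSED"].reset_index(drop=True)
        elif scope == "alleles":
            df = pd.read_sql_query(
                "SELECT a.*, p.status AS project_status FROM alleles a "
                "JOIN projects p ON a.project_id = p.project_id ORDER BY a.allele_id",
                self.conn,
            )
            if not include_closed:
                df = df[df["project_status"] != "CLOSED"].reset_index(drop=True)
            df = df.drop(columns=["timestamps", "file_paths"])
        else:
            raise WorkflowError(f"unknown scope {scope!r}")
        for col, value in (filters or {}).items():
            if col not in df.columns:
                raise WorkflowError(f"unknown filter column {col!r}")
            df = df[df[col].astype(str) == str(value)].reset_index(drop=True)
        if sort_by is not None:
            if sort_by not in df.columns:
                raise WorkflowError(f"unknown sort column {sort_by!r}")
            df = df.sort_values(sort_by).reset_index(drop=True)
        return df
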