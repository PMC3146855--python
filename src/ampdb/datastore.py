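"""Embedded relational store for multi-dataset amplicon surveys.

The schema mirrors the two static relations (``data_upload_summary`` and
``statistics``) plus the seven per-dataset relations (sample info,
primer/barcode info, raw reads, redundant per-sample trimmed reads, pooled
non-redundant set, per-sample non-redundant sets, and the pooled-to-sample
frequency link table).  Instead of creating tables at runtime per dataset,
every per-dataset relation carries a ``dataset_id`` foreign key with
``ON DELETE CASCADE`` — identical semantics, static auditable schema.

Uploads are atomic: the pipeline runs first and a single transaction
persists all relations, so a failing upload leaves the store untouched.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import sqlite3
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .formats import PrimerBarcodeSpec, RawRead, SampleInfo, StepLog, coerce_value
from .pipeline import PipelineConfig, PipelineResult, dereplicate, run_pipeline

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE IF NOT EXISTS schema_version (
    version INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS data_upload_summary (
    dataset_id INTEGER PRIMARY KEY AUTOINCREMENT,
    name TEXT NOT NULL,
    uploaded_at TEXT NOT NULL,
    parameters TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS statistics (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    step_order INTEGER NOT NULL,
    step_name TEXT NOT NULL,
    n_in INTEGER NOT NULL,
    n_kept INTEGER NOT NULL,
    n_discarded INTEGER NOT NULL,
    parameters TEXT NOT NULL,
    PRIMARY KEY (dataset_id, step_order)
);
CREATE TABLE IF NOT EXISTS step_discards (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    step_name TEXT NOT NULL,
    read_id TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS sample_info (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    sample_id TEXT NOT NULL,
    variable TEXT NOT NULL,
    value_num REAL,
    value_text TEXT,
    PRIMARY KEY (dataset_id, sample_id, variable)
);
CREATE TABLE IF NOT EXISTS primer_barcode_info (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    amplicon_id TEXT NOT NULL,
    sample_id TEXT NOT NULL,
    barcode TEXT NOT NULL,
    forward_primer TEXT NOT NULL,
    reverse_primer TEXT NOT NULL,
    adapter_b TEXT NOT NULL,
    min_len INTEGER NOT NULL,
    max_len INTEGER NOT NULL,
    PRIMARY KEY (dataset_id, amplicon_id, sample_id)
);
CREATE TABLE IF NOT EXISTS raw_reads (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    ordinal INTEGER NOT NULL,
    read_id TEXT NOT NULL,
    sequence TEXT NOT NULL,
    qualities TEXT NOT NULL,
    PRIMARY KEY (dataset_id, read_id)
);
CREATE TABLE IF NOT EXISTS redundant_reads (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    read_id TEXT NOT NULL,
    sample_id TEXT NOT NULL,
    amplicon_id TEXT,
    sequence TEXT NOT NULL,
    qualities TEXT NOT NULL,
    PRIMARY KEY (dataset_id, read_id)
);
CREATE TABLE IF NOT EXISTS nonredundant_pooled (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    rank INTEGER NOT NULL,
    sequence TEXT NOT NULL,
    frequency INTEGER NOT NULL,
    amplicon_id TEXT,
    assigned_path TEXT,
    edited_path TEXT,
    edited_by TEXT,
    edited_at TEXT,
    PRIMARY KEY (dataset_id, rank)
);
CREATE TABLE IF NOT EXISTS nonredundant_sample (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    sample_id TEXT NOT NULL,
    sample_rank INTEGER NOT NULL,
    pooled_rank INTEGER NOT NULL,
    sequence TEXT NOT NULL,
    frequency INTEGER NOT NULL,
    amplicon_id TEXT,
    PRIMARY KEY (dataset_id, sample_id, sample_rank),
    FOREIGN KEY (dataset_id, pooled_rank)
        REFERENCES nonredundant_pooled(dataset_id, rank)
);
CREATE TABLE IF NOT EXISTS nonredundant_pooled2sample (
    dataset_id INTEGER NOT NULL REFERENCES data_upload_summary(dataset_id) ON DELETE CASCADE,
    pooled_rank INTEGER NOT NULL,
    sample_id TEXT NOT NULL,
    frequency INTEGER NOT NULL,
    PRIMARY KEY (dataset_id, pooled_rank, sample_id),
    FOREIGN KEY (dataset_id, pooled_rank)
        REFERENCES nonredundant_pooled(dataset_id, rank)
);
"""


class DatastoreError(ValueError):
    """Unknown dataset/sample/sequence or a consistency violation."""


def _config_to_json(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    d["disabled_steps"] = sorted(d["disabled_steps"])
    d["step_order"] = list(d["step_order"])
    return json.dumps(d, sort_keys=True)


def config_from_json(text: str) -> PipelineConfig:
    d = json.loads(text)
    d["disabled_steps"] = frozenset(d["disabled_steps"])
    d["step_order"] = tuple(d["step_order"])
    return PipelineConfig(**d)


class Datastore:
    """Single-file embedded store.  Use ``:memory:`` for throwaway stores."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        cur = self._conn.execute("SELECT version FROM schema_version")
        row = cur.fetchone()
        if row is None:
            with self._conn:
                self._conn.execute(
                    "INSERT INTO schema_version (version) VALUES (?)", (SCHEMA_VERSION,)
                )
        elif row[0] != SCHEMA_VERSION:
            raise DatastoreError(
                f"database schema version {row[0]} != supported {SCHEMA_VERSION}"
            )

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- helpers -----------------------------------------------------------

    def _require_dataset(self, dataset_id: int) -> None:
        cur = self._conn.execute(
            "SELECT 1 FROM data_upload_summary WHERE dataset_id = ?", (dataset_id,)
        )
        if cur.fetchone() is None:
            raise DatastoreError(f"unknown dataset {dataset_id}")

    def dataset_ids(self) -> list[int]:
        cur = self._conn.execute(
            "SELECT dataset_id FROM data_upload_summary ORDER BY dataset_id"
        )
        return [r[0] for r in cur.fetchall()]

    def dataset_name(self, dataset_id: int) -> str:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT name FROM data_upload_summary WHERE dataset_id = ?", (dataset_id,)
        )
        return cur.fetchone()[0]

    # -- upload ------------------------------------------------------------

    def upload_dataset(
        self,
        raw_reads: Sequence[RawRead],
        specs: Sequence[PrimerBarcodeSpec],
        sample_info: Sequence[SampleInfo],
        config: PipelineConfig,
        name: str,
    ) -> int:
        """Run the pipeline and persist all per-dataset relations atomically.

        A pipeline hard error propagates before anything is written.
        """
        result = run_pipeline(raw_reads, specs, sample_info, config)
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO data_upload_summary (name, uploaded_at, parameters) "
                "VALUES (?, ?, ?)",
                (
                    name,
                    datetime.datetime.now().isoformat(timespec="seconds"),
                    _config_to_json(config),
                ),
            )
            dataset_id = cur.lastrowid
            self._insert_dataset_rows(dataset_id, raw_reads, specs, sample_info, result)
        return dataset_id

    def _insert_dataset_rows(
        self,
        dataset_id: int,
        raw_reads: Sequence[RawRead],
        specs: Sequence[PrimerBarcodeSpec],
        sample_info: Sequence[SampleInfo],
        result: PipelineResult,
    ) -> None:
        conn = self._conn
        for order, log in enumerate(result.step_logs, start=1):
            conn.execute(
                "INSERT INTO statistics VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    dataset_id,
                    order,
                    log.step_name,
                    log.n_in,
                    log.n_kept,
                    log.n_discarded,
                    json.dumps(log.parameters, sort_keys=True, default=str),
                ),
            )
            conn.executemany(
                "INSERT INTO step_discards VALUES (?, ?, ?)",
                [(dataset_id, log.step_name, rid) for rid in log.discarded_ids],
            )
        for s in sample_info:
            for variable, value in s.variables.items():
                num = value if isinstance(value, (int, float)) else None
                text = None if num is not None else str(value)
                conn.execute(
                    "INSERT INTO sample_info VALUES (?, ?, ?, ?, ?)",
                    (dataset_id, s.sample_id, variable, num, text),
                )
        for spec in specs:
            for sample_id, barcode in spec.barcode_map.items():
                conn.execute(
                    "INSERT INTO primer_barcode_info VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (
                        dataset_id,
                        spec.amplicon_id,
                        sample_id,
                        barcode,
                        spec.forward_primer,
                        spec.reverse_primer,
                        spec.adapter_b,
                        spec.min_len,
                        spec.max_len,
                    ),
                )
        conn.executemany(
            "INSERT INTO raw_reads VALUES (?, ?, ?, ?, ?)",
            [
                (dataset_id, i, r.read_id, r.sequence, " ".join(map(str, r.qualities)))
                for i, r in enumerate(raw_reads)
            ],
        )
        conn.executemany(
            "INSERT INTO redundant_reads VALUES (?, ?, ?, ?, ?, ?)",
            [
                (
                    dataset_id,
                    r.read_id,
                    r.sample_id or "unassigned",
                    r.amplicon_id,
                    r.sequence,
                    " ".join(map(str, r.qualities)),
                )
                for r in result.processed_reads
            ],
        )
        rank_of: dict[str, int] = {}
        for u in result.unique_sequences:
            rank_of[u.sequence] = u.rank
            conn.execute(
                "INSERT INTO nonredundant_pooled "
                "(dataset_id, rank, sequence, frequency, amplicon_id) "
                "VALUES (?, ?, ?, ?, ?)",
                (dataset_id, u.rank, u.sequence, u.pooled_frequency, u.amplicon_id),
            )
            conn.executemany(
                "INSERT INTO nonredundant_pooled2sample VALUES (?, ?, ?, ?)",
                [
                    (dataset_id, u.rank, sample_id, freq)
                    for sample_id, freq in u.per_sample_frequency.items()
                ],
            )
        # per-sample non-redundant sets, ranked within each sample
        by_sample: dict[str, list] = defaultdict(list)
        for r in result.processed_reads:
            by_sample[r.sample_id or "unassigned"].append(r)
        for sample_id, reads in by_sample.items():
            for u in dereplicate(reads):
                conn.execute(
                    "INSERT INTO nonredundant_sample VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (
                        dataset_id,
                        sample_id,
                        u.rank,
                        rank_of[u.sequence],
                        u.sequence,
                        u.pooled_frequency,
                        u.amplicon_id,
                    ),
                )

    # -- deletion ----------------------------------------------------------

    def delete_dataset(self, dataset_id: int) -> None:
        """Remove the dataset and all of its rows (cascading)."""
        self._require_dataset(dataset_id)
        with self._conn:
            self._conn.execute(
                "DELETE FROM data_upload_summary WHERE dataset_id = ?", (dataset_id,)
            )

    # -- retrieval ---------------------------------------------------------

    def get_raw_reads(self, dataset_id: int) -> list[RawRead]:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT read_id, sequence, qualities FROM raw_reads "
            "WHERE dataset_id = ? ORDER BY ordinal",
            (dataset_id,),
        )
        return [
            RawRead(rid, seq, [int(q) for q in quals.split()])
            for rid, seq, quals in cur.fetchall()
        ]

    def get_specs(self, dataset_id: int) -> list[PrimerBarcodeSpec]:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT amplicon_id, sample_id, barcode, forward_primer, reverse_primer, "
            "adapter_b, min_len, max_len FROM primer_barcode_info "
            "WHERE dataset_id = ? ORDER BY amplicon_id, sample_id",
            (dataset_id,),
        )
        specs: dict[str, PrimerBarcodeSpec] = {}
        for amp, sample, barcode, fwd, rev, adapter, lo, hi in cur.fetchall():
            spec = specs.setdefault(
                amp, PrimerBarcodeSpec(amp, fwd, rev, adapter, lo, hi, {})
            )
            spec.barcode_map[sample] = barcode
        return list(specs.values())

    def get_sample_info(self, dataset_id: int) -> list[SampleInfo]:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT sample_id, variable, value_num, value_text FROM sample_info "
            "WHERE dataset_id = ? ORDER BY sample_id, variable",
            (dataset_id,),
        )
        samples: dict[str, SampleInfo] = {}
        for sample_id, variable, num, text in cur.fetchall():
            info = samples.setdefault(sample_id, SampleInfo(sample_id, {}))
            if num is not None:
                info.variables[variable] = int(num) if num == int(num) else num
            else:
                info.variables[variable] = text
        return list(samples.values())

    def get_config(self, dataset_id: int) -> PipelineConfig:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT parameters FROM data_upload_summary WHERE dataset_id = ?",
            (dataset_id,),
        )
        return config_from_json(cur.fetchone()[0])

    def get_step_logs(self, dataset_id: int) -> list[StepLog]:
        """Rebuild the per-step logs from the statistics and discard rows."""
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT step_name, n_in, n_kept, n_discarded, parameters FROM statistics "
            "WHERE dataset_id = ? ORDER BY step_order",
            (dataset_id,),
        )
        logs = []
        for step_name, n_in, n_kept, n_disc, params in cur.fetchall():
            ids = [
                r[0]
                for r in self._conn.execute(
                    "SELECT read_id FROM step_discards "
                    "WHERE dataset_id = ? AND step_name = ?",
                    (dataset_id, step_name),
                )
            ]
            log = StepLog(step_name, n_in, n_kept, n_disc, ids, json.loads(params))
            log.validate()
            logs.append(log)
        return logs

    def get_pooled_sequences(self, dataset_id: int) -> list[tuple[int, str, int]]:
        """(rank, sequence, frequency) rows of the pooled non-redundant set."""
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT rank, sequence, frequency FROM nonredundant_pooled "
            "WHERE dataset_id = ? ORDER BY rank",
            (dataset_id,),
        )
        return cur.fetchall()

    # -- re-processing -----------------------------------------------------

    def combine_and_reprocess(
        self,
        dataset_ids: Sequence[int],
        specs: Sequence[PrimerBarcodeSpec] | None,
        config: PipelineConfig,
        name: str,
        sample_info: Sequence[SampleInfo] | None = None,
    ) -> int:
        """Pool the raw reads of several datasets and re-run the pipeline.

        Read identifiers are disambiguated with a ``d<dataset_id>:`` prefix.
        Source datasets are left untouched; the result is a new dataset.
        Specs and sample info default to those of the source datasets
        (first dataset wins on conflicts).
        """
        if not dataset_ids:
            raise DatastoreError("no datasets given to combine")
        for dsid in dataset_ids:
            self._require_dataset(dsid)
        pooled_reads: list[RawRead] = []
        for pos, dsid in enumerate(dataset_ids, start=1):
            # positional prefix keeps ids unique even when a dataset is
            # listed more than once
            for r in self.get_raw_reads(dsid):
                pooled_reads.append(
                    RawRead(f"p{pos}.d{dsid}:{r.read_id}", r.sequence, r.qualities)
                )
        if specs is None:
            specs = self.get_specs(dataset_ids[0])
        if sample_info is None:
            merged: dict[str, SampleInfo] = {}
            for dsid in dataset_ids:
                for s in self.get_sample_info(dsid):
                    merged.setdefault(s.sample_id, s)
            sample_info = list(merged.values())
        return self.upload_dataset(pooled_reads, specs, sample_info, config, name)

    # -- editing -----------------------------------------------------------

    def update_sample_info(
        self, dataset_id: int, sample_id: str, variable: str, value
    ) -> None:
        """Upsert one metadata variable; ``value=None`` deletes it."""
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT 1 FROM sample_info WHERE dataset_id = ? AND sample_id = ? LIMIT 1",
            (dataset_id, sample_id),
        )
        known = cur.fetchone() is not None
        if not known:
            cur = self._conn.execute(
                "SELECT 1 FROM primer_barcode_info "
                "WHERE dataset_id = ? AND sample_id = ? LIMIT 1",
                (dataset_id, sample_id),
            )
            known = cur.fetchone() is not None
        if not known:
            raise DatastoreError(f"unknown sample {sample_id!r} in dataset {dataset_id}")
        with self._conn:
            if value is None:
                self._conn.execute(
                    "DELETE FROM sample_info "
                    "WHERE dataset_id = ? AND sample_id = ? AND variable = ?",
                    (dataset_id, sample_id, variable),
                )
                return
            if isinstance(value, str):
                value = coerce_value(value)
            num = value if isinstance(value, (int, float)) else None
            text = None if num is not None else str(value)
            self._conn.execute(
                "INSERT INTO sample_info VALUES (?, ?, ?, ?, ?) "
                "ON CONFLICT(dataset_id, sample_id, variable) "
                "DO UPDATE SET value_num = excluded.value_num, "
                "value_text = excluded.value_text",
                (dataset_id, sample_id, variable, num, text),
            )

    def set_assigned_taxonomy(self, dataset_id: int, rank: int, path: str) -> None:
        """Record/overwrite the automatic assignment; never touches edits."""
        self._require_dataset(dataset_id)
        with self._conn:
            cur = self._conn.execute(
                "UPDATE nonredundant_pooled SET assigned_path = ? "
                "WHERE dataset_id = ? AND rank = ?",
                (path, dataset_id, rank),
            )
        if cur.rowcount == 0:
            raise DatastoreError(f"unknown sequence rank {rank} in dataset {dataset_id}")

    def set_edited_taxonomy(
        self, dataset_id: int, rank: int, new_path: str, editor: str
    ) -> None:
        """Store a manual path in its own column, preserving the automatic one."""
        self._require_dataset(dataset_id)
        with self._conn:
            cur = self._conn.execute(
                "UPDATE nonredundant_pooled "
                "SET edited_path = ?, edited_by = ?, edited_at = ? "
                "WHERE dataset_id = ? AND rank = ?",
                (
                    new_path,
                    editor,
                    datetime.datetime.now().isoformat(timespec="seconds"),
                    dataset_id,
                    rank,
                ),
            )
        if cur.rowcount == 0:
            raise DatastoreError(f"unknown sequence rank {rank} in dataset {dataset_id}")

    def get_taxonomy(self, dataset_id: int, rank: int) -> dict:
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT assigned_path, edited_path, edited_by, edited_at "
            "FROM nonredundant_pooled WHERE dataset_id = ? AND rank = ?",
            (dataset_id, rank),
        )
        row = cur.fetchone()
        if row is None:
            raise DatastoreError(f"unknown sequence rank {rank} in dataset {dataset_id}")
        return dict(
            zip(("assigned_path", "edited_path", "edited_by", "edited_at"), row)
        )

    # -- reporting ---------------------------------------------------------

    def summary_statistics(self, dataset_id: int) -> dict:
        """Per-step counts plus totals, in pipeline execution order."""
        self._require_dataset(dataset_id)
        cur = self._conn.execute(
            "SELECT step_order, step_name, n_in, n_kept, n_discarded FROM statistics "
            "WHERE dataset_id = ? ORDER BY step_order",
            (dataset_id,),
        )
        steps = [
            dict(order=o, step=s, n_in=a, n_kept=k, n_discarded=d)
            for o, s, a, k, d in cur.fetchall()
        ]
        total_in = steps[0]["n_in"] if steps else 0
        retained = steps[-1]["n_kept"] if steps else 0
        return dict(
            dataset_id=dataset_id,
            steps=steps,
            total_in=total_in,
            total_retained=retained,
            total_discarded=sum(s["n_discarded"] for s in steps),
        )

    # -- auditing ----------------------------------------------------------

    def row_counts(self) -> dict[str, int]:
        tables = (
            "data_upload_summary",
            "statistics",
            "step_discards",
            "sample_info",
            "primer_barcode_info",
            "raw_reads",
            "redundant_reads",
            "nonredundant_pooled",
            "nonredundant_sample",
            "nonredundant_pooled2sample",
        )
        return {
            t: self._conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in tables
        }

    def integrity_check(self) -> list[str]:
        """Foreign-key audit plus frequency-reconciliation checks.

        Returns a list of violation descriptions (empty when consistent).
        """
        problems = [
            f"foreign key violation in {row[0]}"
            for row in self._conn.execute("PRAGMA foreign_key_check")
        ]
        cur = self._conn.execute(
            "SELECT p.dataset_id, p.rank, p.frequency, COALESCE(SUM(l.frequency), 0) "
            "FROM nonredundant_pooled p "
            "LEFT JOIN nonredundant_pooled2sample l "
            "ON l.dataset_id = p.dataset_id AND l.pooled_rank = p.rank "
            "GROUP BY p.dataset_id, p.rank"
        )
        for dsid, rank, freq, linked in cur.fetchall():
            if freq != linked:
                problems.append(
                    f"dataset {dsid} rank {rank}: pooled frequency {freq} "
                    f"!= sum of link rows {linked}"
                )
        cur = self._conn.execute(
            "SELECT s.dataset_id, s.pooled_rank, s.sample_id, s.frequency, l.frequency "
            "FROM nonredundant_sample s "
            "LEFT JOIN nonredundant_pooled2sample l "
            "ON l.dataset_id = s.dataset_id AND l.pooled_rank = s.pooled_rank "
            "AND l.sample_id = s.sample_id"
        )
        for dsid, rank, sample, sfreq, lfreq in cur.fetchall():
            if sfreq != lfreq:
                problems.append(
                    f"dataset {dsid} rank {rank} sample {sample}: per-sample "
                    f"frequency {sfreq} != link frequency {lfreq}"
                )
        return problems
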