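"""Six-axis retrieval over the datastore, plus abundance and export.

Filter axes (datasets, amplicons/primers, samples, metadata ranges, taxon
substring, random subsample size) combine by conjunction.  Metadata range
bounds are inclusive; categorical variables filter by equality.  The taxon
filter matches case-insensitively against the edited path when present,
otherwise the automatically assigned path.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import IO, NamedTuple, Sequence, Union

from .datastore import Datastore
from .formats import _writer  # shared path-or-handle plumbing


class QueryError(ValueError):
    pass


class ResultRow(NamedTuple):
    dataset_id: int
    sample_id: str
    sequence: str
    frequency: int
    taxonomy: str | None


@dataclass(frozen=True)
class QueryFilter:
    """One retrieval request.  Empty axes mean "no restriction".

    ``variable_ranges`` entries are ``(name, lo, hi)`` for numeric variables
    (inclusive bounds) or ``(name, value)`` for categorical equality.
    """

    dataset_ids: tuple[int, ...] = ()
    primer_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()
    variable_ranges: tuple[tuple, ...] = ()
    taxon_substring: str | None = None

    def __post_init__(self):
        for entry in self.variable_ranges:
            if len(entry) == 3:
                _, lo, hi = entry
                if lo > hi:
                    raise QueryError(f"range {lo}..{hi} has min > max")
            elif len(entry) != 2:
                raise QueryError(f"bad variable filter {entry!r}")


def _sample_values(store: Datastore, dataset_ids: Sequence[int]):
    values: dict[tuple[int, str, str], tuple] = {}
    for dsid in dataset_ids:
        cur = store._conn.execute(
            "SELECT sample_id, variable, value_num, value_text FROM sample_info "
            "WHERE dataset_id = ?",
            (dsid,),
        )
        for sample_id, variable, num, text in cur.fetchall():
            values[(dsid, sample_id, variable)] = (num, text)
    return values


def select_sequences(store: Datastore, flt: QueryFilter = QueryFilter()) -> list[ResultRow]:
    """All per-sample non-redundant rows satisfying every filter axis.

    Rows are ordered deterministically by (dataset, frequency desc, sequence,
    sample).  A numeric range applied to a categorical variable is an error.
    """
    dataset_ids = list(flt.dataset_ids) if flt.dataset_ids else store.dataset_ids()
    meta = _sample_values(store, dataset_ids)

    rows: list[ResultRow] = []
    for dsid in dataset_ids:
        store._require_dataset(dsid)
        cur = store._conn.execute(
            "SELECT ns.sample_id, ns.sequence, ns.frequency, ns.amplicon_id, "
            "np.assigned_path, np.edited_path "
            "FROM nonredundant_sample ns "
            "JOIN nonredundant_pooled np "
            "ON np.dataset_id = ns.dataset_id AND np.rank = ns.pooled_rank "
            "WHERE ns.dataset_id = ?",
            (dsid,),
        )
        for sample_id, sequence, freq, amplicon, assigned, edited in cur.fetchall():
            if flt.sample_ids and sample_id not in flt.sample_ids:
                continue
            if flt.primer_ids and amplicon not in flt.primer_ids:
                continue
            ok = True
            for entry in flt.variable_ranges:
                name = entry[0]
                value = meta.get((dsid, sample_id, name))
                if value is None:
                    ok = False
                    break
                num, text = value
                if len(entry) == 3:
                    if num is None:
                        raise QueryError(
                            f"range filter on categorical variable {name!r}"
                        )
                    if not (entry[1] <= num <= entry[2]):
                        ok = False
                        break
                else:
                    stored = text if num is None else num
                    if str(stored) != str(entry[1]):
                        ok = False
                        break
            if not ok:
                continue
            effective = edited if edited is not None else assigned
            if flt.taxon_substring is not None:
                if effective is None or flt.taxon_substring.lower() not in effective.lower():
                    continue
            rows.append(ResultRow(dsid, sample_id, sequence, freq, effective))
    rows.sort(key=lambda r: (r.dataset_id, -r.frequency, r.sequence, r.sample_id))
    return rows


def random_subsample(
    store: Datastore, flt: QueryFilter, n: int, seed: int
) -> list[ResultRow]:
    """Draw ``n`` reads without replacement from the frequency-expanded pool.

    The same seed reproduces the same draw; asking for more reads than the
    pool holds is an explicit error, never a silent truncation.
    """
    if n < 0:
        raise QueryError("sample size must be >= 0")
    rows = select_sequences(store, flt)
    pool: list[ResultRow] = []
    for row in rows:
        pool.extend([row._replace(frequency=1)] * row.frequency)
    if n > len(pool):
        raise QueryError(f"requested {n} reads but the filtered pool holds {len(pool)}")
    rng = random.Random(seed)
    return [pool[i] for i in sorted(rng.sample(range(len(pool)), n))]


def sequence_abundance(
    store: Datastore, query_sequence: str, flt: QueryFilter = QueryFilter()
) -> dict[tuple[int, str], int]:
    """Per-(dataset, sample) copy numbers of one exact sequence string."""
    return {
        (row.dataset_id, row.sample_id): row.frequency
        for row in select_sequences(store, flt)
        if row.sequence == query_sequence
    }


TSV_COLUMNS = ("dataset_id", "sample_id", "sequence", "frequency", "taxonomy")


def export_results(rows: Sequence[ResultRow], fmt: str, sink: Union[str, IO[str]]) -> None:
    """Write a selection as frequency-header FASTA or a five-column TSV.

    Output is byte-stable for a fixed selection.
    """
    if fmt not in ("fasta", "tsv"):
        raise QueryError(f"unknown export format {fmt!r}")
    fh, close = _writer(sink)
    try:
        if fmt == "fasta":
            for i, row in enumerate(rows, start=1):
                fh.write(f">seq{i}_freq={row.frequency}\n{row.sequence}\n")
        else:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for row in rows:
                fh.write(
                    "\t".join(
                        [
                            str(row.dataset_id),
                            row.sample_id,
                            row.sequence,
                            str(row.frequency),
                            row.taxonomy or "",
                        ]
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()
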