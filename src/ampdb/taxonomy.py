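"""Closest-hit taxonomic path assignment from precomputed similarity hits.

The similarity search itself (e.g. BLAST against NCBI nt) is an external
tool; this module consumes its standard 12-column tabular output plus a
two-column subject-to-lineage map and emits the three-column report
(query id, query sequence, taxonomic path of the closest hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence, Union

from .formats import FormatError, _reader, _writer

NO_HIT = "no_hit"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def validate(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise FormatError(f"identity {self.identity} outside [0, 100]")
        if self.evalue < 0:
            raise FormatError(f"negative e-value {self.evalue}")


def parse_hit_file(source: Union[str, IO[str]]) -> list[HitRecord]:
    """Parse 12-column tabular hit output (qid, sid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore)."""
    fh, close = _reader(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    hits: list[HitRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise FormatError(f"hit file line {lineno}: expected 12 columns, got {len(cols)}")
        try:
            hit = HitRecord(
                query_id=cols[0],
                subject_id=cols[1],
                identity=float(cols[2]),
                alignment_length=int(cols[3]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]),
            )
            hit.validate()
        except ValueError as exc:
            raise FormatError(f"hit file line {lineno}: {exc}") from None
        hits.append(hit)
    return hits


def parse_lineage_map(source: Union[str, IO[str]]) -> dict[str, str]:
    """Parse the two-column subject_id -> taxonomic path TSV."""
    fh, close = _reader(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    out: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[1]:
            raise FormatError(f"lineage map line {lineno}: expected subject<TAB>path")
        out[cols[0]] = cols[1]
    return out


def best_hit(hits: Sequence[HitRecord]) -> HitRecord | None:
    """Lowest e-value wins; ties go to the highest bit score, then to the
    lexicographically smallest subject id (order-independent)."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def assign_taxonomic_path(
    hits: Iterable[HitRecord],
    lineage_map: Mapping[str, str],
    queries: Mapping[str, str],
    min_identity: float | None = None,
    max_evalue: float | None = None,
) -> list[tuple[str, str, str]]:
    """Per query, the path of its best hit; ``no_hit`` when none qualifies.

    ``queries`` maps query_id -> query sequence and fixes the output order;
    one row is emitted per query regardless of the hit file.  Subjects
    missing from the lineage map get the path ``unknown``.  Optional
    identity/e-value cutoffs are applied before best-hit selection.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for hit in hits:
        if min_identity is not None and hit.identity < min_identity:
            continue
        if max_evalue is not None and hit.evalue > max_evalue:
            continue
        by_query.setdefault(hit.query_id, []).append(hit)
    rows = []
    for query_id, sequence in queries.items():
        hit = best_hit(by_query.get(query_id, []))
        if hit is None:
            path = NO_HIT
        else:
            path = lineage_map.get(hit.subject_id, UNKNOWN)
        rows.append((query_id, sequence, path))
    return rows


def write_taxonomy_table(
    rows: Sequence[tuple[str, str, str]], sink: Union[str, IO[str]]
) -> None:
    """Write the three-column (query id, sequence, path) TSV report."""
    fh, close = _writer(sink)
    try:
        for query_id, sequence, path in rows:
            fh.write(f"{query_id}\t{sequence}\t{path}\n")
    finally:
        if close:
            fh.close()
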