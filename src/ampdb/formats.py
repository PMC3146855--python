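"""Flat-file I/O for the toolkit.

Covers the five external dialects:

* paired FASTA + QUAL read files (454 convention, one integer quality per base),
* the tab-separated primer & barcode specification file,
* the tab-separated sample-information table,
* frequency-annotated FASTA output (``>seq<rank>_freq=<count>``),
* the plain-text reproducibility log.

All readers accept either a filesystem path or an open text handle.
"""

from __future__ import annotations

import csv
import datetime
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Source = Union[str, IO[str]]

_FREQ_HEADER_RE = re.compile(r"^seq(\d+)_freq=(\d+)$")

PRIMER_BARCODE_COLUMNS = (
    "amplicon_id",
    "sample_id",
    "barcode",
    "forward_primer",
    "reverse_primer",
    "adapter_b",
    "min_len",
    "max_len",
)


class FormatError(ValueError):
    """An input file violates its dialect or a declared invariant."""


def _reader(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r"), True


def _writer(sink: Source):
    if hasattr(sink, "write"):
        return sink, False
    return open(sink, "w"), True


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RawRead:
    """One read with per-base quality values."""

    read_id: str
    sequence: str
    qualities: list[int]

    def validate(self) -> None:
        if not self.read_id:
            raise FormatError("read with empty identifier")
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.read_id}")
        if len(self.qualities) != len(self.sequence):
            raise FormatError(f"quality length mismatch for {self.read_id}")


@dataclass
class PrimerBarcodeSpec:
    """Per-amplicon adapter/barcode/primer definition with length bounds.

    ``barcode_map`` maps sample_id -> barcode string; the barcode may be empty
    only for a single-sample run (demultiplexing is then a pass-through).
    """

    amplicon_id: str
    forward_primer: str
    reverse_primer: str
    adapter_b: str
    min_len: int
    max_len: int
    barcode_map: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.forward_primer or not self.reverse_primer or not self.adapter_b:
            raise FormatError(
                f"amplicon {self.amplicon_id}: primers and adapter must be non-empty"
            )
        if self.min_len > self.max_len:
            raise FormatError(
                f"amplicon {self.amplicon_id}: min_len {self.min_len} > max_len {self.max_len}"
            )


@dataclass
class SampleInfo:
    """One sample with its free-form metadata variables.

    Numeric-looking values are stored as int/float, everything else as str.
    Missing cells are simply absent from ``variables``.
    """

    sample_id: str
    variables: dict[str, object] = field(default_factory=dict)


@dataclass
class StepLog:
    """Bookkeeping for one pipeline step."""

    step_name: str
    n_in: int
    n_kept: int
    n_discarded: int
    discarded_ids: list[str] = field(default_factory=list)
    parameters: dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_in != self.n_kept + self.n_discarded:
            raise FormatError(
                f"step {self.step_name}: n_in {self.n_in} != "
                f"n_kept {self.n_kept} + n_discarded {self.n_discarded}"
            )
        if len(self.discarded_ids) != self.n_discarded:
            raise FormatError(
                f"step {self.step_name}: discarded id list length "
                f"{len(self.discarded_ids)} != n_discarded {self.n_discarded}"
            )


# ---------------------------------------------------------------------------
# FASTA + QUAL
# ---------------------------------------------------------------------------


def read_fasta_qual(fasta_source: Source, qual_source: Source) -> list[RawRead]:
    """Parse paired FASTA and QUAL files into :class:`RawRead` records.

    Records are paired positionally; identifiers (the token before the first
    whitespace in each header) must agree record-by-record, and each record's
    quality list must match its sequence length.
    """
    fh, close_f = _reader(fasta_source)
    try:
        fasta_records = list(SeqIO.parse(fh, "fasta"))
    finally:
        if close_f:
            fh.close()
    qh, close_q = _reader(qual_source)
    try:
        qual_records = list(SeqIO.parse(qh, "qual"))
    finally:
        if close_q:
            qh.close()

    fasta_ids = [r.id for r in fasta_records]
    qual_ids = [r.id for r in qual_records]
    if fasta_ids != qual_ids:
        only_f = set(fasta_ids) - set(qual_ids)
        only_q = set(qual_ids) - set(fasta_ids)
        if only_f or only_q:
            missing = sorted(only_f | only_q)[0]
            raise FormatError(
                f"identifier {missing!r} present in only one of FASTA/QUAL"
            )
        raise FormatError("FASTA and QUAL identifiers are out of order")

    reads = []
    for frec, qrec in zip(fasta_records, qual_records):
        quals = list(qrec.letter_annotations["phred_quality"])
        read = RawRead(frec.id, str(frec.seq).upper(), quals)
        read.validate()
        reads.append(read)
    return reads


def write_fasta_qual(reads: Iterable[RawRead], fasta_sink: Source, qual_sink: Source) -> None:
    """Write reads as a paired FASTA + QUAL file set (60-column wrapping)."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    fh, close_f = _writer(fasta_sink)
    try:
        SeqIO.write(records, fh, "fasta")
    finally:
        if close_f:
            fh.close()
    qh, close_q = _writer(qual_sink)
    try:
        SeqIO.write(records, qh, "qual")
    finally:
        if close_q:
            qh.close()


# ---------------------------------------------------------------------------
# frequency-annotated FASTA
# ---------------------------------------------------------------------------


def write_fasta_with_frequency(unique_sequences: Iterable, sink: Source) -> None:
    """Write a non-redundant set as ``>seq<rank>_freq=<count>`` FASTA.

    Accepts either ``(sequence, count)`` pairs or objects exposing
    ``.sequence`` and ``.pooled_frequency``; records are emitted in input
    order (the dereplication contract already sorts by copy number).
    """
    fh, close = _writer(sink)
    try:
        for rank, item in enumerate(unique_sequences, start=1):
            if hasattr(item, "sequence"):
                seq, count = item.sequence, item.pooled_frequency
            else:
                seq, count = item
            fh.write(f">seq{rank}_freq={count}\n{seq}\n")
    finally:
        if close:
            fh.close()


def parse_frequency_fasta(source: Source) -> list[tuple[str, int]]:
    """Parse frequency-annotated FASTA back into (sequence, count) pairs."""
    fh, close = _reader(source)
    try:
        records = list(SeqIO.parse(fh, "fasta"))
    finally:
        if close:
            fh.close()
    out = []
    for rec in records:
        m = _FREQ_HEADER_RE.match(rec.id)
        if m is None:
            raise FormatError(f"header {rec.id!r} does not match seq<rank>_freq=<count>")
        out.append((str(rec.seq).upper(), int(m.group(2))))
    return out


# ---------------------------------------------------------------------------
# primer & barcode specification file
# ---------------------------------------------------------------------------


def _check_prefix_free(barcodes: Mapping[str, int]) -> None:
    # barcodes: barcode -> row number of first appearance
    items = sorted(barcodes)
    for a, b in zip(items, items[1:]):
        if b.startswith(a):
            raise FormatError(
                f"barcode {a!r} (row {barcodes[a]}) is a prefix of {b!r} "
                f"(row {barcodes[b]}); demultiplexing would be ambiguous"
            )


def parse_primer_barcode_file(source: Source) -> list[PrimerBarcodeSpec]:
    """Parse the tab-separated primer & barcode specification.

    Expected header: ``amplicon_id  sample_id  barcode  forward_primer
    reverse_primer  adapter_b  min_len  max_len``.  Rows sharing an
    amplicon_id are aggregated into one spec; their primer/adapter/length
    columns must agree.  All barcodes in the file must be distinct and
    prefix-free.
    """
    fh, close = _reader(source)
    try:
        rows = list(csv.reader(fh, delimiter="\t"))
    finally:
        if close:
            fh.close()
    if not rows:
        raise FormatError("empty primer & barcode file")
    header = tuple(h.strip() for h in rows[0])
    if header != PRIMER_BARCODE_COLUMNS:
        raise FormatError(
            f"bad primer & barcode header {header!r}; "
            f"expected {PRIMER_BARCODE_COLUMNS!r}"
        )

    specs: dict[str, PrimerBarcodeSpec] = {}
    seen_pairs: set[tuple[str, str]] = set()
    barcode_rows: dict[str, int] = {}
    n_samples = 0
    n_empty_barcodes = 0
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(PRIMER_BARCODE_COLUMNS):
            raise FormatError(f"row {lineno}: expected {len(PRIMER_BARCODE_COLUMNS)} columns")
        amp, sample, barcode, fwd, rev, adapter, min_s, max_s = (c.strip() for c in row)
        barcode = barcode.upper()
        try:
            min_len, max_len = int(min_s), int(max_s)
        except ValueError:
            raise FormatError(f"row {lineno}: min_len/max_len must be integers") from None
        if min_len > max_len:
            raise FormatError(f"row {lineno}: min_len {min_len} > max_len {max_len}")
        if (amp, sample) in seen_pairs:
            raise FormatError(f"row {lineno}: duplicate (amplicon_id, sample_id) ({amp}, {sample})")
        seen_pairs.add((amp, sample))
        n_samples += 1
        if barcode:
            if barcode in barcode_rows:
                raise FormatError(
                    f"row {lineno}: barcode {barcode!r} already used at row {barcode_rows[barcode]}"
                )
            barcode_rows[barcode] = lineno
        else:
            n_empty_barcodes += 1
        spec = specs.get(amp)
        if spec is None:
            spec = PrimerBarcodeSpec(
                amplicon_id=amp,
                forward_primer=fwd.upper(),
                reverse_primer=rev.upper(),
                adapter_b=adapter.upper(),
                min_len=min_len,
                max_len=max_len,
            )
            specs[amp] = spec
        else:
            if (spec.forward_primer, spec.reverse_primer, spec.adapter_b,
                    spec.min_len, spec.max_len) != (fwd.upper(), rev.upper(),
                                                    adapter.upper(), min_len, max_len):
                raise FormatError(
                    f"row {lineno}: amplicon {amp} redefined with different "
                    f"primers/adapter/length bounds"
                )
        spec.barcode_map[sample] = barcode
    if n_empty_barcodes and n_samples > 1:
        raise FormatError("empty barcodes are only allowed in a single-sample spec file")
    _check_prefix_free(barcode_rows)
    out = list(specs.values())
    for spec in out:
        spec.validate()
    if not out:
        raise FormatError("primer & barcode file defines no amplicons")
    return out


def write_primer_barcode_file(specs: Iterable[PrimerBarcodeSpec], sink: Source) -> None:
    fh, close = _writer(sink)
    try:
        fh.write("\t".join(PRIMER_BARCODE_COLUMNS) + "\n")
        for spec in specs:
            for sample_id, barcode in spec.barcode_map.items():
                fh.write(
                    "\t".join(
                        [
                            spec.amplicon_id,
                            sample_id,
                            barcode,
                            spec.forward_primer,
                            spec.reverse_primer,
                            spec.adapter_b,
                            str(spec.min_len),
                            str(spec.max_len),
                        ]
                    )
                    + "\n"
                )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# sample information table
# ---------------------------------------------------------------------------


def coerce_value(text: str):
    """Numeric detection used for sample metadata: int, then float, else str."""
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def parse_sample_info_file(source: Source) -> list[SampleInfo]:
    """Parse the sample-information TSV (first column ``sample_id``)."""
    fh, close = _reader(source)
    try:
        rows = list(csv.reader(fh, delimiter="\t"))
    finally:
        if close:
            fh.close()
    if not rows:
        raise FormatError("empty sample info file")
    header = [h.strip() for h in rows[0]]
    if not header or header[0] != "sample_id":
        raise FormatError("sample info header must start with 'sample_id'")
    variables = header[1:]
    if any(not v for v in variables):
        raise FormatError("sample info header contains an empty variable name")
    out: list[SampleInfo] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        sample_id = row[0].strip()
        if not sample_id:
            raise FormatError(f"row {lineno}: empty sample_id")
        if sample_id in seen:
            raise FormatError(f"row {lineno}: duplicate sample_id {sample_id!r}")
        seen.add(sample_id)
        values: dict[str, object] = {}
        for name, cell in zip(variables, row[1:]):
            cell = cell.strip()
            if cell == "":
                continue
            values[name] = coerce_value(cell)
        out.append(SampleInfo(sample_id, values))
    return out


def write_sample_info_file(samples: Iterable[SampleInfo], sink: Source) -> None:
    samples = list(samples)
    variables: list[str] = []
    for s in samples:
        for name in s.variables:
            if name not in variables:
                variables.append(name)
    fh, close = _writer(sink)
    try:
        fh.write("\t".join(["sample_id"] + variables) + "\n")
        for s in samples:
            cells = [s.sample_id] + [
                "" if name not in s.variables else str(s.variables[name])
                for name in variables
            ]
            fh.write("\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# reproducibility log
# ---------------------------------------------------------------------------


def write_log(
    step_logs: Sequence[StepLog],
    parameters: Mapping[str, object],
    sink: Source,
    timestamp: str | None = None,
) -> None:
    """Write the plain-text run log: a global header block followed by one
    section per step with machine-greppable ``KEY: value`` lines."""
    if timestamp is None:
        timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    fh, close = _writer(sink)
    try:
        fh.write("RUN LOG\n")
        fh.write(f"timestamp: {timestamp}\n")
        for key in sorted(parameters):
            fh.write(f"parameter.{key}: {parameters[key]}\n")
        for log in step_logs:
            log.validate()
            fh.write(f"\nSTEP: {log.step_name}\n")
            for key in sorted(log.parameters):
                fh.write(f"param.{key}: {log.parameters[key]}\n")
            fh.write(f"n_in: {log.n_in}\n")
            fh.write(f"n_kept: {log.n_kept}\n")
            fh.write(f"n_discarded: {log.n_discarded}\n")
            fh.write(f"discarded_ids: {','.join(log.discarded_ids)}\n")
    finally:
        if close:
            fh.close()


def parse_log(source: Source) -> list[StepLog]:
    """Parse a run log back into :class:`StepLog` records (header ignored)."""
    fh, close = _reader(source)
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()
    logs: list[StepLog] = []
    current: StepLog | None = None
    for line in text.splitlines():
        if line.startswith("STEP: "):
            current = StepLog(line[6:].strip(), 0, 0, 0)
            logs.append(current)
        elif current is not None and line.startswith("param."):
            key, _, value = line[6:].partition(": ")
            current.parameters[key] = value
        elif current is not None and line.startswith("n_in: "):
            current.n_in = int(line[6:])
        elif current is not None and line.startswith("n_kept: "):
            current.n_kept = int(line[8:])
        elif current is not None and line.startswith("n_discarded: "):
            current.n_discarded = int(line[13:])
        elif current is not None and line.startswith("discarded_ids: "):
            ids = line[15:].strip()
            current.discarded_ids = ids.split(",") if ids else []
    for log in logs:
        log.validate()
    return logs
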