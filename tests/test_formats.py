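import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampdb.formats import (
    FormatError,
    RawRead,
    SampleInfo,
    StepLog,
    parse_frequency_fasta,
    parse_log,
    parse_primer_barcode_file,
    parse_sample_info_file,
    read_fasta_qual,
    write_fasta_qual,
    write_fasta_with_frequency,
    write_log,
    write_sample_info_file,
)


def _parse(fasta: str, qual: str):
    return read_fasta_qual(io.StringIO(fasta), io.StringIO(qual))


class TestReadFastaQual:
    def test_single_record(self):
        reads = _parse(">r1\nACGT\n", ">r1\n30 30 40 40\n")
        assert len(reads) == 1
        assert reads[0].read_id == "r1"
        assert reads[0].sequence == "ACGT"
        assert reads[0].qualities == [30, 30, 40, 40]

    def test_quality_length_mismatch(self):
        with pytest.raises(FormatError, match="quality length mismatch for r1"):
            _parse(">r1\nACGT\n", ">r1\n30 30 40\n")

    def test_id_in_one_file_only(self):
        with pytest.raises(FormatError, match="only one"):
            _parse(">r1\nACGT\n>r2\nGGGG\n", ">r1\n30 30 40 40\n")

    def test_header_id_is_first_token(self):
        reads = _parse(">r1 length=4 extra\nACGT\n", ">r1 something\n1 2 3 4\n")
        assert reads[0].read_id == "r1"

    def test_lowercase_normalized(self):
        reads = _parse(">r1\nacgt\n", ">r1\n1 2 3 4\n")
        assert reads[0].sequence == "ACGT"

    def test_wrapped_records_round_trip(self):
        # two records with sequences long enough to be wrapped at 60 columns
        reads = [
            RawRead("r1", "ACGT" * 40, [30] * 160),
            RawRead("r2", "TTGCA" * 20, list(range(100))),
        ]
        fasta, qual = io.StringIO(), io.StringIO()
        write_fasta_qual(reads, fasta, qual)
        assert max(len(l) for l in fasta.getvalue().splitlines()) <= 60
        back = _parse(fasta.getvalue(), qual.getvalue())
        assert [(r.read_id, r.sequence, r.qualities) for r in back] == [
            (r.read_id, r.sequence, r.qualities) for r in reads
        ]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
                st.integers(min_value=0, max_value=1000000),
            ),
            min_size=0,
            max_size=8,
        )
    )
    def test_round_trip_lossless(self, items):
        reads = [
            RawRead(f"read{i}", seq, [(i * 7 + j) % 41 for j in range(len(seq))])
            for i, (seq, _) in enumerate(items)
        ]
        fasta, qual = io.StringIO(), io.StringIO()
        write_fasta_qual(reads, fasta, qual)
        back = _parse(fasta.getvalue(), qual.getvalue())
        assert [(r.read_id, r.sequence, r.qualities) for r in back] == [
            (r.read_id, r.sequence, r.qualities) for r in reads
        ]


class TestFrequencyFasta:
    def test_dialect(self):
        sink = io.StringIO()
        write_fasta_with_frequency([("ACGT", 5), ("ACGA", 1)], sink)
        assert sink.getvalue() == ">seq1_freq=5\nACGT\n>seq2_freq=1\nACGA\n"

    def test_empty(self):
        sink = io.StringIO()
        write_fasta_with_frequency([], sink)
        assert sink.getvalue() == ""

    def test_round_trip(self):
        pairs = [("ACGTACGT", 12), ("GGGG", 3), ("ACGT", 1)]
        sink = io.StringIO()
        write_fasta_with_frequency(pairs, sink)
        assert parse_frequency_fasta(io.StringIO(sink.getvalue())) == pairs

    def test_bad_header_rejected(self):
        with pytest.raises(FormatError):
            parse_frequency_fasta(io.StringIO(">notfreq\nACGT\n"))


HEADER = "amplicon_id\tsample_id\tbarcode\tforward_primer\treverse_primer\tadapter_b\tmin_len\tmax_len\n"


class TestPrimerBarcodeFile:
    def test_single_row(self):
        text = HEADER + "amp1\ts1\tACGT\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        specs = parse_primer_barcode_file(io.StringIO(text))
        assert len(specs) == 1
        spec = specs[0]
        assert spec.amplicon_id == "amp1"
        assert spec.barcode_map == {"s1": "ACGT"}
        assert (spec.min_len, spec.max_len) == (100, 400)

    def test_rows_aggregate_by_amplicon(self):
        text = (
            HEADER
            + "amp1\ts1\tACGT\tGGCA\tTTGC\tCTGAG\t100\t400\n"
            + "amp1\ts2\tTGCA\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        )
        specs = parse_primer_barcode_file(io.StringIO(text))
        assert len(specs) == 1
        assert specs[0].barcode_map == {"s1": "ACGT", "s2": "TGCA"}

    def test_barcode_prefix_conflict(self):
        text = (
            HEADER
            + "amp1\ts1\tAC\tGGCA\tTTGC\tCTGAG\t100\t400\n"
            + "amp1\ts2\tACGT\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        )
        with pytest.raises(FormatError, match="prefix"):
            parse_primer_barcode_file(io.StringIO(text))

    def test_duplicate_sample_within_amplicon(self):
        text = (
            HEADER
            + "amp1\ts1\tACGT\tGGCA\tTTGC\tCTGAG\t100\t400\n"
            + "amp1\ts1\tTGCA\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        )
        with pytest.raises(FormatError, match="row 3"):
            parse_primer_barcode_file(io.StringIO(text))

    def test_min_greater_than_max(self):
        text = HEADER + "amp1\ts1\tACGT\tGGCA\tTTGC\tCTGAG\t400\t100\n"
        with pytest.raises(FormatError, match="row 2"):
            parse_primer_barcode_file(io.StringIO(text))

    def test_empty_barcode_single_sample_ok(self):
        text = HEADER + "amp1\ts1\t\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        specs = parse_primer_barcode_file(io.StringIO(text))
        assert specs[0].barcode_map == {"s1": ""}

    def test_empty_barcode_multi_sample_rejected(self):
        text = (
            HEADER
            + "amp1\ts1\t\tGGCA\tTTGC\tCTGAG\t100\t400\n"
            + "amp1\ts2\tACGT\tGGCA\tTTGC\tCTGAG\t100\t400\n"
        )
        with pytest.raises(FormatError, match="single-sample"):
            parse_primer_barcode_file(io.StringIO(text))


class TestSampleInfoFile:
    def test_numeric_detection(self):
        text = "sample_id\ttemperature\tpH\ns1\t15\t7.2\n"
        samples = parse_sample_info_file(io.StringIO(text))
        assert samples[0].variables == {"temperature": 15, "pH": 7.2}
        assert isinstance(samples[0].variables["temperature"], int)

    def test_non_numeric_kept_as_string(self):
        text = "sample_id\tdepth\ns1\t10-20\n"
        samples = parse_sample_info_file(io.StringIO(text))
        assert samples[0].variables == {"depth": "10-20"}

    def test_missing_cell_absent(self):
        text = "sample_id\ta\tb\ns1\t\t4\n"
        samples = parse_sample_info_file(io.StringIO(text))
        assert samples[0].variables == {"b": 4}

    def test_duplicate_sample_id(self):
        text = "sample_id\ta\ns1\t1\ns1\t2\n"
        with pytest.raises(FormatError, match="duplicate sample_id"):
            parse_sample_info_file(io.StringIO(text))

    def test_round_trip(self):
        samples = [
            SampleInfo("s1", {"temperature": 15, "site": "lake"}),
            SampleInfo("s2", {"temperature": 25.5}),
        ]
        sink = io.StringIO()
        write_sample_info_file(samples, sink)
        back = parse_sample_info_file(io.StringIO(sink.getvalue()))
        assert [(s.sample_id, s.variables) for s in back] == [
            (s.sample_id, s.variables) for s in samples
        ]


class TestLog:
    def test_sections_and_round_trip(self):
        logs = [
            StepLog("adapter_trim", 10, 8, 2, ["r1", "r2"], {"mode": "perfect"}),
            StepLog("ambiguity_filter", 8, 8, 0, [], {}),
        ]
        sink = io.StringIO()
        write_log(logs, {"quality_threshold": 25}, sink, timestamp="2020-01-01T00:00:00")
        text = sink.getvalue()
        assert "parameter.quality_threshold: 25" in text
        assert text.count("STEP: ") == 2
        assert "discarded_ids: r1,r2" in text
        back = parse_log(io.StringIO(text))
        assert [(l.step_name, l.n_in, l.n_kept, l.n_discarded, l.discarded_ids) for l in back] == [
            (l.step_name, l.n_in, l.n_kept, l.n_discarded, l.discarded_ids) for l in logs
        ]

    def test_empty_discarded_section_present(self):
        sink = io.StringIO()
        write_log([StepLog("quality_filter", 5, 5, 0, [], {})], {}, sink)
        assert "n_discarded: 0" in sink.getvalue()

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(FormatError):
            write_log([StepLog("x", 5, 3, 1, ["a"], {})], {}, io.StringIO())
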