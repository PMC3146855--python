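import pytest

from ampdb.datastore import Datastore, DatastoreError
from ampdb.formats import RawRead
from ampdb.pipeline import run_pipeline
from ampdb.simdata import generate_dataset

from conftest import MIXED_RATES


@pytest.fixture(scope="module")
def small_ds():
    return generate_dataset(n_reads=200, n_samples=3, defect_rates=MIXED_RATES, seed=21)


def _upload(store, ds, name="run"):
    return store.upload_dataset(ds.reads, ds.specs, ds.sample_info, ds.pipeline_config(), name)


class TestUpload:
    def test_statistics_match_pipeline_logs(self, store, small_ds):
        dsid = _upload(store, small_ds)
        result = run_pipeline(
            small_ds.reads, small_ds.specs, small_ds.sample_info, small_ds.pipeline_config()
        )
        stored = store.get_step_logs(dsid)
        assert [(l.step_name, l.n_in, l.n_kept, l.n_discarded) for l in stored] == [
            (l.step_name, l.n_in, l.n_kept, l.n_discarded) for l in result.step_logs
        ]
        assert [sorted(l.discarded_ids) for l in stored] == [
            sorted(l.discarded_ids) for l in result.step_logs
        ]
        report = store.summary_statistics(dsid)
        assert report["total_in"] == 200

    def test_two_uploads_are_isolated(self, store, small_ds):
        d1 = _upload(store, small_ds, "one")
        d2 = _upload(store, small_ds, "two")
        assert d1 != d2
        r1 = store.get_raw_reads(d1)
        r2 = store.get_raw_reads(d2)
        assert len(r1) == len(r2) == 200
        p1 = store.get_pooled_sequences(d1)
        p2 = store.get_pooled_sequences(d2)
        assert p1 == p2  # same content, independent scopes
        store.delete_dataset(d2)
        assert store.get_pooled_sequences(d1) == p1

    def test_failed_upload_is_atomic(self, store, small_ds):
        before = store.row_counts()
        bad = [RawRead("r1", "ACGT", [30, 30, 30, 30])]
        with pytest.raises(Exception):
            # barcode samples missing from sample_info -> pipeline hard error
            store.upload_dataset(bad, small_ds.specs, [], small_ds.pipeline_config(), "bad")
        assert store.row_counts() == before

    def test_raw_reads_round_trip(self, store, small_ds):
        dsid = _upload(store, small_ds)
        back = store.get_raw_reads(dsid)
        assert [(r.read_id, r.sequence, r.qualities) for r in back] == [
            (r.read_id, r.sequence, r.qualities) for r in small_ds.reads
        ]

    def test_referential_integrity(self, store, small_ds):
        _upload(store, small_ds)
        assert store.integrity_check() == []


class TestDelete:
    def test_delete_restores_pre_upload_state(self, store, small_ds):
        before = store.row_counts()
        dsid = _upload(store, small_ds)
        assert store.row_counts() != before
        store.delete_dataset(dsid)
        assert store.row_counts() == before

    def test_delete_unknown_errors(self, store):
        with pytest.raises(DatastoreError, match="unknown dataset"):
            store.delete_dataset(999)

    def test_delete_twice_errors(self, store, small_ds):
        dsid = _upload(store, small_ds)
        store.delete_dataset(dsid)
        with pytest.raises(DatastoreError):
            store.delete_dataset(dsid)


class TestCombineAndReprocess:
    def test_split_singleton_survives_combination(self, store):
        # one copy of the same template in each of two runs (different
        # samples): discarded as a singleton in each run alone, but retained
        # once the raw reads are pooled and re-processed
        from ampdb.simdata import ADAPTER_B, FORWARD_PRIMER, RC_REVERSE

        a = generate_dataset(n_reads=40, n_samples=2, seed=30)
        b = generate_dataset(n_reads=40, n_samples=2, seed=30)  # same barcodes
        barcode = a.specs[0].barcode_map
        tmpl = "ATGGA" * 16  # 80 bp, adapter-free, run-safe boundaries
        seq1 = barcode["s1"] + FORWARD_PRIMER + tmpl + RC_REVERSE + ADAPTER_B
        seq2 = barcode["s2"] + FORWARD_PRIMER + tmpl + RC_REVERSE + ADAPTER_B
        reads_a = a.reads + [RawRead("extraA", seq1, [35] * len(seq1))]
        reads_b = b.reads + [RawRead("extraB", seq2, [35] * len(seq2))]
        d1 = store.upload_dataset(reads_a, a.specs, a.sample_info, a.pipeline_config(), "a")
        d2 = store.upload_dataset(reads_b, b.specs, b.sample_info, b.pipeline_config(), "b")
        assert tmpl not in {s for _, s, _ in store.get_pooled_sequences(d1)}
        assert tmpl not in {s for _, s, _ in store.get_pooled_sequences(d2)}
        combined = store.combine_and_reprocess([d1, d2], None, a.pipeline_config(), "ab")
        pooled = {s: f for _, s, f in store.get_pooled_sequences(combined)}
        assert pooled[tmpl] == 2

    def test_combine_with_self_doubles_frequencies(self, store, small_ds):
        d1 = _upload(store, small_ds)
        combined = store.combine_and_reprocess(
            [d1, d1], None, small_ds.pipeline_config(), "double"
        )
        p1 = dict((s, f) for _, s, f in store.get_pooled_sequences(d1))
        pc = dict((s, f) for _, s, f in store.get_pooled_sequences(combined))
        assert pc == {s: 2 * f for s, f in p1.items()}

    def test_single_dataset_idempotent(self, store, small_ds):
        d1 = _upload(store, small_ds)
        combined = store.combine_and_reprocess(
            [d1], None, small_ds.pipeline_config(), "again"
        )
        assert [
            (s, f) for _, s, f in store.get_pooled_sequences(combined)
        ] == [(s, f) for _, s, f in store.get_pooled_sequences(d1)]

    def test_unknown_source_errors_before_work(self, store):
        before = store.row_counts()
        with pytest.raises(DatastoreError):
            store.combine_and_reprocess([123], None, None, "nope")
        assert store.row_counts() == before

    def test_sources_untouched(self, store, small_ds):
        d1 = _upload(store, small_ds)
        raw_before = store.get_raw_reads(d1)
        store.combine_and_reprocess([d1], None, small_ds.pipeline_config(), "copy")
        assert store.get_raw_reads(d1) == raw_before


class TestEditing:
    def test_update_sample_info_upsert_and_delete(self, store, small_ds):
        dsid = _upload(store, small_ds)
        store.update_sample_info(dsid, "s1", "temperature", 12)
        info = {s.sample_id: s.variables for s in store.get_sample_info(dsid)}
        assert info["s1"]["temperature"] == 12
        store.update_sample_info(dsid, "s1", "temperature", None)
        info = {s.sample_id: s.variables for s in store.get_sample_info(dsid)}
        assert "temperature" not in info["s1"]

    def test_update_unknown_sample_errors(self, store, small_ds):
        dsid = _upload(store, small_ds)
        with pytest.raises(DatastoreError, match="unknown sample"):
            store.update_sample_info(dsid, "sX", "temperature", 1)

    def test_edited_taxonomy_preserves_assigned(self, store, small_ds):
        dsid = _upload(store, small_ds)
        store.set_assigned_taxonomy(dsid, 1, "Eukaryota;Alpha")
        store.set_edited_taxonomy(dsid, 1, "Eukaryota;Beta", "alice")
        tax = store.get_taxonomy(dsid, 1)
        assert tax["assigned_path"] == "Eukaryota;Alpha"
        assert tax["edited_path"] == "Eukaryota;Beta"
        assert tax["edited_by"] == "alice"
        assert tax["edited_at"] is not None

    def test_second_edit_replaces_edited_only(self, store, small_ds):
        dsid = _upload(store, small_ds)
        store.set_assigned_taxonomy(dsid, 1, "A")
        store.set_edited_taxonomy(dsid, 1, "B", "alice")
        store.set_edited_taxonomy(dsid, 1, "C", "bob")
        tax = store.get_taxonomy(dsid, 1)
        assert (tax["assigned_path"], tax["edited_path"], tax["edited_by"]) == ("A", "C", "bob")

    def test_reassignment_leaves_edit_alone(self, store, small_ds):
        dsid = _upload(store, small_ds)
        store.set_assigned_taxonomy(dsid, 1, "A")
        store.set_edited_taxonomy(dsid, 1, "B", "alice")
        store.set_assigned_taxonomy(dsid, 1, "A2")  # automatic re-assignment
        tax = store.get_taxonomy(dsid, 1)
        assert (tax["assigned_path"], tax["edited_path"]) == ("A2", "B")

    def test_edit_unknown_sequence_errors(self, store, small_ds):
        dsid = _upload(store, small_ds)
        with pytest.raises(DatastoreError, match="unknown sequence"):
            store.set_edited_taxonomy(dsid, 99999, "X", "alice")


class TestSummaryStatistics:
    def test_conservation(self, store, small_ds):
        dsid = _upload(store, small_ds)
        report = store.summary_statistics(dsid)
        assert report["total_in"] == report["total_retained"] + report["total_discarded"]
        for step in report["steps"]:
            assert step["n_in"] == step["n_kept"] + step["n_discarded"]

    def test_unknown_dataset_errors(self, store):
        with pytest.raises(DatastoreError):
            store.summary_statistics(42)

    def test_everything_discarded_still_well_formed(self, store):
        ds = generate_dataset(n_reads=50, n_samples=2, defect_rates={"adapter": 1.0}, seed=31)
        dsid = _upload(store, ds)
        report = store.summary_statistics(dsid)
        assert report["total_retained"] == 0
        assert len(report["steps"]) == 7
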