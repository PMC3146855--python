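# ampdb

Amplicon read cleaning, storage and retrieval for 454-style biodiversity
surveys: a seven-step read-cleaning pipeline with indel-aware dereplication,
an embedded relational store for multi-dataset surveys, a six-axis query
engine over sequences linked to sample metadata, closest-hit taxonomy
assignment from precomputed similarity hits, and a synthetic-data generator
with exact per-step ground truth.

## The pipeline

Raw reads (paired FASTA + QUAL) pass through, in order:

1. **adapter_trim** — strip 3' poly-N tails, then trim adapter B
   (perfect match, or a fuzzy mode allowing `ceil(len/10)` mismatches per
   adapter; a ≥ 4 bp exact adapter prefix at the very read end also counts,
   covering reads that truncate inside the adapter). Unmatched reads are
   discarded.
2. **ambiguity_filter** — discard reads containing any N.
3. **demultiplex** — assign reads to samples by 5' barcode (variable-length,
   prefix-free) and strip it; skipped for single-sample runs without barcodes.
4. **singleton_removal** — keep a sequence only if the exact string occurs in
   ≥ 2 distinct samples (within-sample copies do not count); single-sample
   runs fall back to a ≥ 2-copies rule.
5. **length_filter** — per-amplicon inclusive length bounds, measured after
   barcode/adapter removal and before primer removal.
6. **primer_trim** — both primers required with exact identity, except the
   primer-terminal homopolymer run (≥ 2 bases), whose length may vary by up
   to a configurable slack (454 slippage).
7. **quality_filter** — mean phred quality of the fully trimmed read.

Dereplication collapses exact strings only (indels are informative), records
pooled and per-sample copy numbers, and ranks by frequency descending.

## CLI

```sh
# generate a synthetic run with known ground truth
ampdb simulate --reads 1000 --samples 4 --seed 7 --out sim \
    --singleton-rate 0.05 --low-quality-rate 0.05

# clean it and store it
ampdb --db survey.sqlite upload --fasta sim/reads.fna --qual sim/reads.qual \
    --primers sim/primer_barcode.tsv --samples sim/sample_info.tsv \
    --quality 25 --name run1

# per-step statistics, queries, export
ampdb --db survey.sqlite stats --dataset 1
ampdb --db survey.sqlite query --where temperature:10:20 --format tsv
ampdb --db survey.sqlite export --samples s1 --out s1.fna --format fasta
ampdb --db survey.sqlite query --subsample 100 --seed 3 --format fasta

# combine runs and re-process (rescues cross-run low-frequency variants)
ampdb --db survey.sqlite reprocess --datasets 1,2 --name combined

# metadata and taxonomy editing (manual edits never overwrite the
# automatic assignment)
ampdb --db survey.sqlite edit-sample --dataset 1 --sample s1 --var pH --value 7.1
ampdb --db survey.sqlite assign-taxonomy --dataset 1 --hits hits.tsv \
    --lineage lineage.tsv --out taxonomy.tsv
ampdb --db survey.sqlite edit-taxonomy --dataset 1 --rank 3 \
    --path "Eukaryota;Chlorophyta" --editor alice
```

Every data-modifying run writes a plain-text reproducibility log with the
parameters, per-step counts and discarded read identifiers.

A `key=value` config file (`--config`) can set defaults for `db`,
`quality_threshold`, `adapter_mode`, `homopolymer_slack` and
`fuzzy_max_mismatch_per_10bp`.

## Layout

- `src/ampdb/formats.py` — FASTA+QUAL, primer/barcode TSV, sample-info TSV,
  frequency-FASTA and run-log I/O
- `src/ampdb/pipeline.py` — the seven steps, dereplication, driver
- `src/ampdb/datastore.py` — embedded sqlite store (two static + seven
  per-dataset relations, scoped by `dataset_id`), upload/delete/reprocess,
  editing with provenance
- `src/ampdb/query.py` — filtering, random subsampling, abundance, export
- `src/ampdb/taxonomy.py` — closest-hit path assignment
- `src/ampdb/simdata.py` — ground-truthed synthetic dataset generator
- `src/ampdb/cli.py` — `ampdb` entry point
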