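"""Seven-step amplicon read-cleaning pipeline with indel-aware dereplication.

Step order (the default; configurable in code):

1. ``adapter_trim``      – strip terminal poly-N, then trim the 3' adapter B
                           (reads without an adapter match are discarded)
2. ``ambiguity_filter``  – discard reads containing any N
3. ``demultiplex``       – assign reads to samples by 5' barcode and strip it
4. ``singleton_removal`` – discard sequences not present in >= 2 distinct samples
5. ``length_filter``     – per-amplicon length bounds (pre primer trim)
6. ``primer_trim``       – both primers required; the primer-terminal
                           homopolymer run may vary in length (454 slippage)
7. ``quality_filter``    – mean phred quality of the trimmed read

Dereplication collapses exact sequence strings only: variants differing by a
single indel stay separate.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .formats import PrimerBarcodeSpec, RawRead, SampleInfo, StepLog

STEP_ORDER = (
    "adapter_trim",
    "ambiguity_filter",
    "demultiplex",
    "singleton_removal",
    "length_filter",
    "primer_trim",
    "quality_filter",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNASSIGNED = "unassigned"


class PipelineError(ValueError):
    """Unrecoverable input inconsistency detected before or during a run."""


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs for one pipeline run.

    ``disabled_steps`` may name any step from :data:`STEP_ORDER`; a disabled
    step passes every read through untouched and logs zero discards.  The
    ``remove_ambiguous`` / ``remove_singletons`` flags are shorthands for
    disabling steps 2 and 4.
    """

    adapter_mode: str = "perfect"  # "perfect" | "fuzzy"
    fuzzy_max_mismatch_per_10bp: int = 1
    remove_ambiguous: bool = True
    remove_singletons: bool = True
    quality_threshold: float = 25.0
    homopolymer_slack: int = 3
    single_sample_singleton_fallback: str = "min_two_copies"  # | "skip"
    disabled_steps: frozenset[str] = frozenset()
    step_order: tuple[str, ...] = STEP_ORDER

    def __post_init__(self):
        if self.adapter_mode not in ("perfect", "fuzzy"):
            raise PipelineError(f"unknown adapter_mode {self.adapter_mode!r}")
        if self.single_sample_singleton_fallback not in ("min_two_copies", "skip"):
            raise PipelineError(
                f"unknown singleton fallback {self.single_sample_singleton_fallback!r}"
            )
        if self.quality_threshold < 0:
            raise PipelineError("quality_threshold must be >= 0")
        if self.homopolymer_slack < 0:
            raise PipelineError("homopolymer_slack must be >= 0")
        unknown = set(self.disabled_steps) - set(STEP_ORDER)
        if unknown:
            raise PipelineError(f"unknown step(s) in disabled_steps: {sorted(unknown)}")
        if sorted(self.step_order) != sorted(STEP_ORDER):
            raise PipelineError("step_order must be a permutation of STEP_ORDER")

    def step_enabled(self, step: str) -> bool:
        if step in self.disabled_steps:
            return False
        if step == "ambiguity_filter" and not self.remove_ambiguous:
            return False
        if step == "singleton_removal" and not self.remove_singletons:
            return False
        return True


@dataclass
class ProcessedRead:
    """A read moving through the pipeline.

    ``window`` is the currently retained [start, end) span on the original
    read; ``provenance`` records the window after each trimming step.
    """

    read_id: str
    sequence: str
    qualities: list[int]
    sample_id: str | None = None
    amplicon_id: str | None = None
    window: tuple[int, int] = (0, 0)
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    @classmethod
    def from_raw(cls, read: RawRead) -> "ProcessedRead":
        return cls(
            read_id=read.read_id,
            sequence=read.sequence,
            qualities=list(read.qualities),
            window=(0, len(read.sequence)),
        )

    def trim(self, step: str, n_left: int, n_right: int) -> None:
        """Drop ``n_left`` bases from the 5' end and ``n_right`` from the 3'
        end, keeping sequence and qualities in lockstep."""
        n = len(self.sequence)
        assert 0 <= n_left and 0 <= n_right and n_left + n_right <= n
        self.sequence = self.sequence[n_left : n - n_right]
        self.qualities = self.qualities[n_left : n - n_right]
        start, end = self.window
        self.window = (start + n_left, end - n_right)
        self.provenance[step] = self.window


@dataclass
class UniqueSequence:
    """One dereplicated variant with pooled and per-sample copy numbers."""

    sequence: str
    pooled_frequency: int
    per_sample_frequency: dict[str, int]
    rank: int
    amplicon_id: str | None = None


@dataclass
class PipelineResult:
    processed_reads: list[ProcessedRead]
    unique_sequences: list[UniqueSequence]
    step_logs: list[StepLog]


# ---------------------------------------------------------------------------
# step 1: poly-N strip + adapter B trim
# ---------------------------------------------------------------------------


def strip_poly_n(read: ProcessedRead) -> bool:
    """Remove the maximal terminal run of N at the 3' end (with qualities).

    Returns False when the read becomes empty (caller discards it).
    """
    n_tail = len(read.sequence) - len(read.sequence.rstrip("N"))
    if n_tail:
        if n_tail == len(read.sequence):
            return False
        read.trim("poly_n", 0, n_tail)
    return True


def find_adapter_cut(
    sequence: str,
    adapters: Sequence[str],
    mode: str = "perfect",
    fuzzy_budget: int = 1,
) -> int | None:
    """Locate the adapter-B cut position (start of the matched region).

    The rightmost qualifying occurrence wins; ties at the same position go to
    the longest match.  A 3'-terminal exact prefix of an adapter (>= 4 bases)
    at the very end of the read also qualifies, covering reads that truncate
    inside the adapter.  Fuzzy mode additionally allows full-length matches
    with up to ``ceil(len(adapter)/10) * fuzzy_budget`` mismatches (no indels).
    """
    candidates: list[tuple[int, int]] = []  # (start, matched_length)
    n = len(sequence)
    for adapter in adapters:
        alen = len(adapter)
        if mode == "perfect":
            idx = sequence.rfind(adapter)
            if idx != -1:
                candidates.append((idx, alen))
        else:
            budget = math.ceil(alen / 10) * fuzzy_budget
            for start in range(n - alen, -1, -1):
                mismatches = 0
                for a, b in zip(sequence[start : start + alen], adapter):
                    if a != b:
                        mismatches += 1
                        if mismatches > budget:
                            break
                else:
                    candidates.append((start, alen))
                    break  # rightmost occurrence for this adapter found
        # truncated adapter at the very end of the read (exact prefix, >= 4 bp)
        for k in range(min(alen - 1, n), 3, -1):
            if sequence.endswith(adapter[:k]):
                candidates.append((n - k, k))
                break
    if not candidates:
        return None
    start, _ = max(candidates, key=lambda c: (c[0], c[1]))
    return start


def trim_adapter_b(
    read: ProcessedRead,
    adapters: Sequence[str],
    mode: str = "perfect",
    fuzzy_budget: int = 1,
) -> bool:
    """Trim adapter B and everything 3' of it.  False means no match."""
    cut = find_adapter_cut(read.sequence, adapters, mode, fuzzy_budget)
    if cut is None:
        return False
    read.trim("adapter_trim", 0, len(read.sequence) - cut)
    return True


# ---------------------------------------------------------------------------
# step 2: ambiguity filter
# ---------------------------------------------------------------------------


def has_ambiguous(sequence: str) -> bool:
    return "N" in sequence


# ---------------------------------------------------------------------------
# step 3: demultiplexing
# ---------------------------------------------------------------------------


def build_barcode_map(specs: Sequence[PrimerBarcodeSpec]) -> dict[str, str]:
    """Merge barcode maps across amplicons into barcode -> sample_id."""
    merged: dict[str, str] = {}
    for spec in specs:
        for sample_id, barcode in spec.barcode_map.items():
            if not barcode:
                continue
            if barcode in merged and merged[barcode] != sample_id:
                raise PipelineError(
                    f"barcode {barcode!r} assigned to both "
                    f"{merged[barcode]!r} and {sample_id!r}"
                )
            merged[barcode] = sample_id
    return merged


def defined_samples(specs: Sequence[PrimerBarcodeSpec]) -> list[str]:
    seen: list[str] = []
    for spec in specs:
        for sample_id in spec.barcode_map:
            if sample_id not in seen:
                seen.append(sample_id)
    return seen


def demultiplex(read: ProcessedRead, specs: Sequence[PrimerBarcodeSpec]) -> bool:
    """Assign the read to a sample by its 5' barcode and strip the barcode.

    With exactly one defined sample and no barcode, the step is a tag-only
    pass-through.  Returns False when no barcode is a prefix (unassigned).
    """
    barcode_map = build_barcode_map(specs)
    samples = defined_samples(specs)
    if not barcode_map and len(samples) == 1:
        read.sample_id = samples[0]
        return True
    for barcode, sample_id in barcode_map.items():
        if read.sequence.startswith(barcode):
            read.trim("demultiplex", len(barcode), 0)
            read.sample_id = sample_id
            return True
    return False


# ---------------------------------------------------------------------------
# step 4: cross-sample singleton removal
# ---------------------------------------------------------------------------


def remove_cross_sample_singletons(
    reads: Sequence[ProcessedRead],
    n_defined_samples: int,
    fallback: str = "min_two_copies",
) -> tuple[list[ProcessedRead], list[ProcessedRead]]:
    """Split reads into (kept, discarded) by the cross-sample criterion.

    A sequence string is trusted only if it occurs in >= 2 distinct samples;
    within-sample copy number does not count.  Single-sample runs fall back to
    ``min_two_copies`` (total copy number >= 2) or ``skip`` (keep everything).
    """
    if n_defined_samples <= 1:
        if fallback == "skip":
            return list(reads), []
        counts = Counter(r.sequence for r in reads)
        kept = [r for r in reads if counts[r.sequence] >= 2]
        discarded = [r for r in reads if counts[r.sequence] < 2]
        return kept, discarded
    samples_per_seq: dict[str, set] = defaultdict(set)
    for r in reads:
        samples_per_seq[r.sequence].add(r.sample_id)
    kept = [r for r in reads if len(samples_per_seq[r.sequence]) >= 2]
    discarded = [r for r in reads if len(samples_per_seq[r.sequence]) < 2]
    return kept, discarded


# ---------------------------------------------------------------------------
# steps 5 & 6: amplicon identification, length filter, primer trim
# ---------------------------------------------------------------------------


def match_forward_primer(sequence: str, primer: str, slack: int) -> int | None:
    """Match the forward primer at the 5' end, tolerating 454 homopolymer
    length variants in the primer's 3'-terminal run.

    Returns the number of read bases covered by the match (to be removed),
    or None.  Outside the terminal run the match must be exact; the run
    itself (when >= 2 bases long in the primer) may appear with its length
    off by up to ``slack`` bases, but never shorter than one base.
    """
    ch = primer[-1]
    run = len(primer) - len(primer.rstrip(ch))
    if run >= 2 and slack > 0:
        stem = primer[: len(primer) - run]
        if not sequence.startswith(stem):
            return None
        i = len(stem)
        k_obs = 0
        while i + k_obs < len(sequence) and sequence[i + k_obs] == ch:
            k_obs += 1
        k = min(k_obs, run + slack)
        if k < max(1, run - slack):
            return None
        return len(stem) + k
    return len(primer) if sequence.startswith(primer) else None


def match_reverse_primer(sequence: str, reverse_primer: str, slack: int) -> int | None:
    """Match the reverse complement of the reverse primer at the 3' end,
    with the homopolymer rule applied to its terminal run at the read end.

    Returns the number of 3' read bases covered, or None.
    """
    rc = revcomp(reverse_primer)
    ch = rc[-1]
    run = len(rc) - len(rc.rstrip(ch))
    if run >= 2 and slack > 0:
        stem = rc[: len(rc) - run]
        k_obs = len(sequence) - len(sequence.rstrip(ch))
        k = min(k_obs, run + slack)
        if k < max(1, run - slack):
            return None
        if not sequence[: len(sequence) - k].endswith(stem):
            return None
        return len(stem) + k
    return len(rc) if sequence.endswith(rc) else None


def identify_amplicon(
    sequence: str, specs: Sequence[PrimerBarcodeSpec], slack: int
) -> PrimerBarcodeSpec | None:
    """Pick the amplicon whose forward primer matches the read's 5' end.

    Longer forward primers are tried first so that nested primers resolve
    deterministically to the more specific amplicon.
    """
    for spec in sorted(specs, key=lambda s: -len(s.forward_primer)):
        if match_forward_primer(sequence, spec.forward_primer, slack) is not None:
            return spec
    return None


def filter_length(read: ProcessedRead, spec: PrimerBarcodeSpec) -> bool:
    """Inclusive per-amplicon length bounds, measured before primer removal."""
    return spec.min_len <= len(read.sequence) <= spec.max_len


def trim_primers(read: ProcessedRead, spec: PrimerBarcodeSpec, slack: int) -> bool:
    """Trim both primers (forward at 5', revcomp(reverse) at 3').

    Both must match; False means no-match and the read is discarded.
    """
    fwd = match_forward_primer(read.sequence, spec.forward_primer, slack)
    if fwd is None:
        return False
    rev = match_reverse_primer(read.sequence[fwd:], spec.reverse_primer, slack)
    if rev is None:
        return False
    read.trim("primer_trim", fwd, rev)
    return True


# ---------------------------------------------------------------------------
# step 7: quality filter
# ---------------------------------------------------------------------------


def mean_quality(qualities: Sequence[int]) -> float:
    return sum(qualities) / len(qualities) if qualities else 0.0


def filter_quality(read: ProcessedRead, threshold: float) -> bool:
    """Keep iff the mean of the remaining quality values >= threshold.

    Empty reads are discarded regardless of threshold.
    """
    if not read.qualities:
        return False
    return mean_quality(read.qualities) >= threshold


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------


def dereplicate(reads: Iterable[ProcessedRead]) -> list[UniqueSequence]:
    """Collapse exact sequence strings into a ranked non-redundant set.

    Indels are informative: no alignment is performed, so variants differing
    by a single inserted/deleted base remain separate entries.  Output is
    sorted by pooled copy number descending, ties broken lexicographically
    by sequence; ranks run 1..N.
    """
    pooled: Counter[str] = Counter()
    per_sample: dict[str, Counter] = defaultdict(Counter)
    amplicon: dict[str, str | None] = {}
    for read in reads:
        pooled[read.sequence] += 1
        per_sample[read.sequence][read.sample_id or UNASSIGNED] += 1
        amplicon.setdefault(read.sequence, read.amplicon_id)
    ordered = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        UniqueSequence(
            sequence=seq,
            pooled_frequency=count,
            per_sample_frequency=dict(sorted(per_sample[seq].items())),
            rank=rank,
            amplicon_id=amplicon[seq],
        )
        for rank, (seq, count) in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _validate_inputs(
    specs: Sequence[PrimerBarcodeSpec],
    sample_info: Sequence[SampleInfo] | None,
) -> None:
    if not specs:
        raise PipelineError("no amplicon specs given")
    for spec in specs:
        spec.validate()
    build_barcode_map(specs)  # raises on conflicts
    if sample_info is not None:
        known = {s.sample_id for s in sample_info}
        missing = [s for s in defined_samples(specs) if s not in known]
        if missing:
            raise PipelineError(
                f"samples {missing} appear in the primer/barcode spec "
                f"but not in the sample info table"
            )


def run_pipeline(
    raw_reads: Sequence[RawRead],
    specs: Sequence[PrimerBarcodeSpec],
    sample_info: Sequence[SampleInfo] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all seven steps in ``config.step_order`` and dereplicate.

    Every step emits a :class:`StepLog`; logs chain (n_kept of step i equals
    n_in of step i+1) and each satisfies n_in = n_kept + n_discarded.
    """
    if config is None:
        config = PipelineConfig()
    _validate_inputs(specs, sample_info)

    adapters = sorted({s.adapter_b for s in specs}, key=len, reverse=True)
    n_samples = len(defined_samples(specs))
    current = [ProcessedRead.from_raw(r) for r in raw_reads]
    step_logs: list[StepLog] = []

    for step in config.step_order:
        n_in = len(current)
        enabled = config.step_enabled(step)
        params: dict[str, object] = {"enabled": enabled}
        if not enabled:
            step_logs.append(StepLog(step, n_in, n_in, 0, [], params))
            continue
        kept: list[ProcessedRead] = []
        discarded: list[ProcessedRead] = []

        if step == "adapter_trim":
            params.update(
                mode=config.adapter_mode,
                adapters=",".join(adapters),
                fuzzy_budget=config.fuzzy_max_mismatch_per_10bp,
            )
            for read in current:
                if not strip_poly_n(read):
                    discarded.append(read)
                elif trim_adapter_b(
                    read, adapters, config.adapter_mode, config.fuzzy_max_mismatch_per_10bp
                ):
                    kept.append(read)
                else:
                    discarded.append(read)
        elif step == "ambiguity_filter":
            for read in current:
                (discarded if has_ambiguous(read.sequence) else kept).append(read)
        elif step == "demultiplex":
            params.update(n_samples=n_samples)
            for read in current:
                (kept if demultiplex(read, specs) else discarded).append(read)
        elif step == "singleton_removal":
            params.update(
                criterion="present in >= 2 distinct samples",
                single_sample_fallback=config.single_sample_singleton_fallback,
            )
            kept, discarded = remove_cross_sample_singletons(
                current, n_samples, config.single_sample_singleton_fallback
            )
        elif step == "length_filter":
            params.update(
                bounds={s.amplicon_id: (s.min_len, s.max_len) for s in specs}
            )
            for read in current:
                spec = identify_amplicon(read.sequence, specs, config.homopolymer_slack)
                if spec is None:
                    discarded.append(read)
                    continue
                read.amplicon_id = spec.amplicon_id
                (kept if filter_length(read, spec) else discarded).append(read)
        elif step == "primer_trim":
            params.update(homopolymer_slack=config.homopolymer_slack)
            by_id = {s.amplicon_id: s for s in specs}
            for read in current:
                spec = (
                    by_id.get(read.amplicon_id)
                    if read.amplicon_id is not None
                    else identify_amplicon(read.sequence, specs, config.homopolymer_slack)
                )
                if spec is not None and trim_primers(read, spec, config.homopolymer_slack):
                    read.amplicon_id = spec.amplicon_id
                    kept.append(read)
                else:
                    discarded.append(read)
        elif step == "quality_filter":
            params.update(threshold=config.quality_threshold)
            for read in current:
                (kept if filter_quality(read, config.quality_threshold) else discarded).append(read)
        else:  # pragma: no cover - guarded by config validation
            raise PipelineError(f"unknown step {step!r}")

        log = StepLog(
            step_name=step,
            n_in=n_in,
            n_kept=len(kept),
            n_discarded=len(discarded),
            discarded_ids=[r.read_id for r in discarded],
            parameters=params,
        )
        log.validate()
        step_logs.append(log)
        current = kept

    unique = dereplicate(current)
    return PipelineResult(current, unique, step_logs)
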