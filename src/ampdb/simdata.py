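"""Synthetic 454-style amplicon datasets with exact per-step ground truth.

Reads are assembled as::

    barcode + forward_primer + template + revcomp(reverse_primer) + adapter_B
    (+ optional poly-N tail)

Defects are planted so that each read's first fatal defect determines the
pipeline step at which it must be discarded; the generator's bookkeeping
therefore serves as an exact oracle for per-step discard sets.

Construction rules that keep the bookkeeping exact:

* templates never start or end with the base adjoining a primer-terminal
  homopolymer run, so run-length counting is unambiguous;
* the adapter never occurs inside an adapter-less read (checked, with a
  brute-force mismatch scan when fuzzy mode is requested);
* defects that must survive the cross-sample singleton step are planted as
  identical pairs in two distinct samples;
* every shared template gets two clean copies in two distinct samples, so
  late-step defect copies of it always have cross-sample support;
* clean/low-quality base qualities are clipped to disjoint bands around the
  quality threshold, so the mean-quality verdict is deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .formats import (
    PrimerBarcodeSpec,
    RawRead,
    SampleInfo,
    write_fasta_qual,
    write_primer_barcode_file,
    write_sample_info_file,
)
from .pipeline import PipelineConfig, revcomp

ADAPTER_B = "CTGAGACTGC"
FORWARD_PRIMER = "GTGCCAGCAGCC"   # 3'-terminal run: CC
REVERSE_PRIMER = "GGACTACCAGGG"   # revcomp CCCTGGTAGTCC: terminal run CC at read end
RC_REVERSE = revcomp(REVERSE_PRIMER)
BARCODE_LEN = 6
AMPLICON_ID = "amp1"
MIN_LEN, MAX_LEN = 80, 130
TEMPLATE_LEN_RANGE = (70, 90)
SHORT_TEMPLATE_LEN = 20
LONG_TEMPLATE_LEN = 170
TEMPERATURES = [8, 15, 25, 30, 5, 12, 18, 22, 28, 35]

DEFECT_KEYS = (
    "adapter",          # missing or heavily mutated adapter B  -> step 1
    "internal_n",       # ambiguous base in the template        -> step 2
    "bad_barcode",      # unknown barcode                       -> step 3
    "singleton",        # unique sequence in one sample         -> step 4
    "chimera",          # spliced hybrid of two templates       -> step 4
    "off_length",       # template too short/long (paired)      -> step 5
    "primer_mutation",  # mutated reverse primer (paired)       -> step 6
    "low_quality",      # low mean quality on the insert        -> step 7
    "homopolymer",      # primer-run length slip (paired; benign)
    "poly_n",           # 3' poly-N tail (benign)
)

_DISCARD_STEP = {
    "adapter": "adapter_trim",
    "internal_n": "ambiguity_filter",
    "bad_barcode": "demultiplex",
    "singleton": "singleton_removal",
    "chimera": "singleton_removal",
    "off_length": "length_filter",
    "primer_mutation": "primer_trim",
    "low_quality": "quality_filter",
    "homopolymer": None,
    "poly_n": None,
    "clean": None,
}

_PAIRED = ("off_length", "primer_mutation", "homopolymer")


class SimulationError(ValueError):
    pass


@dataclass
class ReadTruth:
    read_id: str
    template_id: str
    sample_id: str
    defect: str | None
    discard_step: str | None


@dataclass
class GroundTruth:
    """Planted-defect bookkeeping; the oracle for a pipeline run."""

    reads: list[ReadTruth] = field(default_factory=list)

    def expected_discards(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for rt in self.reads:
            if rt.discard_step is not None:
                out.setdefault(rt.discard_step, set()).add(rt.read_id)
        return out

    def retained_ids(self) -> set[str]:
        return {rt.read_id for rt in self.reads if rt.discard_step is None}


@dataclass
class SimulatedDataset:
    reads: list[RawRead]
    specs: list[PrimerBarcodeSpec]
    sample_info: list[SampleInfo]
    truth: GroundTruth
    adapter_mode: str
    quality_threshold: float

    def pipeline_config(self, **overrides) -> PipelineConfig:
        """The config under which the ground truth is exact."""
        kwargs = dict(
            adapter_mode=self.adapter_mode,
            quality_threshold=self.quality_threshold,
            homopolymer_slack=3,
            remove_ambiguous=True,
            remove_singletons=True,
            single_sample_singleton_fallback="min_two_copies",
        )
        kwargs.update(overrides)
        return PipelineConfig(**kwargs)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "reads.fna",
            "qual": out / "reads.qual",
            "primer_barcode": out / "primer_barcode.tsv",
            "sample_info": out / "sample_info.tsv",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_fasta_qual(self.reads, str(paths["fasta"]), str(paths["qual"]))
        write_primer_barcode_file(self.specs, str(paths["primer_barcode"]))
        write_sample_info_file(self.sample_info, str(paths["sample_info"]))
        with open(paths["ground_truth"], "w") as fh:
            fh.write("read_id\ttemplate_id\tsample_id\tdefect\tdiscard_step\n")
            for rt in self.truth.reads:
                fh.write(
                    f"{rt.read_id}\t{rt.template_id}\t{rt.sample_id}\t"
                    f"{rt.defect or ''}\t{rt.discard_step or ''}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# independent low-level checkers (generator-side validation only)
# ---------------------------------------------------------------------------


def _fuzzy_hit(sequence: str, adapter: str, budget: int) -> bool:
    """Brute-force: does any full-length window match within ``budget``?"""
    alen = len(adapter)
    for start in range(len(sequence) - alen + 1):
        mism = sum(1 for a, b in zip(sequence[start : start + alen], adapter) if a != b)
        if mism <= budget:
            return True
    return False


def _prefix_at_end(sequence: str, adapter: str) -> bool:
    for k in range(4, len(adapter)):
        if sequence.endswith(adapter[:k]):
            return True
    return False


def _check_constants() -> None:
    if ADAPTER_B in RC_REVERSE or ADAPTER_B in FORWARD_PRIMER:
        raise SimulationError("adapter embedded in a primer constant")
    if _prefix_at_end(RC_REVERSE, ADAPTER_B):
        raise SimulationError("revcomp(reverse primer) ends with an adapter prefix")


_check_constants()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rand_template(rng: random.Random, length: int, taken: set[str]) -> str:
    # First base must differ from the forward primer's terminal run character
    # and the last base from the reverse-side run character, so homopolymer
    # run counting at the primer boundaries stays unambiguous.
    fwd_run_ch = FORWARD_PRIMER[-1]
    rev_run_ch = RC_REVERSE[0]
    for _ in range(1000):
        t = "".join(rng.choice("ACGT") for _ in range(length))
        if t[0] == fwd_run_ch or t[-1] == rev_run_ch:
            continue
        if ADAPTER_B in t or t in taken:
            continue
        taken.add(t)
        return t
    raise SimulationError("could not draw a valid template")


def _rand_barcodes(rng: random.Random, n: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(rng.choice("ACGT") for _ in range(BARCODE_LEN))
        if bc in seen:
            continue
        seen.add(bc)
        out.append(bc)
    return out


def _quals(rng, length, mu, sd, lo, hi):
    return [int(min(hi, max(lo, round(rng.gauss(mu, sd))))) for _ in range(length)]


def _mutate(rng: random.Random, sequence: str, pos: int) -> str:
    old = sequence[pos]
    new = rng.choice([b for b in "ACGT" if b != old])
    return sequence[:pos] + new + sequence[pos + 1 :]


def generate_dataset(
    n_reads: int = 1000,
    n_samples: int = 4,
    n_templates: int = 20,
    defect_rates: dict[str, float] | None = None,
    quality_profile: tuple[float, float] = (35.0, 5.0),
    seed: int = 0,
    adapter_mode: str = "perfect",
    quality_threshold: float = 25.0,
) -> SimulatedDataset:
    """Build a deterministic synthetic dataset with exact ground truth.

    ``defect_rates`` maps keys from :data:`DEFECT_KEYS` to fractions of
    ``n_reads``; unspecified defects default to 0 (a fully clean dataset).
    """
    if n_reads < 1 or n_samples < 1 or n_templates < 1:
        raise SimulationError("n_reads, n_samples and n_templates must be >= 1")
    if min(TEMPLATE_LEN_RANGE) <= len(FORWARD_PRIMER):
        raise SimulationError("templates must be longer than the primers")
    rates = dict.fromkeys(DEFECT_KEYS, 0.0)
    for key, value in (defect_rates or {}).items():
        if key not in rates:
            raise SimulationError(f"unknown defect key {key!r}")
        if not 0.0 <= value <= 1.0:
            raise SimulationError(f"rate for {key!r} outside [0, 1]")
        rates[key] = value

    rng = random.Random(seed)
    mu, sd = quality_profile
    q_lo_clean = int(quality_threshold) + 3  # guarantees mean >= threshold
    q_hi_lowq = max(2, int(quality_threshold) - 3)

    samples = [f"s{i + 1}" for i in range(n_samples)]
    barcodes = _rand_barcodes(rng, n_samples + 1)
    unknown_barcode = barcodes[-1]
    barcode_of = dict(zip(samples, barcodes))
    spec = PrimerBarcodeSpec(
        amplicon_id=AMPLICON_ID,
        forward_primer=FORWARD_PRIMER,
        reverse_primer=REVERSE_PRIMER,
        adapter_b=ADAPTER_B,
        min_len=MIN_LEN,
        max_len=MAX_LEN,
        barcode_map=dict(barcode_of),
    )
    sample_info = [
        SampleInfo(
            s,
            {
                "temperature": TEMPERATURES[i % len(TEMPERATURES)],
                "pH": round(6.5 + 0.3 * i, 2),
                "site": f"site{i + 1}",
            },
        )
        for i, s in enumerate(samples)
    ]

    # --- category counts -------------------------------------------------
    counts: dict[str, int] = {}
    for key in DEFECT_KEYS:
        c = int(round(rates[key] * n_reads))
        if key in _PAIRED and c % 2:
            c -= 1
        counts[key] = c
    n_special = sum(counts.values())
    if n_special > n_reads:
        raise SimulationError("defect rates sum past 1.0 after rounding")
    n_clean = n_reads - n_special
    needs_shared = counts["low_quality"] > 0 or counts["poly_n"] > 0 or n_clean > 0
    if needs_shared and n_clean < 2 and n_samples >= 1:
        raise SimulationError(
            "defect rates leave fewer than two clean reads, but shared "
            "templates need cross-sample support"
        )

    taken_templates: set[str] = set()
    n_shared = min(n_templates, n_clean // 2) if n_clean >= 2 else 0
    shared: list[tuple[str, str]] = []  # (template_id, sequence)
    for i in range(n_shared):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        shared.append((f"t{i + 1}", _rand_template(rng, length, taken_templates)))

    def pick_pair_samples() -> tuple[str, str]:
        if n_samples >= 2:
            a, b = rng.sample(samples, 2)
            return a, b
        return samples[0], samples[0]

    def pick_shared() -> tuple[str, str]:
        return shared[rng.randrange(len(shared))]

    fuzzy_budget = 1  # matches PipelineConfig default (per 10 bp)

    # Each entry: (template_id, sample, sequence, qual_region, defect)
    # qual_region: None for clean, or (start, end) span to degrade.
    pending: list[dict] = []

    def core_of(sample: str, template: str) -> str:
        return barcode_of[sample] + FORWARD_PRIMER + template + RC_REVERSE

    def add(template_id, sample, sequence, defect, lowq_span=None, clip_band=None):
        pending.append(
            dict(
                template_id=template_id,
                sample_id=sample,
                sequence=sequence,
                defect=defect,
                discard_step=_DISCARD_STEP[defect if defect else "clean"],
                lowq_span=lowq_span,
                clip_band=clip_band,
            )
        )

    # --- clean reads: guaranteed pair per shared template, rest random ---
    clean_budget = n_clean
    for i, (tid, tmpl) in enumerate(shared):
        sa, sb = pick_pair_samples()
        add(tid, sa, core_of(sa, tmpl) + ADAPTER_B, None)
        add(tid, sb, core_of(sb, tmpl) + ADAPTER_B, None)
        clean_budget -= 2
    for _ in range(clean_budget):
        tid, tmpl = pick_shared()
        s = rng.choice(samples)
        add(tid, s, core_of(s, tmpl) + ADAPTER_B, None)

    # --- poly-N tails (benign) -------------------------------------------
    for _ in range(counts["poly_n"]):
        tid, tmpl = pick_shared()
        s = rng.choice(samples)
        tail = "N" * rng.randint(3, 8)
        add(tid, s, core_of(s, tmpl) + ADAPTER_B + tail, "poly_n")

    # --- homopolymer run-length slips (benign, paired) --------------------
    for _ in range(counts["homopolymer"] // 2):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        tmpl = _rand_template(rng, length, taken_templates)
        tid = f"hp{len(taken_templates)}"
        slip = rng.choice([-1, 1, 2])  # run of 2 -> 1, 3 or 4; within slack 3
        run_ch = FORWARD_PRIMER[-1]
        run = len(FORWARD_PRIMER) - len(FORWARD_PRIMER.rstrip(run_ch))
        slipped_fwd = FORWARD_PRIMER[: len(FORWARD_PRIMER) - run] + run_ch * (run + slip)
        sa, sb = pick_pair_samples()
        for s in (sa, sb):
            seq = barcode_of[s] + slipped_fwd + tmpl + RC_REVERSE + ADAPTER_B
            add(tid, s, seq, "homopolymer")

    # --- step 1: adapter missing / heavily mutated ------------------------
    for i in range(counts["adapter"]):
        for _ in range(200):
            length = rng.randint(*TEMPLATE_LEN_RANGE)
            tmpl = _rand_template(rng, length, taken_templates)
            s = rng.choice(samples)
            core = core_of(s, tmpl)
            if i % 2 == 0:  # missing adapter
                seq = core
                if ADAPTER_B in seq or _prefix_at_end(seq, ADAPTER_B):
                    continue
                if adapter_mode == "fuzzy" and _fuzzy_hit(seq, ADAPTER_B, fuzzy_budget):
                    continue
            else:  # two mismatches in the adapter middle (beyond fuzzy budget)
                p1, p2 = rng.sample(range(2, 6), 2)
                mut = _mutate(rng, _mutate(rng, ADAPTER_B, p1), p2)
                seq = core + mut
                if ADAPTER_B in seq or _prefix_at_end(seq, ADAPTER_B):
                    continue
                if adapter_mode == "fuzzy" and _fuzzy_hit(seq, ADAPTER_B, fuzzy_budget):
                    continue
            add(f"ad{i}", s, seq, "adapter")
            break
        else:
            raise SimulationError("could not build an adapter-defect read")

    # --- step 2: internal N ----------------------------------------------
    for i in range(counts["internal_n"]):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        tmpl = _rand_template(rng, length, taken_templates)
        pos = rng.randrange(1, length - 1)
        tmpl_n = tmpl[:pos] + "N" + tmpl[pos + 1 :]
        s = rng.choice(samples)
        add(f"in{i}", s, barcode_of[s] + FORWARD_PRIMER + tmpl_n + RC_REVERSE + ADAPTER_B,
            "internal_n")

    # --- step 3: unknown barcode ------------------------------------------
    for i in range(counts["bad_barcode"]):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        tmpl = _rand_template(rng, length, taken_templates)
        s = rng.choice(samples)  # intended sample, never recovered
        seq = unknown_barcode + FORWARD_PRIMER + tmpl + RC_REVERSE + ADAPTER_B
        add(f"bb{i}", s, seq, "bad_barcode")

    # --- step 4: singletons and chimeras ----------------------------------
    for i in range(counts["singleton"]):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        tmpl = _rand_template(rng, length, taken_templates)
        s = rng.choice(samples)
        add(f"sg{i}", s, core_of(s, tmpl) + ADAPTER_B, "singleton")
    for i in range(counts["chimera"]):
        for _ in range(200):
            if len(shared) >= 2:
                (_, ta), (_, tb) = rng.sample(shared, 2)
            else:
                la = rng.randint(*TEMPLATE_LEN_RANGE)
                lb = rng.randint(*TEMPLATE_LEN_RANGE)
                ta = _rand_template(rng, la, taken_templates)
                tb = _rand_template(rng, lb, taken_templates)
            cut = rng.randint(25, min(len(ta), len(tb)) - 25)
            chim = ta[:cut] + tb[cut:]
            if chim in taken_templates or chim == ta or chim == tb:
                continue
            if chim[0] == FORWARD_PRIMER[-1] or chim[-1] == RC_REVERSE[0]:
                continue
            if ADAPTER_B in chim:
                continue
            taken_templates.add(chim)
            s = rng.choice(samples)
            add(f"ch{i}", s, core_of(s, chim) + ADAPTER_B, "chimera")
            break
        else:
            raise SimulationError("could not build a chimera read")

    # --- step 5: off-range length (paired) --------------------------------
    for i in range(counts["off_length"] // 2):
        length = SHORT_TEMPLATE_LEN if i % 2 == 0 else LONG_TEMPLATE_LEN
        tmpl = _rand_template(rng, length, taken_templates)
        tid = f"ol{i}"
        sa, sb = pick_pair_samples()
        for s in (sa, sb):
            add(tid, s, core_of(s, tmpl) + ADAPTER_B, "off_length")

    # --- step 6: mutated reverse primer (paired) --------------------------
    rc_tail_run = len(RC_REVERSE) - len(RC_REVERSE.rstrip(RC_REVERSE[-1]))
    for i in range(counts["primer_mutation"] // 2):
        length = rng.randint(*TEMPLATE_LEN_RANGE)
        tmpl = _rand_template(rng, length, taken_templates)
        tid = f"pm{i}"
        # a substitution inside the stem breaks the exact anchored match
        pos = rng.randrange(0, len(RC_REVERSE) - rc_tail_run)
        mut_rc = _mutate(rng, RC_REVERSE, pos)
        sa, sb = pick_pair_samples()
        for s in (sa, sb):
            seq = barcode_of[s] + FORWARD_PRIMER + tmpl + mut_rc + ADAPTER_B
            add(tid, s, seq, "primer_mutation")

    # --- step 7: low mean quality on the insert ---------------------------
    for i in range(counts["low_quality"]):
        tid, tmpl = pick_shared()
        s = rng.choice(samples)
        seq = core_of(s, tmpl) + ADAPTER_B
        start = BARCODE_LEN + len(FORWARD_PRIMER)
        add(tid, s, seq, "low_quality", lowq_span=(start, start + len(tmpl)))

    # --- finalize: shuffle, assign ids, draw qualities --------------------
    rng.shuffle(pending)
    reads: list[RawRead] = []
    truth = GroundTruth()
    tail_len = len(RC_REVERSE) + len(ADAPTER_B)
    for i, entry in enumerate(pending):
        read_id = f"r{i + 1:06d}"
        seq = entry["sequence"]
        quals = _quals(rng, len(seq), mu, sd, q_lo_clean, 40)
        # degrade the 3' tail (trimmed away before the quality step)
        body_end = len(seq) - len(seq) + len(seq.rstrip("N"))
        for j in range(max(0, body_end - tail_len), body_end):
            quals[j] = max(10, quals[j] - rng.randint(0, 8))
        for j in range(body_end, len(seq)):  # poly-N tail bases
            quals[j] = 5
        if entry["lowq_span"] is not None:
            a, b = entry["lowq_span"]
            quals[a:b] = _quals(rng, b - a, 15.0, 3.0, 2, q_hi_lowq)
        reads.append(RawRead(read_id, seq, quals))
        truth.reads.append(
            ReadTruth(
                read_id=read_id,
                template_id=entry["template_id"],
                sample_id=entry["sample_id"],
                defect=entry["defect"],
                discard_step=entry["discard_step"],
            )
        )

    return SimulatedDataset(
        reads=reads,
        specs=[spec],
        sample_info=sample_info,
        truth=truth,
        adapter_mode=adapter_mode,
        quality_threshold=quality_threshold,
    )
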