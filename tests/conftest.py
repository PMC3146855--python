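import pytest

from ampdb.datastore import Datastore
from ampdb.formats import PrimerBarcodeSpec, SampleInfo
from ampdb.simdata import generate_dataset

MIXED_RATES = {
    "adapter": 0.05,
    "internal_n": 0.04,
    "bad_barcode": 0.04,
    "singleton": 0.05,
    "chimera": 0.03,
    "off_length": 0.04,
    "primer_mutation": 0.04,
    "low_quality": 0.05,
    "homopolymer": 0.04,
    "poly_n": 0.03,
}


@pytest.fixture
def simple_spec():
    """One amplicon, two barcoded samples; small hand-checkable primers."""
    return PrimerBarcodeSpec(
        amplicon_id="amp1",
        forward_primer="GGCAA",
        reverse_primer="TTGC",  # revcomp GCAA appears at the 3' end
        adapter_b="CTGAG",
        min_len=10,
        max_len=60,
        barcode_map={"s1": "ACGT", "s2": "TGCA"},
    )


@pytest.fixture
def simple_samples():
    return [
        SampleInfo("s1", {"temperature": 15, "site": "lake"}),
        SampleInfo("s2", {"temperature": 25, "site": "pond"}),
    ]


@pytest.fixture(scope="session")
def mixed_dataset():
    """1,000-read synthetic run with every defect class planted."""
    return generate_dataset(
        n_reads=1000, n_samples=4, n_templates=20, defect_rates=MIXED_RATES, seed=11
    )


@pytest.fixture
def store():
    with Datastore(":memory:") as st:
        yield st
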