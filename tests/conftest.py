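import numpy as np
import pandas as pd
import pytest

from mpratools import (
    BarcodeCountSet,
    SampleSheet,
    SimulationSpec,
    generate_mpra,
    total_count_normalize,
)


@pytest.fixture
def tiny_counts() -> BarcodeCountSet:
    """Hand-built 4-barcode, 2-element, 3-sample dataset (B = 2 each)."""
    barcodes = ["bc1", "bc2", "bc3", "bc4"]
    samples = ["s1", "s2", "s3"]
    rna = pd.DataFrame(
        [[10, 20, 30], [5, 15, 25], [40, 50, 60], [35, 45, 55]],
        index=barcodes,
        columns=samples,
    )
    dna = pd.DataFrame(
        [[12, 18, 24], [8, 16, 20], [30, 40, 50], [25, 35, 45]],
        index=barcodes,
        columns=samples,
    )
    mapping = pd.Series(["e1", "e1", "e2", "e2"], index=barcodes)
    sheet = SampleSheet(sample_ids=samples, condition=["A", "A", "B"])
    return BarcodeCountSet(rna=rna, dna=dna, barcode_to_element=mapping, samples=sheet)


@pytest.fixture
def unit_scale_counts(tiny_counts) -> BarcodeCountSet:
    """tiny_counts with every scale factor forced to exactly 1."""
    counts = tiny_counts
    counts.rna_lib_sizes = pd.Series(1.0, index=counts.sample_ids)
    counts.dna_lib_sizes = pd.Series(1.0, index=counts.sample_ids)
    return total_count_normalize(counts, common_lib_size=1.0)


@pytest.fixture(scope="session")
def null_dataset():
    """Fully null overdispersed synthetic dataset, 300 elements, 4 vs 4."""
    spec = SimulationSpec(n_elements=300, barcodes_per_element=5, seed=42)
    counts, truth = generate_mpra(spec)
    return counts, truth


@pytest.fixture(scope="session")
def signal_dataset():
    """10% differential elements at log2 effect 1.0, 4 vs 4 samples."""
    # milder overdispersion than the null fixture: ranking ability is only
    # testable when per-test power is adequate (see docs/methods.md)
    spec = SimulationSpec(
        n_elements=500,
        barcodes_per_element=5,
        effect_fraction=0.1,
        effect_size=1.0,
        phi_d=0.1,
        phi_r=0.1,
        seed=7,
    )
    counts, truth = generate_mpra(spec)
    return counts, truth
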