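"""Element-level activity estimators.

Two summaries of barcode-level counts into one log2 activity measure per
element per sample are in common use.  The *aggregate* estimator sums
counts over barcodes first,

    a_agg = log2( (1 + (L/N_r) * sum_b R_b) / (1 + (L/N_d) * sum_b D_b) ),

effectively using barcodes to deepen the element's sequencing coverage.
The *average* estimator treats barcodes as technical replicates and
averages per-barcode log-ratios,

    a_av = (1/B) * sum_b log2( (R_b L/N_r + 1) / (D_b L/N_d + 1) ).

Both are defined for all non-negative counts thanks to the +1 offset
applied after library-size scaling.  A Taylor expansion of either formula
(see :mod:`mpratools.theory_power`) shows the average estimator carries
roughly B times the bias of the aggregate estimator, which is why the
aggregate form is the default throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import BarcodeCountSet, ElementActivityMatrix

__all__ = [
    "aggregate_estimator",
    "average_estimator",
    "aggregate_activity",
    "average_activity",
    "summarize_dataset",
]


def _scaled(counts: BarcodeCountSet) -> tuple[np.ndarray, np.ndarray]:
    """Barcode-level counts scaled to the common library size L."""
    r = counts.rna.to_numpy(dtype=float) * counts.rna_scale.to_numpy()
    d = counts.dna.to_numpy(dtype=float) * counts.dna_scale.to_numpy()
    return r, d


def _group_sum(mat: np.ndarray, counts: BarcodeCountSet) -> pd.DataFrame:
    frame = pd.DataFrame(mat, index=counts.rna.index, columns=counts.sample_ids)
    agg = frame.groupby(counts.barcode_to_element.to_numpy(), sort=False).sum()
    return agg.reindex(counts.element_ids)


def aggregate_activity(counts: BarcodeCountSet) -> pd.DataFrame:
    """Aggregate-estimator log2 activities, elements x samples."""
    r, d = _scaled(counts)
    r_sum = _group_sum(r, counts)
    d_sum = _group_sum(d, counts)
    return np.log2(1.0 + r_sum) - np.log2(1.0 + d_sum)


def average_activity(counts: BarcodeCountSet) -> pd.DataFrame:
    """Average-estimator log2 activities, elements x samples."""
    r, d = _scaled(counts)
    ratios = pd.DataFrame(
        np.log2(r + 1.0) - np.log2(d + 1.0),
        index=counts.rna.index,
        columns=counts.sample_ids,
    )
    avg = ratios.groupby(counts.barcode_to_element.to_numpy(), sort=False).mean()
    return avg.reindex(counts.element_ids)


def aggregate_estimator(counts: BarcodeCountSet, element, sample) -> float:
    """Aggregate-estimator log2 activity for a single (element, sample)."""
    return float(_single(aggregate_activity, counts, element, sample))


def average_estimator(counts: BarcodeCountSet, element, sample) -> float:
    """Average-estimator log2 activity for a single (element, sample)."""
    return float(_single(average_activity, counts, element, sample))


def _single(fn, counts, element, sample):
    table = fn(counts)
    if element not in table.index:
        raise KeyError(f"unknown element: {element!r}")
    return table.loc[element, sample]


def summarize_dataset(counts: BarcodeCountSet, estimator: str = "aggregate") -> ElementActivityMatrix:
    """Apply the chosen estimator to every (element, sample).

    Also records, per observation, the log2 aggregated library-size-
    corrected DNA abundance log2(1 + (L/N_d) * sum_b D_b) and its
    across-sample mean — the x-axis of the copy-number-variance trend.
    """
    if estimator == "aggregate":
        activity = aggregate_activity(counts)
    elif estimator == "average":
        activity = average_activity(counts)
    else:
        raise ValueError(f"estimator must be 'aggregate' or 'average', got {estimator!r}")
    _, d = _scaled(counts)
    obs_log2_dna = np.log2(1.0 + _group_sum(d, counts))
    return ElementActivityMatrix(
        activity=activity,
        estimator=estimator,
        mean_log2_dna=obs_log2_dna.mean(axis=1),
        common_lib_size=float(counts.common_lib_size),
        obs_log2_dna=obs_log2_dna,
    )
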