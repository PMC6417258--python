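"""Calibration and comparison metrics for differential-activity methods.

Given p values from data known to be fully null (e.g. produced by
:func:`mpratools.simulate.null_resample`), :func:`empirical_type1` reports
the fraction of rejections at each nominal level — the empirical type I
error rate.  :func:`prop_true_null` estimates the proportion pi0 of truly
null hypotheses from an observed p-value distribution via a histogram
local-false-discovery-rate scheme, and :func:`estimate_fdr` combines pi0,
the empirical error rate and the rejection count into an estimated false
discovery rate:

    FDR(alpha) = pi0 * m * type1_rate(alpha) / n_rejected(alpha).

Two classical baselines are provided for comparison: a per-element t test
on aggregate-estimator activities and Fisher's exact test on counts pooled
into a 2x2 (RNA/DNA x group) table.  The exact test ignores both
biological replication and overdispersion, which is why its empirical type
I error on overdispersed count data is badly inflated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BarcodeCountSet, ElementActivityMatrix, MpraFormatError

__all__ = [
    "empirical_type1",
    "prop_true_null",
    "estimate_fdr",
    "rejections_vs_error",
    "ttest_baseline",
    "fisher_baseline",
    "default_alpha_grid",
]


def default_alpha_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced nominal levels from 1e-6 to 0.1."""
    return np.logspace(-6, -1, n_points)


def empirical_type1(p_values, alphas=None) -> pd.DataFrame:
    """Rejection rate of truly null p values at each nominal level.

    Returns a table with columns ``alpha``, ``rate``, ``n_rejected`` and
    ``m`` (the number of tests), so rates can be reported as "x/m".
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise MpraFormatError("no p values supplied")
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    counts = np.array([(p <= a).sum() for a in alphas])
    return pd.DataFrame(
        {"alpha": alphas, "rate": counts / p.size, "n_rejected": counts, "m": p.size}
    )


def prop_true_null(p_values) -> float:
    """Local-fdr estimate of the proportion of true null hypotheses.

    Each sorted p value p_(r) gets a local false-discovery proxy
    q_r = min(n * p_(r) / r, 1) — its Benjamini-Hochberg adjusted value —
    and pi0 is the rank-weighted average 2 * sum(r * q_r) / (n * (n + 1)),
    which up-weights the large (null-dominated) p values.  For uniform p
    the q_r concentrate at 1 and the estimate approaches 1; alternatives
    piling up near 0 pull it down in proportion to their mass.  Clipped to
    (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise MpraFormatError(f"pi0 estimation needs >= 100 p values, got {p.size}")
    n = p.size
    ranks = np.arange(1, n + 1)
    q = np.minimum(n * np.sort(p) / ranks, 1.0)
    pi0 = 2.0 * float(np.sum(ranks * q)) / (n * (n + 1))
    return min(max(pi0, 1e-12), 1.0)


def estimate_fdr(pi0: float, m: int, type1_rate: float, n_rejected: int) -> float:
    """Estimated FDR = pi0 * m * type1_rate / n_rejected, clipped to [0, 1].

    Returns NaN when nothing is rejected (the ratio is undefined).
    """
    if not 0.0 <= pi0 <= 1.0:
        raise MpraFormatError("pi0 must be in [0, 1]")
    if n_rejected == 0:
        return float("nan")
    return float(min(max(pi0 * m * type1_rate / n_rejected, 0.0), 1.0))


def rejections_vs_error(p_null, p_obs, alphas=None) -> pd.DataFrame:
    """Pair empirical error rates (null data) with rejection counts.

    For each nominal level, the x coordinate is the empirical type I error
    estimated from ``p_null`` and the y coordinate the number of rejections
    in ``p_obs`` — the fair power comparison across methods whose nominal
    levels are calibrated differently.
    """
    if alphas is None:
        alphas = default_alpha_grid()
    null_table = empirical_type1(p_null, alphas)
    p = np.asarray(p_obs, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise MpraFormatError("no observed p values supplied")
    n_rej = np.array([(p <= a).sum() for a in np.atleast_1d(alphas)])
    return pd.DataFrame(
        {
            "alpha": null_table["alpha"],
            "observed_type1": null_table["rate"],
            "n_rejections": n_rej,
        }
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _two_groups(condition: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    levels = list(pd.unique(condition))
    if len(levels) != 2:
        raise MpraFormatError(f"expected 2 groups, found {levels}")
    return condition == levels[0], condition == levels[1], levels


def ttest_baseline(
    activity: ElementActivityMatrix | pd.DataFrame,
    condition,
    paired: bool = False,
    block=None,
) -> pd.Series:
    """Classical two-sided t test per element on activity measures.

    Unpaired: pooled-variance two-sample t.  Paired: one-sample t on the
    within-block differences (``block`` pairs samples across the groups).
    Elements whose statistic is undefined (zero variance) get NaN.
    """
    values = activity.activity if isinstance(activity, ElementActivityMatrix) else activity
    index = values.index
    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition)
    g1, g2, _ = _two_groups(condition)
    if paired:
        if block is None:
            raise MpraFormatError("paired t test requires block assignments")
        block = np.asarray(block)
        order1 = np.where(g1)[0][np.argsort(block[g1], kind="stable")]
        order2 = np.where(g2)[0][np.argsort(block[g2], kind="stable")]
        if len(order1) != len(order2) or len(order1) < 2:
            raise MpraFormatError("paired t test needs >= 2 complete pairs")
        diffs = values[:, order1] - values[:, order2]
        degenerate = diffs.var(axis=1, ddof=1) == 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(values[:, order1], values[:, order2], axis=1)
    else:
        if g1.sum() < 2 or g2.sum() < 2:
            raise MpraFormatError("unpaired t test needs >= 2 samples per group")
        degenerate = (values[:, g1].var(axis=1, ddof=1) == 0.0) & (
            values[:, g2].var(axis=1, ddof=1) == 0.0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(values[:, g1], values[:, g2], axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance: statistic undefined, not "infinitely
    # significant" — except when the means are equal too (t = 0/0 handled
    # by scipy as nan anyway)
    mean_diff = values[:, g1].mean(axis=1) - values[:, g2].mean(axis=1)
    p[degenerate & (mean_diff != 0.0)] = np.nan
    if np.isnan(p).any():
        warnings.warn(
            f"{int(np.isnan(p).sum())} elements with undefined t statistic", stacklevel=2
        )
    return pd.Series(p, index=index, name="p_value")


def fisher_baseline(counts: BarcodeCountSet, condition=None) -> pd.Series:
    """Fisher's exact test per element on pooled 2x2 count tables.

    RNA and DNA counts are summed over samples within each group, forming a
    (RNA/DNA) x group table per element.  All-zero tables get p = 1 with a
    warning.  Pooling discards replicate-to-replicate variability, so this
    test is anticonservative on overdispersed data.
    """
    if condition is None:
        condition = counts.samples.condition.to_numpy()
    condition = np.asarray(condition)
    g1, g2, _ = _two_groups(condition)
    rna = counts.aggregated("rna").to_numpy(dtype=float)
    dna = counts.aggregated("dna").to_numpy(dtype=float)
    table = np.stack(
        [
            np.stack([rna[:, g1].sum(axis=1), rna[:, g2].sum(axis=1)], axis=1),
            np.stack([dna[:, g1].sum(axis=1), dna[:, g2].sum(axis=1)], axis=1),
        ],
        axis=1,
    ).astype(np.int64)
    p = np.empty(table.shape[0])
    n_zero = 0
    for idx in range(table.shape[0]):
        if table[idx].sum() == 0:
            p[idx] = 1.0
            n_zero += 1
            continue
        p[idx] = stats.fisher_exact(table[idx])[1]
    if n_zero:
        warnings.warn(f"{n_zero} elements with all-zero tables; p set to 1", stacklevel=2)
    return pd.Series(p, index=counts.element_ids, name="p_value")
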