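"""Synthetic MPRA data and the null-resampling type I error simulator.

:func:`generate_mpra` draws barcode-level counts with the structure assumed
throughout the package: element copy numbers (DNA read fractions) are
log-normal across elements, per-barcode DNA counts are negative binomial
with Var = (1 + phi_d mu) mu, and RNA counts are negative binomial around
mu_d * 2^a * (N_r / N_d) where a is the element's log2 activity.  Because
the count noise of a log-ratio shrinks with the counts, the generated data
reproduce the empirical copy-number-variance trend without any explicit
variance model.  Optional block effects (shared activity perturbations for
the samples of a block) induce a target within-block correlation for
paired designs.

:func:`null_resample` turns a real or synthetic two-group dataset into a
matched fully-null dataset by standardizing the element-level log-ratios
within each group, permuting the standardized residuals across samples
within each element, restoring the saved element SDs and group-1 means for
both groups, and reconstructing RNA counts from the untouched DNA counts.
The result preserves each element's location, scale and count magnitudes
while removing any group difference, which is what makes it suitable for
estimating empirical type I error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    BarcodeCountSet,
    MpraFormatError,
    SampleSheet,
    total_count_normalize,
)
from .summarize import aggregate_activity
from .theory_power import NBTheoryParams, to_log2_var, var_aggregate

__all__ = ["SimulationSpec", "generate_mpra", "null_resample"]

# floor applied to zero residual SDs before standardizing in null_resample
_SD_FLOOR = 1e-8


@dataclass
class SimulationSpec:
    """Generation parameters for a synthetic two-group MPRA dataset.

    Defaults describe a typical mid-size experiment: 1000 elements with 10
    barcodes each, 4 replicates per condition, library sizes of 1e7 reads
    for both RNA and DNA, log-normal copy numbers (sdlog 0.7), baseline
    log2 activities normal around 0.8 (sd 0.5), and strong negative-
    binomial overdispersion phi = 2 in both libraries.  ``effect_fraction``
    of the elements receive a log2 shift of ``effect_size`` in group 2;
    ``within_block_correlation`` > 0 adds shared block effects that pair
    sample i of group 1 with sample i of group 2.
    """

    n_elements: int = 1000
    barcodes_per_element: int = 10
    samples_per_group: tuple[int, int] = (4, 4)
    dna_lib_size: float = 1e7
    rna_lib_size: float = 1e7
    copy_number_sdlog: float = 0.7
    activity_mean: float = 0.8
    activity_sd: float = 0.5
    effect_fraction: float = 0.0
    effect_size: float = 1.0
    phi_d: float = 2.0
    phi_r: float = 2.0
    within_block_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_elements, self.barcodes_per_element) < 1:
            raise MpraFormatError("need at least one element and one barcode")
        if min(self.samples_per_group) < 1:
            raise MpraFormatError("each group needs at least one sample")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise MpraFormatError("effect_fraction must be in [0, 1]")
        if self.phi_d < 0 or self.phi_r < 0:
            raise MpraFormatError("overdispersions must be non-negative")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise MpraFormatError("within_block_correlation must be in [0, 1)")
        if min(self.dna_lib_size, self.rna_lib_size) <= 0:
            raise MpraFormatError("library sizes must be positive")


def _nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Counts with mean ``mean`` and variance (1 + phi * mean) * mean."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def generate_mpra(spec: SimulationSpec) -> tuple[BarcodeCountSet, pd.DataFrame]:
    """Draw a barcode-level dataset and its per-element truth table.

    Returns the counts plus a table recording each element's true log2
    activity in both groups, its DNA read fraction, and whether it is
    differential.  Bit-identical for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_e = spec.n_elements
    b = spec.barcodes_per_element
    n1, n2 = spec.samples_per_group
    n_samples = n1 + n2
    group = np.array(["A"] * n1 + ["B"] * n2)

    # element copy numbers: log-normal read fractions with mean 1/n_elements
    sdlog = spec.copy_number_sdlog
    p_d = rng.lognormal(np.log(1.0 / n_e) - 0.5 * sdlog**2, sdlog, size=n_e)

    a1 = rng.normal(spec.activity_mean, spec.activity_sd, size=n_e)
    differential = np.zeros(n_e, dtype=bool)
    n_diff = int(round(spec.effect_fraction * n_e))
    if n_diff:
        differential[rng.choice(n_e, size=n_diff, replace=False)] = True
    a2 = a1 + np.where(differential, spec.effect_size, 0.0)
    a_by_group = np.where(group == "A", a1[:, None], a2[:, None])  # elements x samples

    mu_d = (spec.dna_lib_size * p_d / b)[:, None, None]  # per barcode, per sample

    # optional block effects: a shared activity perturbation for the two
    # samples of each block, scaled so the implied within-block correlation
    # of the aggregate log-ratio matches the requested value
    rho = spec.within_block_correlation
    blocks = None
    if rho > 0.0:
        if n1 != n2:
            raise MpraFormatError("block correlation requires equal group sizes")
        blocks = np.array([f"blk{i + 1}" for i in range(n1)] * 2)
        count_var = np.array(
            [
                to_log2_var(
                    var_aggregate(
                        NBTheoryParams(
                            N_r=spec.rna_lib_size,
                            N_d=spec.dna_lib_size,
                            L=spec.dna_lib_size,
                            p_r=p_d[e] * 2.0 ** a1[e] / b,
                            p_d=p_d[e] / b,
                            k_r=1.0 + spec.phi_r * spec.rna_lib_size * p_d[e] * 2.0 ** a1[e] / b,
                            k_d=1.0 + spec.phi_d * mu_d[e, 0, 0],
                            B=b,
                        )
                    )
                )
                for e in range(n_e)
            ]
        )
        block_sd = np.sqrt(rho / (1.0 - rho) * count_var)
        block_effect = rng.normal(0.0, 1.0, size=(n_e, n1)) * block_sd[:, None]
        block_idx = np.concatenate([np.arange(n1), np.arange(n2)])
        a_by_group = a_by_group + block_effect[:, block_idx]

    dna = _nb(rng, np.broadcast_to(mu_d, (n_e, b, n_samples)), spec.phi_d)
    mu_r = mu_d * 2.0 ** a_by_group[:, None, :] * (spec.rna_lib_size / spec.dna_lib_size)
    rna = _nb(rng, np.broadcast_to(mu_r, (n_e, b, n_samples)), spec.phi_r)

    element_ids = [f"elem{e + 1:05d}" for e in range(n_e)]
    barcode_ids = [f"elem{e + 1:05d}_bc{j + 1:02d}" for e in range(n_e) for j in range(b)]
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    mapping = pd.Series(np.repeat(element_ids, b), index=barcode_ids)
    samples = SampleSheet(sample_ids=sample_ids, condition=group, block=blocks)
    counts = BarcodeCountSet(
        rna=pd.DataFrame(rna.reshape(n_e * b, n_samples), index=barcode_ids, columns=sample_ids),
        dna=pd.DataFrame(dna.reshape(n_e * b, n_samples), index=barcode_ids, columns=sample_ids),
        barcode_to_element=mapping,
        samples=samples,
    )
    truth = pd.DataFrame(
        {
            "a_group1": a1,
            "a_group2": a2,
            "differential": differential,
            "p_d": p_d,
        },
        index=pd.Index(element_ids, name="element"),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# null resampling
# ---------------------------------------------------------------------------

def _allocate_integer(total: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Split integer totals over barcodes by largest-remainder rounding."""
    raw = total * fractions
    base = np.floor(raw)
    short = np.round(total - base.sum(axis=0)).astype(int)
    remainder = raw - base
    out = base.astype(int)
    for j, extra in enumerate(short):
        if extra > 0:
            order = np.argsort(-remainder[:, j], kind="stable")
            out[order[:extra], j] += 1
    return out


def null_resample(
    counts: BarcodeCountSet,
    seed: int = 0,
    paired: bool = False,
) -> BarcodeCountSet:
    """Build a matched fully-null dataset from a two-group dataset.

    Steps: (1) compute element-level log-ratio activities; (2) save the
    element-wise residual SDs after group-centering and the group-1 means;
    (3) standardize the log-ratios within each group to mean 0, variance 1;
    (4) permute the standardized residuals without replacement within each
    element across all samples — the cross-group mixing is what turns the
    (now identically standardized) groups into a null with realistic
    between-group sampling noise; for paired designs the two samples of a
    block move jointly between blocks, preserving the within-block
    correlation structure; (5) rescale by the saved SDs and add the group-1
    means to all samples, making the two groups identically distributed;
    (6) keep the original DNA counts; (7) reconstruct RNA counts from the
    original DNA and the resampled log-ratios, rounded to non-negative
    integers; (8) return DNA plus the new RNA.

    Per element, the permutation preserves the pooled multiset of
    standardized residuals exactly, so the mean over *all* samples equals
    the saved group-1 mean up to RNA rounding; individual group means
    scatter around it with permutation noise but carry no systematic
    group difference.

    Permutations are drawn from a stream keyed by ``(seed, element index)``
    so results do not depend on element order.  The original RNA library
    sizes are carried over so the scale factors used for reconstruction
    remain attached to the output.
    """
    condition = counts.samples.condition.to_numpy()
    levels = list(pd.unique(condition))
    if len(levels) != 2:
        raise MpraFormatError(f"null resampling needs 2 groups, found {levels}")
    g1 = condition == levels[0]
    g2 = condition == levels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise MpraFormatError("each group needs at least 2 samples")
    if not counts.is_normalized:
        counts = total_count_normalize(counts)

    activity = aggregate_activity(counts)  # elements x samples, log2
    values = activity.to_numpy(dtype=float)
    n = values.shape[1]

    mean1 = values[:, g1].mean(axis=1)
    mean2 = values[:, g2].mean(axis=1)
    centered = values.copy()
    centered[:, g1] -= mean1[:, None]
    centered[:, g2] -= mean2[:, None]
    resid_sd = np.sqrt((centered**2).sum(axis=1) / (n - 2))
    resid_sd = np.maximum(resid_sd, _SD_FLOOR)

    z = np.empty_like(values)
    for g in (g1, g2):
        group_sd = np.maximum(values[:, g].std(axis=1, ddof=1), _SD_FLOOR)
        z[:, g] = centered[:, g] / group_sd[:, None]

    block_members = None
    if paired:
        if counts.samples.block is None:
            raise MpraFormatError("paired resampling requires a block column")
        blocks = counts.samples.block.to_numpy()
        block_members = [np.where(blocks == blk)[0] for blk in pd.unique(blocks)]

    z_perm = np.empty_like(z)
    for idx in range(z.shape[0]):
        rng = np.random.default_rng([seed, idx])
        if block_members is None:
            z_perm[idx] = z[idx, rng.permutation(n)]
        else:
            order = rng.permutation(len(block_members))
            for dest, src in zip(block_members, (block_members[k] for k in order)):
                z_perm[idx, dest] = z[idx, src]

    new_activity = mean1[:, None] + z_perm * resid_sd[:, None]

    # reconstruct RNA: invert the aggregate estimator at element level,
    # then spread over barcodes proportional to the original RNA fractions
    agg_dna = counts.aggregated("dna").to_numpy(dtype=float)
    dna_scaled = agg_dna * counts.dna_scale.to_numpy()
    rna_scale = counts.rna_scale.to_numpy()
    elem_rna = np.round((2.0**new_activity * (1.0 + dna_scaled) - 1.0) / rna_scale)
    elem_rna = np.maximum(elem_rna, 0.0)

    rna_raw = counts.rna.to_numpy(dtype=float)
    elem_of_barcode = counts.barcode_to_element.to_numpy()
    new_rna = np.empty_like(rna_raw)
    element_ids = counts.element_ids
    elem_index = {e: i for i, e in enumerate(element_ids)}
    for e, rows in pd.Series(range(len(elem_of_barcode))).groupby(elem_of_barcode, sort=False):
        rows = rows.to_numpy()
        sub = rna_raw[rows]
        totals = sub.sum(axis=0)
        fractions = np.where(
            totals > 0, sub / np.where(totals > 0, totals, 1.0), 1.0 / len(rows)
        )
        new_rna[rows] = _allocate_integer(elem_rna[elem_index[e]], fractions)

    return BarcodeCountSet(
        rna=pd.DataFrame(new_rna.astype(int), index=counts.rna.index, columns=counts.sample_ids),
        dna=counts.dna.copy(),
        barcode_to_element=counts.barcode_to_element,
        samples=counts.samples,
        rna_lib_sizes=counts.rna_lib_sizes,
        dna_lib_sizes=counts.dna_lib_sizes,
        common_lib_size=counts.common_lib_size,
    )
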