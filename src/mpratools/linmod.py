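"""Precision-weighted linear models with empirical-Bayes moderated t tests.

Each element's log2 activity profile across samples is fit with a weighted
linear model y = X b + e, Var(e_i) = s^2 / w_i, where the weights come from
the copy-number-variance trend (:mod:`mpratools.variance_weights`).
Residual variances are then shrunk toward a common prior fitted across all
elements: assuming s_e^2 | sigma_e^2 follows a scaled chi-square on d_e
degrees of freedom and sigma_e^2 a scaled inverse chi-square prior
(d0, s0^2), the posterior variance is

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated t statistic b / (se_unscaled * sqrt(s2_post)) has d0 + d
degrees of freedom.  Paired designs (e.g. two alleles measured in the same
transfection) are handled with a single consensus within-block correlation
shared across elements and generalized least squares under a
block-compound-symmetric working covariance.

:func:`mpralm` chains the whole pipeline: normalize -> summarize ->
filter -> weight curve -> (consensus correlation) -> per-element fits ->
variance moderation -> moderated t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    BarcodeCountSet,
    ElementActivityMatrix,
    MpraFormatError,
    SampleSheet,
    filter_elements,
    total_count_normalize,
)
from .summarize import summarize_dataset
from .variance_weights import fit_weight_curve

__all__ = [
    "DesignMatrix",
    "FitResult",
    "two_group_design",
    "wls_fit",
    "gls_fit",
    "squeeze_var",
    "moderated_t",
    "estimate_consensus_correlation",
    "fit_elements",
    "mpralm",
    "top_table",
]

# variances below this floor are clipped before taking logs in the
# moment-matching fit of the variance prior
_VAR_FLOOR = 1e-12

# symmetric trimming fraction for the consensus-correlation average on the
# Fisher z scale
_CONSENSUS_TRIM = 0.15


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """A samples x coefficients design with optional block structure."""

    matrix: np.ndarray
    coefficient_names: list[str]
    block: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise MpraFormatError("design matrix must be 2-dimensional")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise MpraFormatError("design matrix is rank deficient")
        if self.block is not None:
            self.block = np.asarray(self.block)
            if len(self.block) != self.matrix.shape[0]:
                raise MpraFormatError("block length does not match design rows")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]

    @property
    def df_residual(self) -> int:
        return self.n_samples - self.n_coefficients


def two_group_design(samples: SampleSheet, use_block: bool = False) -> DesignMatrix:
    """Intercept + group-indicator design from a two-level condition."""
    levels = list(pd.unique(samples.condition))
    if len(levels) != 2:
        raise MpraFormatError(f"expected 2 condition levels, found {levels}")
    indicator = (samples.condition.to_numpy() == levels[1]).astype(float)
    matrix = np.column_stack([np.ones_like(indicator), indicator])
    block = None
    if use_block:
        if samples.block is None:
            raise MpraFormatError("paired analysis requested but no block column")
        block = samples.block.to_numpy()
    return DesignMatrix(
        matrix=matrix,
        coefficient_names=["intercept", f"{levels[1]}_vs_{levels[0]}"],
        block=block,
    )


# ---------------------------------------------------------------------------
# per-element least squares
# ---------------------------------------------------------------------------

def wls_fit(activity_row, weights_row, design):
    """Weighted least squares for one element.

    Returns ``(coefficients, stdev_unscaled, sigma, df_residual,
    cov_unscaled)`` where ``stdev_unscaled`` are the square roots of the
    diagonal of (X' W X)^-1 — standard errors are
    ``stdev_unscaled * sigma`` — and ``sigma`` is the square root of the
    weighted residual mean square.
    """
    matrix = np.asarray(getattr(design, "matrix", design), dtype=float)
    y = np.asarray(activity_row, dtype=float)
    w = np.asarray(weights_row, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise MpraFormatError("weights must be positive and finite")
    sw = np.sqrt(w)
    xw = matrix * sw[:, None]
    yw = y * sw
    coef, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    if rank < matrix.shape[1]:
        raise MpraFormatError("design matrix is rank deficient")
    cov_unscaled = np.linalg.inv(xw.T @ xw)
    resid = yw - xw @ coef
    df = matrix.shape[0] - matrix.shape[1]
    sigma = math.sqrt(float(resid @ resid) / df) if df > 0 else np.nan
    return coef, np.sqrt(np.diag(cov_unscaled)), sigma, df, cov_unscaled


def _block_correlation_matrix(block: np.ndarray, rho: float) -> np.ndarray:
    same = np.equal.outer(block, block)
    corr = np.where(same, rho, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def gls_fit(activity_row, weights_row, design, block=None, rho: float = 0.0):
    """Generalized least squares under block-compound-symmetric correlation.

    Observation variances are 1/w_i and observations sharing a block have
    correlation ``rho``.  With ``rho = 0`` this reduces exactly to
    :func:`wls_fit`.  Same return contract as :func:`wls_fit`.
    """
    if not -1.0 < rho < 1.0:
        raise MpraFormatError(f"correlation must be in (-1, 1), got {rho}")
    if block is None:
        block = getattr(design, "block", None)
    if rho == 0.0 or block is None:
        return wls_fit(activity_row, weights_row, design)
    matrix = np.asarray(getattr(design, "matrix", design), dtype=float)
    y = np.asarray(activity_row, dtype=float)
    w = np.asarray(weights_row, dtype=float)
    inv_sqrt_w = 1.0 / np.sqrt(w)
    cov = _block_correlation_matrix(np.asarray(block), rho) * np.outer(inv_sqrt_w, inv_sqrt_w)
    chol = np.linalg.cholesky(cov)
    # whiten: solve T z = y with T lower-triangular, then OLS on whitened data
    from scipy.linalg import solve_triangular

    yt = solve_triangular(chol, y, lower=True)
    xt = solve_triangular(chol, matrix, lower=True)
    coef, _, rank, _ = np.linalg.lstsq(xt, yt, rcond=None)
    if rank < matrix.shape[1]:
        raise MpraFormatError("design matrix is rank deficient")
    cov_unscaled = np.linalg.inv(xt.T @ xt)
    resid = yt - xt @ coef
    df = matrix.shape[0] - matrix.shape[1]
    sigma = math.sqrt(float(resid @ resid) / df) if df > 0 else np.nan
    return coef, np.sqrt(np.diag(cov_unscaled)), sigma, df, cov_unscaled


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2, df):
    """Fit the scaled inverse-chi-square variance prior and shrink.

    Hyperparameters (d0, s0^2) are estimated by matching the first two
    moments of log s^2, whose distribution under the model is a shifted
    log-F; this is the standard digamma/trigamma moment fit.  Returns
    ``(df_prior, s2_prior, s2_post)``.  When the observed log-variances are
    no more dispersed than the chi-square sampling noise alone, the prior
    degrees of freedom are infinite and every posterior variance equals the
    prior value.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    ok = np.isfinite(s2) & (df >= 1)
    if ok.sum() < 2:
        raise MpraFormatError("variance moderation needs >= 2 elements with df >= 1")
    s2_ok = np.maximum(s2[ok], _VAR_FLOOR)
    df_ok = df[ok]
    if np.ptp(np.log(s2_ok)) == 0.0:
        # all variances identical: point-mass prior at the common value
        d0, s0_sq = np.inf, float(s2_ok[0])
    else:
        z = np.log(s2_ok)
        e = z - special.digamma(df_ok / 2.0) + np.log(df_ok / 2.0)
        e_mean = float(e.mean())
        e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df_ok / 2.0)))
        if e_var > 0:
            d0 = 2.0 * _trigamma_inverse(e_var)
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0, s0_sq = np.inf, float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_filled = np.where(ok, np.maximum(s2, _VAR_FLOOR), 0.0)
        df_filled = np.where(ok, df, 0.0)
        s2_post = (d0 * s0_sq + df_filled * s2_filled) / (d0 + df_filled)
    return d0, s0_sq, s2_post


# ---------------------------------------------------------------------------
# consensus correlation
# ---------------------------------------------------------------------------

def estimate_consensus_correlation(
    activity: ElementActivityMatrix | pd.DataFrame,
    weights: pd.DataFrame | np.ndarray,
    design: DesignMatrix,
    block=None,
) -> float:
    """Single within-block correlation shared across elements.

    Per element, the weighted (whitened by sqrt-weight) residuals of the
    fixed-effect fit are used to form a moment estimate of the within-block
    correlation: the mean cross-product over within-block pairs divided by
    the mean squared residual.  Per-element estimates are combined on the
    Fisher z scale by a symmetric trimmed mean and transformed back.
    """
    if block is None:
        block = design.block
    if block is None:
        raise MpraFormatError("consensus correlation requires a block assignment")
    block = np.asarray(block)
    values = activity.activity if isinstance(activity, ElementActivityMatrix) else activity
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    matrix = design.matrix
    n = matrix.shape[0]
    pair_i, pair_j = np.where(np.triu(np.equal.outer(block, block), k=1))
    if len(pair_i) == 0:
        raise MpraFormatError("no within-block sample pairs")
    rhos = np.full(values.shape[0], np.nan)
    for idx in range(values.shape[0]):
        coef, _, _, df, _ = wls_fit(values[idx], w[idx], matrix)
        resid = (values[idx] - matrix @ coef) * np.sqrt(w[idx])
        ms = float(resid @ resid) / n
        if ms <= 0 or df < 1:
            continue
        cross = float(np.mean(resid[pair_i] * resid[pair_j]))
        rhos[idx] = cross / ms
    rhos = rhos[np.isfinite(rhos)]
    if len(rhos) == 0:
        raise MpraFormatError("no usable elements for consensus correlation")
    z = np.arctanh(np.clip(rhos, -0.99, 0.99))
    consensus = float(np.tanh(stats.trim_mean(z, _CONSENSUS_TRIM)))
    return min(max(consensus, -0.99), 0.99)


# ---------------------------------------------------------------------------
# fitting all elements + moderated inference
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Per-element fit summaries and empirical-Bayes moderated statistics."""

    element_ids: list
    coefficient_names: list[str]
    coefficients: np.ndarray  # elements x p
    stdev_unscaled: np.ndarray  # elements x p
    cov_unscaled: np.ndarray  # elements x p x p
    sigma: np.ndarray
    df_residual: np.ndarray
    s2_prior: float | None = None
    df_prior: float | None = None
    s2_post: np.ndarray | None = None
    t_moderated: np.ndarray | None = None
    p_value: np.ndarray | None = None
    df_total: np.ndarray | None = None
    tested: np.ndarray | None = None  # contrast vector used for t/p
    consensus_correlation: float | None = None
    weight_model = None
    filter_report = None

    @property
    def logFC(self) -> np.ndarray:
        if self.tested is None:
            raise MpraFormatError("no coefficient tested yet")
        return self.coefficients @ self.tested


def fit_elements(
    activity: ElementActivityMatrix | pd.DataFrame,
    weights,
    design: DesignMatrix,
    rho: float = 0.0,
) -> FitResult:
    """Fit every element with WLS (or GLS when ``rho != 0`` and blocks exist)."""
    values = activity.activity if isinstance(activity, ElementActivityMatrix) else activity
    index = list(values.index) if hasattr(values, "index") else list(range(len(values)))
    values = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != values.shape:
        w = np.broadcast_to(w, values.shape)
    n_elem, _ = values.shape
    p = design.n_coefficients
    coefs = np.empty((n_elem, p))
    stdev = np.empty((n_elem, p))
    covs = np.empty((n_elem, p, p))
    sigma = np.empty(n_elem)
    dfs = np.empty(n_elem)
    for idx in range(n_elem):
        coef, sd_u, sig, df, cov = gls_fit(values[idx], w[idx], design, rho=rho)
        coefs[idx] = coef
        stdev[idx] = sd_u
        covs[idx] = cov
        sigma[idx] = sig
        dfs[idx] = df
    return FitResult(
        element_ids=index,
        coefficient_names=list(design.coefficient_names),
        coefficients=coefs,
        stdev_unscaled=stdev,
        cov_unscaled=covs,
        sigma=sigma,
        df_residual=dfs,
        consensus_correlation=rho if rho != 0.0 else None,
    )


def moderated_t(fit: FitResult, coefficient=-1) -> FitResult:
    """Empirical-Bayes moderated t statistics for a coefficient or contrast.

    ``coefficient`` is either a column index/name or a numeric contrast
    vector over coefficients.  Elements with zero residual df do not enter
    the hyperparameter fit but still receive moderated statistics through
    the shared prior.
    """
    p = len(fit.coefficient_names)
    if isinstance(coefficient, str):
        contrast = np.zeros(p)
        contrast[fit.coefficient_names.index(coefficient)] = 1.0
    elif np.isscalar(coefficient):
        contrast = np.zeros(p)
        contrast[int(coefficient)] = 1.0
    else:
        contrast = np.asarray(coefficient, dtype=float)
        if contrast.shape != (p,):
            raise MpraFormatError(
                f"contrast length {contrast.shape} does not match {p} coefficients"
            )
    d0, s0_sq, s2_post = squeeze_var(fit.sigma ** 2, fit.df_residual)
    beta = fit.coefficients @ contrast
    se_unscaled = np.sqrt(np.einsum("i,eij,j->e", contrast, fit.cov_unscaled, contrast))
    t = beta / (se_unscaled * np.sqrt(s2_post))
    df_total = (d0 if np.isfinite(d0) else np.inf) + np.where(
        fit.df_residual >= 0, fit.df_residual, 0.0
    )
    if np.isinf(d0):
        p_val = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_val = 2.0 * stats.t.sf(np.abs(t), df_total)
    fit.s2_prior = s0_sq
    fit.df_prior = d0
    fit.s2_post = s2_post
    fit.t_moderated = t
    fit.p_value = p_val
    fit.df_total = df_total
    fit.tested = contrast
    return fit


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------

def mpralm(
    counts: BarcodeCountSet,
    design: DesignMatrix | None = None,
    estimator: str = "aggregate",
    span: float = 0.3,
    paired: bool = False,
    min_dna: int = 10,
    coefficient=-1,
) -> FitResult:
    """Differential activity analysis of barcode-level MPRA counts.

    Pipeline: total-count normalize -> summarize barcodes into element
    activities -> filter low-DNA / constant elements -> fit the
    copy-number-variance trend into precision weights -> (for paired
    designs, estimate the consensus within-block correlation) -> weighted
    per-element linear fits -> empirical-Bayes variance moderation ->
    moderated t tests on ``coefficient`` (default: the last design column).
    Deterministic for fixed input.
    """
    if not counts.is_normalized:
        counts = total_count_normalize(counts)
    if design is None:
        design = two_group_design(counts.samples, use_block=paired)
    activity = summarize_dataset(counts, estimator=estimator)
    activity, report = filter_elements(activity, counts, min_dna=min_dna)
    weight_model = fit_weight_curve(activity, design, span=span)
    rho = 0.0
    if paired:
        rho = estimate_consensus_correlation(
            activity, weight_model.weights, design
        )
    fit = fit_elements(activity, weight_model.weights, design, rho=rho)
    fit = moderated_t(fit, coefficient)
    fit.weight_model = weight_model
    fit.filter_report = report
    return fit


def top_table(fit: FitResult) -> pd.DataFrame:
    """Per-element results: logFC, moderated t, df, p, BH-adjusted p."""
    if fit.p_value is None:
        raise MpraFormatError("call moderated_t before top_table")
    adj = multipletests(fit.p_value, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": fit.logFC,
            "t": fit.t_moderated,
            "df": fit.df_total,
            "p_value": fit.p_value,
            "adj_p_value": adj,
        },
        index=pd.Index(fit.element_ids, name="element"),
    )
    return table.sort_values("p_value")
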