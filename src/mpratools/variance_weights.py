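"""Copy-number-dependent precision weights.

MPRA activity measures are log-ratios of sequencing counts, and their
across-sample variability decreases with element copy number (DNA
abundance): low-copy elements yield noisy log-ratios.  Mirroring the voom
approach for RNA-seq, the trend is estimated empirically — the square root
of each element's residual standard deviation is smoothed against its mean
log2 DNA level with lowess — and predicted variances are inverted into
observation-level precision weights for the per-element linear models.

The curve is fit on the fourth-root scale (sqrt of the SD) for stability;
predictions are evaluated at each observation's *own* sample-specific log2
DNA abundance and raised to the 4th power before inversion, so each count
observation receives a weight matching its expected noise level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import ElementActivityMatrix, MpraFormatError

__all__ = ["WeightModel", "fit_weight_curve", "empirical_sd_profile"]

# predicted sqrt-SD values are floored here before inversion so that
# weights stay finite even where the smoother dips to zero
_MIN_SQRT_SD = 1e-3


@dataclass
class WeightModel:
    """Fitted sqrt-SD-vs-log2-DNA curve and derived precision weights."""

    curve_x: np.ndarray
    curve_y: np.ndarray
    smoother_span: float
    weights: pd.DataFrame

    def predict_sqrt_sd(self, x) -> np.ndarray:
        """Evaluate the fitted curve; constant beyond the observed range."""
        return np.interp(np.asarray(x, dtype=float), self.curve_x, self.curve_y)

    def predict_weight(self, x) -> np.ndarray:
        sqrt_sd = np.maximum(self.predict_sqrt_sd(x), _MIN_SQRT_SD)
        return sqrt_sd ** -4.0


def _residual_sd(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Unweighted residual SD of each row after removing the design fit."""
    n, p = design.shape
    hat = design @ np.linalg.pinv(design)
    resid = values - values @ hat.T
    df = n - p
    if df < 1:
        raise MpraFormatError("design leaves no residual degrees of freedom")
    return np.sqrt((resid ** 2).sum(axis=1) / df)


def fit_weight_curve(
    activity: ElementActivityMatrix,
    design,
    span: float = 0.3,
) -> WeightModel:
    """Fit the copy-number-variance trend and derive precision weights.

    Parameters
    ----------
    activity
        Element-level activities carrying per-observation log2 DNA levels.
    design
        Design matrix (``DesignMatrix`` or array, samples x coefficients)
        whose fitted means are removed before computing residual SDs; for a
        two-group comparison this is group-wise centering.
    span
        Lowess span (fraction of points in each local window).
    """
    matrix = getattr(design, "matrix", design)
    matrix = np.asarray(matrix, dtype=float)
    values = activity.activity.to_numpy(dtype=float)
    if values.shape[0] < 10:
        raise MpraFormatError(
            f"weight-curve fitting needs >= 10 elements, got {values.shape[0]}"
        )
    sd = _residual_sd(values, matrix)
    x = activity.mean_log2_dna.to_numpy(dtype=float)
    y = np.sqrt(sd)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.all():
        warnings.warn(
            f"excluding {np.sum(~ok)} elements with non-finite SD from the trend fit",
            stacklevel=2,
        )
    # average y within duplicated x before smoothing
    grouped = pd.Series(y[ok]).groupby(pd.Series(x[ok])).mean()
    gx = grouped.index.to_numpy(dtype=float)
    gy = grouped.to_numpy(dtype=float)
    fitted = lowess(gy, gx, frac=span, it=3, return_sorted=True)
    model = WeightModel(
        curve_x=fitted[:, 0],
        curve_y=fitted[:, 1],
        smoother_span=float(span),
        weights=pd.DataFrame(),  # filled below
    )
    obs_x = (
        activity.obs_log2_dna.to_numpy(dtype=float)
        if activity.obs_log2_dna is not None
        else np.broadcast_to(x[:, None], values.shape)
    )
    weights = model.predict_weight(obs_x)
    model.weights = pd.DataFrame(
        weights, index=activity.activity.index, columns=activity.activity.columns
    )
    return model


def empirical_sd_profile(activity: ElementActivityMatrix, counts=None) -> pd.DataFrame:
    """Per-element (mean log2 DNA, across-sample SD) pairs.

    These are the raw inputs of the copy-number-variance scatter: the
    across-sample standard deviation of the library-size-corrected
    log-ratios against the across-sample mean log2 aggregated DNA.
    """
    if activity.activity.shape[1] < 2:
        raise MpraFormatError("SD profile needs at least 2 samples")
    sd = activity.activity.std(axis=1, ddof=1)
    return pd.DataFrame(
        {"mean_log2_dna": activity.mean_log2_dna, "sd": sd},
        index=activity.activity.index,
    )
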