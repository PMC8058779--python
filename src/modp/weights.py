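"""logCPM transform and precision weights for RNA-seq heteroscedasticity.

Raw counts are log2-counts-per-million transformed; the per-observation
variance of logCPM depends strongly on the underlying count size, which
violates the homoscedastic Normal model the optimal discovery procedure
assumes.  Inverse-variance precision weights are estimated from the observed
mean-variance trend (a lowess fit of sqrt residual standard deviation
against mean log-count) and reduce weighted least squares to ordinary least
squares through the sqrt-weight data transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import ModelPair
from .fitting import _ols_fit

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMatrix",
    "logcpm",
    "filter_low_counts",
    "estimate_weights",
    "weight_transform",
]

#: lowess span for the mean-variance trend (fraction of genes per local fit)
TREND_SPAN = 0.5
#: minimum number of genes required to fit a trend
MIN_GENES_FOR_TREND = 50


@dataclass
class WeightMatrix:
    """Strictly positive inverse-variance weights, one per observation."""

    weights: np.ndarray
    provenance: str = "estimated"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and strictly positive")


def logcpm(counts: np.ndarray) -> np.ndarray:
    """log2 counts-per-million: log2((count + 0.5) / (libsize + 1) * 1e6).

    The half-count offset keeps zeros finite; the +1 on the library size
    keeps the transform bounded by log2(1e6) for any count.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every library (column sum) must be positive")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def filter_low_counts(counts: np.ndarray, min_total: int = 10) -> np.ndarray:
    """Row mask keeping genes with at least ``min_total`` reads in total.

    The default of 10 removes genes whose counts are too sparse for the
    logCPM-plus-weights model to be meaningful.
    """
    counts = np.asarray(counts)
    return counts.sum(axis=1) >= min_total


def estimate_weights(counts: np.ndarray, pair: ModelPair) -> WeightMatrix:
    """Estimate inverse-variance precision weights from the count trend.

    Steps: (i) logCPM transform; (ii) per-gene OLS residual standard
    deviations under the alternative design; (iii) robust lowess of
    sqrt(residual sd) on mean log2-count; (iv) the trend evaluated at each
    observation's fitted log2-count, clamped to the fitted range, gives a
    predicted sd whose inverse fourth power (inverse variance on the
    sd-scale trend) is the weight.
    """
    counts = np.asarray(counts, dtype=float)
    m, n = counts.shape
    y = logcpm(counts)
    if m < MIN_GENES_FOR_TREND:
        logger.warning(
            "only %d genes (< %d): refusing to fit a mean-variance trend; "
            "all weights set to 1", m, MIN_GENES_FOR_TREND,
        )
        return WeightMatrix(np.ones_like(y), provenance="estimated")

    _, fitted, rss = _ols_fit(y, pair.X_alt)
    resid_df = n - pair.p_alt
    sd = np.sqrt(np.maximum(rss, 0.0) / resid_df)
    sqrt_sd = np.sqrt(sd)

    lib = counts.sum(axis=0)
    # mean log2-count per gene and fitted log2-count per observation,
    # both on the count scale of a typical library
    log_lib = np.log2(lib + 1.0).mean() - np.log2(1e6)
    mean_logcount = y.mean(axis=1) + log_lib
    fitted_logcount = fitted + log_lib

    keep = sd > 0
    trend = lowess(
        sqrt_sd[keep], mean_logcount[keep], frac=TREND_SPAN, it=3,
        return_sorted=True,
    )
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    # np.interp clamps at the endpoints, which is the required extrapolation
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    w = pred_sqrt_sd ** -4.0
    return WeightMatrix(w, provenance="estimated")


def weight_transform(y: np.ndarray, design: np.ndarray, w: np.ndarray):
    """Scale data and design by sqrt(w) so OLS reproduces WLS exactly.

    Returns ``(ybar, Sbar)`` with ybar = sqrt(w) * y and Sbar the design
    with rows scaled by sqrt(w); ordinary least squares on the pair solves
    the weighted normal equations X' W X b = X' W y.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sw = np.sqrt(w)
    return sw * y, sw[:, None] * design
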