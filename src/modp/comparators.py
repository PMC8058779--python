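"""F-test, moderated F-test, and their bootstrap-null variants.

These are the benchmark testing procedures the modular ODP is compared
against.  The moderated F shrinks each gene's residual variance toward a
pooled value through an empirical-Bayes scaled-inverse-chi-square prior on
the true variances, stabilizing inference at small sample sizes; its
hyperparameters are estimated by method of moments on the log sample
variances using digamma/trigamma identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .design import ModelPair
from .fitting import GeneFitTable, fit_all
from .significance import bootstrap_pool, significance_from_pool, studentized_residuals

logger = logging.getLogger(__name__)

__all__ = [
    "ModeratedVariancePrior",
    "f_statistic",
    "f_statistics",
    "f_pvalues",
    "fit_variance_prior",
    "moderated_f",
    "bootstrap_comparator",
]


def f_statistics(fits: GeneFitTable) -> np.ndarray:
    """Classical nested-model F statistic for every gene.

    F = ((rss0 - rss1)/(df1 - df0)) / (rss1/(N - df1)); genes with zero
    alternative residual variance get +inf.
    """
    num_df = fits.df1 - fits.df0
    den_df = fits.n - fits.df1
    num = (fits.rss0 - fits.rss1) / num_df
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(fits.rss1 > 0, num / (fits.rss1 / den_df), np.inf)
    f = np.where((fits.rss1 <= 0) & (num <= 0), 0.0, f)
    return np.maximum(f, 0.0)


def f_statistic(fit) -> float:
    """F statistic of a single GeneFit."""
    num = (fit.rss0 - fit.rss1) / (fit.df1 - fit.df0)
    if fit.rss1 <= 0:
        return float("inf") if num > 0 else 0.0
    n = len(fit.mu1_hat)
    return float(num / (fit.rss1 / (n - fit.df1)))


def f_pvalues(f: np.ndarray, fits: GeneFitTable) -> np.ndarray:
    """Parametric p-values from the F(df1-df0, N-df1) reference distribution."""
    p = stats.f.sf(f, fits.df1 - fits.df0, fits.n - fits.df1)
    return np.clip(p, np.finfo(float).tiny, 1.0)


@dataclass
class ModeratedVariancePrior:
    """Scaled-inverse-chi-square prior (d0, s0^2) on the true gene variances."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def fit_variance_prior(s_sq: np.ndarray, df_resid: int) -> ModeratedVariancePrior:
    """Method-of-moments prior fit on log sample variances.

    Under s_i^2 | sigma_i^2 ~ sigma_i^2 chi^2_d / d with
    sigma_i^2 ~ d0 s0^2 / chi^2_{d0}, the quantity
    e_i = log s_i^2 - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2).  Solving the two moment equations with
    a trigamma inverse gives (d0, s0^2); when the observed spread of log
    variances does not exceed trigamma(d/2), the prior is degenerate
    (d0 = inf) and s0^2 is the pooled value.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq > 0
    if pos.sum() < 50:
        raise ValueError("need at least 50 positive variances to fit a prior")
    z = np.log(s_sq[pos])
    d = float(df_resid)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModeratedVariancePrior(d0=np.inf, s0_sq=float(np.exp(e_mean)))

    def f(x):
        return float(special.polygamma(1, x)) - excess

    # trigamma is strictly decreasing on (0, inf): bracket and bisect
    half_d0 = optimize.brentq(f, 1e-8, 1e8)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedVariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_f(fits: GeneFitTable, prior: ModeratedVariancePrior):
    """Moderated F statistics and p-values under the fitted variance prior.

    The posterior residual variance s~_i^2 = (d0 s0^2 + d_i s_i^2)/(d0 + d_i)
    replaces s_i^2 in the F statistic; the null reference is
    F(df1 - df0, d0 + d_i), degenerating to the chi-square limit when
    d0 = inf (every gene then uses the pooled variance s0^2).
    """
    num_df = fits.df1 - fits.df0
    d_i = fits.n - fits.df1
    s_sq = fits.rss1 / d_i
    if np.isinf(prior.d0):
        s_tilde = np.full_like(s_sq, prior.s0_sq)
        total_df = np.inf
    else:
        s_tilde = (prior.d0 * prior.s0_sq + d_i * s_sq) / (prior.d0 + d_i)
        total_df = prior.d0 + d_i
    num = (fits.rss0 - fits.rss1) / num_df
    f_mod = num / s_tilde
    if np.isinf(prior.d0):
        p = stats.chi2.sf(num_df * f_mod, num_df)
    else:
        p = stats.f.sf(f_mod, num_df, total_df)
    return f_mod, np.clip(p, np.finfo(float).tiny, 1.0)


def bootstrap_comparator(
    statistic_fn,
    Y: np.ndarray,
    pair: ModelPair,
    B: int,
    seed=None,
    gene_ids=None,
    method: str = "bootstrap-f",
):
    """Empirical-null version of an F-type comparator.

    Uses the same residual-resampling engine as the mODP bootstrap: each
    iteration refits the nested model pair on resampled studentized
    alternative-fit residuals and recomputes ``statistic_fn`` (a function of
    the refitted GeneFitTable); pooled p-values follow.
    """
    Y = np.asarray(Y, dtype=float)
    fits = fit_all(Y, pair, gene_ids=gene_ids)
    observed = statistic_fn(fits)
    Yt = Y - fits.mu0
    resid = studentized_residuals(Yt, pair, fits)
    pool = bootstrap_pool(
        resid,
        lambda ystar: statistic_fn(fit_all(ystar, pair)),
        B=B,
        seed=seed,
    )
    pool = pool[np.isfinite(pool)]
    finite_obs = np.where(np.isfinite(observed), observed, np.nanmax(pool) + 1.0)
    return significance_from_pool(
        fits.gene_ids if gene_ids is None else gene_ids,
        finite_obs,
        pool,
        B=B,
        method=method,
        degenerate=fits.degenerate,
    )
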