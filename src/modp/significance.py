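"""Bootstrap empirical null, pooled p-values, pi0, q-values and local FDR.

The theoretical null distribution of the (m)ODP statistic is unknown, so an
empirical null is generated by resampling residuals.  Per iteration one
shared draw of measurement indices resamples every gene's
leverage-studentized alternative-fit residuals (preserving cross-gene
dependence), the null-model projection is re-applied so the resampled data
mimic the observed null transform, each resampled gene is rescaled to its
signal-free error-scale estimate (resampling adds a second layer of scale
noise the observed cross-section does not have, and the statistic is
scale-sensitive against the frozen dictionary), the per-gene alternative
fits are recomputed on the resampled data, and the statistics are evaluated against
the observed modules with each gene re-assigned to the module nearest its
refit and scored against that module with its parameters re-formed from
the bootstrap refits assigned to it (see core.modp_statistics_bootstrap).
The re-assignment and re-formed module — but never a re-run of the
clustering — are essential for calibration: the observed statistic of
every gene benefits from the clustering having matched a module to its
fitted model and from the module parameters having been averaged over the
gene and co-members selected for similarity to it, and the null statistics
must carry the same self-fit effects or the pool is stochastically too
small and the p-values anti-conservative.  All m x B null statistics form a single pool: the
optimal discovery procedure ranks all genes on one common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .core import ModuleSet, modp_statistics, modp_statistics_bootstrap
from .design import ModelPair
from .fitting import GeneFitTable
from .splines import natural_cubic_basis

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceTable",
    "studentized_residuals",
    "bootstrap_pool",
    "bootstrap_null",
    "empirical_pvalues",
    "estimate_pi0",
    "qvalues",
    "local_fdr",
    "significance_from_pool",
]

#: default number of bootstrap iterations
DEFAULT_B = 500
#: p-value exceedance thresholds for pi0 estimation
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class SignificanceTable:
    """Per-gene significance results plus the global null-proportion estimate."""

    table: pd.DataFrame  # gene_id, stat, p_value, q_value, lfdr
    pi0: float
    B: int
    pool_size: int
    method: str = "modp"

    def __post_init__(self):
        if not 0 < self.pi0 <= 1:
            raise ValueError("pi0 must be in (0, 1]")
        order = np.argsort(self.table["p_value"].to_numpy(), kind="stable")
        q = self.table["q_value"].to_numpy()[order]
        if np.any(np.diff(q) < -1e-12):
            raise ValueError("q-values are not monotone in p-values")

    def n_significant(self, q_cutoff: float = 0.1) -> int:
        return int((self.table["q_value"] <= q_cutoff).sum())

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# pi0={self.pi0:.6g} B={self.B} method={self.method}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def studentized_residuals(Yt: np.ndarray, pair: ModelPair,
                          fits: GeneFitTable) -> np.ndarray:
    """Alternative-fit residuals scaled by 1/sqrt(1 - h_jj).

    Raw least-squares residuals have per-observation variance
    sigma^2 (1 - h_jj); the leverage adjustment restores the error scale so
    resampled null data match the spread of null-gene data.
    """
    q, _ = np.linalg.qr(pair.X_alt)
    h = np.square(q).sum(axis=1)
    resid = Yt - (fits.mu1 - fits.mu0)
    return resid / np.sqrt(np.maximum(1.0 - h, 1e-12))[None, :]


def bootstrap_pool(
    resid: np.ndarray,
    statistic_fn,
    B: int,
    seed=None,
    null_projector: np.ndarray | None = None,
) -> np.ndarray:
    """Generic residual-resampling engine returning the pooled null statistics.

    For b = 1..B: draw one set of measurement indices with replacement
    (shared by every gene), form y* from the resampled residual columns,
    optionally re-apply the null-model projection, then evaluate
    ``statistic_fn(Ystar)`` (an m-vector).  Pools all m statistics per
    iteration; the result has length m*B.
    """
    resid = np.asarray(resid, dtype=float)
    m, n = resid.shape
    if B < 1:
        raise ValueError("B must be >= 1")
    if n < 4:
        raise ValueError(f"too few measurements to resample (N={n} < 4)")
    rng = np.random.default_rng(seed)
    pool = np.empty((B, m))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        ystar = resid[:, idx]
        if null_projector is not None:
            ystar = ystar @ null_projector.T
        pool[b] = statistic_fn(ystar)
    return pool.ravel()


def bootstrap_null(
    Yt: np.ndarray,
    pair: ModelPair,
    modules: ModuleSet,
    B: int = DEFAULT_B,
    seed=None,
    fits: GeneFitTable | None = None,
) -> np.ndarray:
    """Pooled mODP null statistics (length m*B).

    The module dictionary and size weights stay frozen at their observed
    values; per iteration each gene's alternative model is refit on the
    resampled data, the gene is re-assigned to the module nearest the
    refit, and it is scored against that module with its parameters
    re-formed from the bootstrap refits assigned to it (see module
    docstring and core.modp_statistics_bootstrap).
    """
    Yt = np.asarray(Yt, dtype=float)
    n = Yt.shape[1]
    q0, _ = np.linalg.qr(pair.X_null)
    projector = np.eye(n) - q0 @ q0.T
    q1, _ = np.linalg.qr(pair.X_alt)
    alt_projector = q1 @ q1.T

    if fits is not None:
        resid = studentized_residuals(Yt, pair, fits)
        # pin each resampled gene's realized null-residual scale to its
        # signal-free error-scale estimate (unbiased sigma^2 times the
        # null-projection shrinkage (n - p0)/n).  Resampling from a finite
        # residual set adds a second layer of scale noise on top of the
        # estimation noise the observed cross-section already carries; the
        # statistic compares absolute scales against the frozen module
        # dictionary, so without the pinning the pool is over-dispersed
        # (severely so for skewed count-scale residuals) and large
        # p-values are depleted, which biases pi0 downward.
        scale_target = (
            np.square(fits.sigma1) * n / (n - pair.p_alt) * (n - pair.p_null) / n
        )
    else:
        resid = Yt
        scale_target = None

    def stat_fn(ystar):
        if scale_target is not None:
            var0_raw = np.square(ystar).sum(axis=1) / n
            ystar = ystar * np.sqrt(
                scale_target / np.maximum(var0_raw, 1e-300)
            )[:, None]
        mu1_star = ystar @ alt_projector.T
        var1_star = np.square(ystar - mu1_star).sum(axis=1) / n
        var0_star = np.square(ystar).sum(axis=1) / n
        return modp_statistics_bootstrap(
            ystar, modules, mu1_star, var1_star, var0_star,
        )

    return bootstrap_pool(
        resid,
        stat_fn,
        B=B,
        seed=seed,
        null_projector=projector,
    )


def empirical_pvalues(observed: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Pooled empirical p-values with the add-one correction.

    p_i = (1 + #{pool >= s_i}) / (|pool| + 1); ties count as exceedances and
    the correction keeps every p-value strictly positive.
    """
    observed = np.asarray(observed, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty null pool")
    sorted_pool = np.sort(pool)
    n_ge = pool.size - np.searchsorted(sorted_pool, observed, side="left")
    return (1.0 + n_ge) / (pool.size + 1.0)


def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the proportion of true nulls from the p-value distribution.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) increases toward the true
    pi0 as lambda -> 1; the sequence over the lambda grid is smoothed with a
    dimension-3 natural cubic spline and evaluated at the largest lambda,
    then clamped to (0, 1].  With fewer than 100 p-values the single-lambda
    estimate at 0.5 is used instead.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 100:
        logger.warning("fewer than 100 p-values: pi0 from fixed lambda = 0.5")
        pi0 = (p > 0.5).sum() / (m * 0.5)
        return float(min(max(pi0, 1e-8), 1.0))
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    basis = natural_cubic_basis(lam, np.quantile(lam, np.linspace(0, 1, 4)))
    X = np.column_stack([np.ones_like(lam), basis.matrix])
    coef, *_ = np.linalg.lstsq(X, pi0_lam, rcond=None)
    at_max = np.concatenate([[1.0], basis.evaluate(np.array([lam.max()]))[0]])
    pi0 = float(at_max @ coef)
    return float(min(max(pi0, 1e-8), 1.0))


def qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """q-values by the pi0-scaled step-up rule.

    q_(i) = min_{t >= p_(i)} pi0 * m * t / #{p <= t}, enforced monotone
    non-decreasing in p and capped at 1; pi0 = 1 gives Benjamini-Hochberg
    adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Grenander (decreasing) density estimate evaluated at the sorted p's.

    The slopes of the least concave majorant of the empirical CDF are the
    weighted decreasing isotonic fit of the raw interval densities, with
    interval widths as weights.
    """
    m = p_sorted.size
    uniq, counts = np.unique(p_sorted, return_counts=True)
    edges = np.concatenate([[0.0], uniq])
    widths = np.diff(edges)
    mass = counts / m
    raw = mass / widths
    iso = IsotonicRegression(increasing=False)
    dens = iso.fit_transform(np.arange(uniq.size), raw, sample_weight=widths)
    dens = np.maximum(dens, 1e-12)
    return np.repeat(dens, counts)


def local_fdr(p: np.ndarray, pi0: float) -> np.ndarray:
    """Local FDR: clamp(pi0 / fhat(p), 0, 1) with a Grenander density fit.

    fhat is the monotone-decreasing density of the p-values; at p where the
    density is at the null level (fhat ~ pi0... ~1) the local FDR approaches
    1, and it approaches 0 where small p-values pile up.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    dens_sorted = _grenander_density(p[order])
    lfdr = np.empty_like(p)
    lfdr[order] = np.clip(pi0 / dens_sorted, 0.0, 1.0)
    return lfdr


def significance_from_pool(
    gene_ids,
    observed: np.ndarray,
    pool: np.ndarray,
    B: int,
    method: str = "modp",
    degenerate: np.ndarray | None = None,
) -> SignificanceTable:
    """Assemble a SignificanceTable from observed statistics and a null pool."""
    observed = np.asarray(observed, dtype=float)
    p = empirical_pvalues(observed, pool)
    if degenerate is not None and np.any(degenerate):
        # zero-variance genes carry no evidence
        observed = observed.copy()
        observed[degenerate] = -np.inf
        p = p.copy()
        p[degenerate] = 1.0
    pi0 = estimate_pi0(p)
    q = qvalues(p, pi0)
    lfdr = local_fdr(p, pi0)
    table = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "stat": observed,
            "p_value": p,
            "q_value": q,
            "lfdr": lfdr,
        }
    )
    return SignificanceTable(
        table=table, pi0=pi0, B=B, pool_size=pool.size, method=method
    )
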