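"""Per-gene least-squares fitting, eigen-genes, and spline-dimension selection.

All genes in a study share one pair of design matrices, so fits are
vectorized through a single thin-QR factorization per design.  Scale
estimates use the maximum-likelihood divisor N (the optimal discovery
procedure is likelihood-based); the classical unbiased divisor N - p is used
only inside the F-type comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelPair
from .splines import spline_basis

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFit",
    "GeneFitTable",
    "fit_gene",
    "fit_all",
    "eigen_genes",
    "loocv_error",
    "select_dimension",
    "null_transform",
]

#: genes whose alternative-model residual variance is numerically zero carry
#: no evidence and break Normal likelihoods; they are excluded from module
#: clustering and assigned statistic 0 / p-value 1 downstream.
DEGENERATE_TOL = 1e-12


def _ols_fit(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of every row of Y on X: (coef, fitted, rss)."""
    q, r = np.linalg.qr(X)
    qty = q.T @ Y.T                       # p x m
    fitted = (q @ qty).T                  # m x n
    coef = np.linalg.solve(r, qty).T      # m x p
    rss = np.square(Y - fitted).sum(axis=1)
    return coef, fitted, rss


@dataclass
class GeneFit:
    """Null/alternative least-squares fit for one gene."""

    gene_id: str
    mu0_hat: np.ndarray
    mu1_hat: np.ndarray
    sigma0_hat: float
    sigma1_hat: float
    rss0: float
    rss1: float
    df0: int
    df1: int
    degenerate: bool = False


@dataclass
class GeneFitTable:
    """Vectorized null/alternative fits for all genes of a study."""

    gene_ids: list
    mu0: np.ndarray      # m x N
    mu1: np.ndarray      # m x N
    rss0: np.ndarray
    rss1: np.ndarray
    sigma0: np.ndarray   # ML scale sqrt(rss0 / N)
    sigma1: np.ndarray
    df0: int
    df1: int
    n: int

    @property
    def degenerate(self) -> np.ndarray:
        return self.rss1 <= DEGENERATE_TOL * np.maximum(1.0, self.rss0)

    def __getitem__(self, i: int) -> GeneFit:
        return GeneFit(
            gene_id=self.gene_ids[i],
            mu0_hat=self.mu0[i],
            mu1_hat=self.mu1[i],
            sigma0_hat=float(self.sigma0[i]),
            sigma1_hat=float(self.sigma1[i]),
            rss0=float(self.rss0[i]),
            rss1=float(self.rss1[i]),
            df0=self.df0,
            df1=self.df1,
            degenerate=bool(self.degenerate[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "rss0": self.rss0,
                "rss1": self.rss1,
                "sigma0": self.sigma0,
                "sigma1": self.sigma1,
                "df0": self.df0,
                "df1": self.df1,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_all(
    Y: np.ndarray,
    pair: ModelPair,
    weights: np.ndarray | None = None,
    gene_ids=None,
) -> GeneFitTable:
    """Fit null and alternative models to every gene by (weighted) least squares.

    With weights, each gene's data and design rows are scaled by sqrt(w)
    (the exact WLS-to-OLS reduction) before ordinary least squares; weights
    may be one vector shared by all genes or an m x N matrix.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if n <= pair.p_alt:
        raise ValueError(
            f"need more measurements ({n}) than alternative parameters ({pair.p_alt})"
        )
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(m)]

    if weights is None:
        _, mu0, rss0 = _ols_fit(Y, pair.X_null)
        _, mu1, rss1 = _ols_fit(Y, pair.X_alt)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and strictly positive")
        if w.ndim == 1:
            w = np.broadcast_to(w, Y.shape)
        sw = np.sqrt(w)
        Yw = sw * Y
        mu0 = np.empty_like(Y)
        mu1 = np.empty_like(Y)
        rss0 = np.empty(m)
        rss1 = np.empty(m)
        for X, mu, rss in ((pair.X_null, mu0, rss0), (pair.X_alt, mu1, rss1)):
            # batched per-gene WLS via the normal equations on scaled data
            Xw = sw[:, :, None] * X[None, :, :]          # m x n x p
            xtx = np.einsum("inp,inq->ipq", Xw, Xw)
            xty = np.einsum("inp,in->ip", Xw, Yw)
            try:
                coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    "rank-deficient design after weighting"
                ) from err
            mu[:] = np.einsum("inp,ip->in", Xw, coef)
            rss[:] = np.square(Yw - mu).sum(axis=1)
        Y = Yw  # fitted means live on the transformed scale

    table = GeneFitTable(
        gene_ids=list(gene_ids),
        mu0=mu0,
        mu1=mu1,
        rss0=rss0,
        rss1=rss1,
        sigma0=np.sqrt(np.maximum(rss0, 0.0) / n),
        sigma1=np.sqrt(np.maximum(rss1, 0.0) / n),
        df0=pair.p_null,
        df1=pair.p_alt,
        n=n,
    )
    bad = rss1 > rss0 + 1e-9
    if bad.any():
        raise AssertionError("nestedness violated: rss1 > rss0 for some gene")
    ndeg = int(table.degenerate.sum())
    if ndeg:
        logger.info("flagged %d zero-residual-variance genes as degenerate", ndeg)
    return table


def fit_gene(
    y: np.ndarray,
    pair: ModelPair,
    weights: np.ndarray | None = None,
    gene_id: str = "gene",
) -> GeneFit:
    """Fit one gene (convenience wrapper over the vectorized path)."""
    y = np.asarray(y, dtype=float)
    table = fit_all(y[None, :], pair, weights=weights, gene_ids=[gene_id])
    return table[0]


def eigen_genes(Y: np.ndarray, E: int) -> np.ndarray:
    """Top E right-singular vectors of the row-centered expression matrix.

    Rows of the result are the eigen-genes, ordered by singular value; they
    are the directions of maximal variation across measurements and serve as
    data-driven summary curves for spline-dimension selection.
    """
    Y = np.asarray(Y, dtype=float)
    if E > min(Y.shape):
        raise ValueError(f"E={E} exceeds min(m, N)={min(Y.shape)}")
    centered = Y - Y.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[:E]


def loocv_error(v: np.ndarray, design: np.ndarray) -> float:
    """Leave-one-out CV error of regressing ``v`` on ``design``.

    Uses the hat-matrix shortcut: mean of ((v_j - vhat_j) / (1 - h_jj))^2,
    which equals the brute-force refit-without-j computation exactly for
    least squares.  Any leverage at 1 makes the error infinite (such a fit
    can never be selected).
    """
    v = np.asarray(v, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    q, _ = np.linalg.qr(design)
    h = np.square(q).sum(axis=1)
    if np.any(h >= 1 - 1e-12):
        return float("inf")
    resid = v - q @ (q.T @ v)
    return float(np.mean(np.square(resid / (1.0 - h))))


def select_dimension(
    Y: np.ndarray,
    x: np.ndarray,
    D: int = 4,
    E: int = 4,
    splits: np.ndarray | None = None,
) -> int:
    """Choose the spline dimension by eigen-gene leave-one-out cross-validation.

    For each of the top E eigen-genes and each candidate d = 1..D, regress
    the eigen-gene on an intercept plus a d-dimensional natural cubic basis
    and record the LOOCV error; each eigen-gene votes for its arg-min d
    (smallest d on ties), and the returned estimate is the maximum vote, so
    the basis is rich enough for every major direction of variation.

    ``splits`` (optional group labels, one per measurement) separates the
    data into per-group datasets first; eigen-genes from every split vote.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    if D < 1:
        raise ValueError("D must be >= 1")

    if splits is not None:
        splits = np.asarray(splits)
        votes = []
        for lev in pd.unique(splits):
            mask = splits == lev
            votes.append(
                select_dimension(Y[:, mask], x[mask], D=D, E=min(E, int(mask.sum())))
            )
        return max(votes)

    n_distinct = np.unique(x).size
    D_max = n_distinct - 1
    if D > D_max:
        logger.warning(
            "truncating spline-dimension search D=%d to %d "
            "(covariate has %d distinct values)", D, D_max, n_distinct,
        )
        D = D_max
    E = min(E, min(Y.shape))
    vgenes = eigen_genes(Y, E)
    ones = np.ones((len(x), 1))
    designs = [np.hstack([ones, spline_basis(x, d).matrix]) for d in range(1, D + 1)]
    best = []
    for v in vgenes:
        errors = np.array([loocv_error(v, X) for X in designs])
        best.append(int(np.argmin(errors)) + 1)  # argmin takes smallest d on ties
    return max(best)


def null_transform(Y: np.ndarray, fits: GeneFitTable) -> np.ndarray:
    """Remove the fitted null signal: y'_i = y_i - muhat_i0(x).

    After the transform the null hypothesis for every gene is that the mean
    curve is identically zero, so null likelihoods need no per-gene mean.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape != fits.mu0.shape:
        raise ValueError("fits are not aligned with the expression matrix")
    return Y - fits.mu0
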