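"""Natural cubic spline bases with knots at evenly spaced covariate quantiles.

A natural cubic spline is a piecewise cubic polynomial, twice continuously
differentiable, constrained to be linear beyond its boundary knots.  The
population mean curve of a gene is modelled as ``mu(x) = alpha + s(x) @ beta``
where ``s(x)`` is a d-dimensional basis of this space excluding the constant
function (the intercept is a separate design column).  A d-dimensional basis
uses d+1 knots: the natural spline space on K knots has dimension K including
the intercept, so K-1 non-constant columns remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SplineBasis", "knot_positions", "natural_cubic_basis", "spline_basis"]


def knot_positions(x: np.ndarray, k: int) -> np.ndarray:
    """Place ``k`` knots at evenly spaced empirical quantiles of ``x``.

    Quantile probabilities are 0, 1/(k-1), ..., (k-2)/(k-1), 1 using linear
    interpolation of order statistics (type-7), so the first and last knots
    equal min(x) and max(x).

    Raises
    ------
    ValueError
        if ``x`` has fewer than ``k`` distinct values (duplicate knots).
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 knots")
    n_distinct = np.unique(x).size
    knots = np.quantile(x, np.linspace(0.0, 1.0, k))
    if np.unique(knots).size < k:
        raise ValueError(
            f"cannot place {k} distinct knots: covariate has only "
            f"{n_distinct} distinct values"
        )
    return knots


def _raw_natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic basis, K knots -> K-1 columns.

    Columns: N_1(x) = x and N_{j+1}(x) = d_j(x) - d_{K-1}(x) for j = 1..K-2
    with d_j(x) = [(x - k_j)_+^3 - (x - k_K)_+^3] / (k_K - k_j).  Each column
    is linear outside [k_1, k_K] by construction.
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    cols = [x]
    if K > 2:
        def d(j):
            return (
                np.maximum(x - knots[j], 0.0) ** 3
                - np.maximum(x - knots[-1], 0.0) ** 3
            ) / (knots[-1] - knots[j])

        d_last = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - d_last)
    return np.column_stack(cols)


@dataclass
class SplineBasis:
    """A fitted natural cubic spline basis.

    The stored matrix is centered and orthonormalized (QR) against the
    intercept; fitted values of any least-squares fit are invariant to this
    reparameterization, which only improves conditioning.  ``evaluate``
    applies the same affine map to new covariate values so the basis extends
    linearly beyond the boundary knots.
    """

    dimension: int
    knots: np.ndarray
    matrix: np.ndarray
    x: np.ndarray
    _col_means: np.ndarray = field(repr=False, default=None)
    _transform: np.ndarray = field(repr=False, default=None)

    def evaluate(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate the basis at new covariate values (linear extrapolation)."""
        x_new = np.asarray(x_new, dtype=float)
        if x_new.min() < self.knots[0] or x_new.max() > self.knots[-1]:
            logger.info(
                "evaluating spline basis outside knot range [%g, %g]: "
                "linear extrapolation", self.knots[0], self.knots[-1],
            )
        raw = _raw_natural_basis(x_new, self.knots)
        return (raw - self._col_means) @ self._transform


def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> SplineBasis:
    """Build the natural cubic spline basis on the given knots.

    With K knots the returned basis has K-1 columns; together with an
    intercept they span the full natural cubic spline space on those knots.
    With exactly 2 knots the space is the linear functions of ``x``.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(knots) < 2:
        raise ValueError("need at least 2 knots")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    raw = _raw_natural_basis(x, knots)
    means = raw.mean(axis=0)
    centered = raw - means
    q, r = np.linalg.qr(centered)
    # sign-fix so the basis is a deterministic function of (x, knots)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    r = r * signs[:, None]
    transform = np.linalg.solve(r, np.eye(r.shape[0]))
    return SplineBasis(
        dimension=raw.shape[1],
        knots=knots,
        matrix=q,
        x=x,
        _col_means=means,
        _transform=transform,
    )


def spline_basis(x: np.ndarray, d: int) -> SplineBasis:
    """Natural cubic basis of dimension ``d`` (d+1 knots at even quantiles).

    ``d`` counts the beta coefficients of s(x); the intercept is separate.
    d = 1 degenerates to the single linear column x.
    """
    if d < 1:
        raise ValueError("spline dimension must be >= 1")
    knots = knot_positions(x, d + 1)
    return natural_cubic_basis(x, knots)
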