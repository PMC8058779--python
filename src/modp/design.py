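"""Nested null/alternative design matrices for the three sampling designs.

The study designs are:

* ``static`` — subjects sampled once, compared across biological groups;
  null = intercept only, alternative adds group indicators.
* ``independent`` — subjects sampled once along a continuous covariate
  (age, dose); null = intercept only, alternative adds a d-dimensional
  natural cubic spline basis (tests beta_l = 0 for l = 1..d).
* ``longitudinal`` — subjects measured repeatedly over a covariate (time),
  compared across classes; the null fits one curve to all classes combined
  and the alternative fits a separate curve per class.

The null column space is always a subspace of the alternative column space,
so all tests are of nested least-squares models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineBasis, spline_basis

__all__ = ["ModelPair", "build_study", "DESIGN_KINDS"]

DESIGN_KINDS = ("static", "independent", "longitudinal")

_NEST_TOL = 1e-10


@dataclass
class ModelPair:
    """A nested pair of design matrices realizing one study design."""

    design_kind: str
    X_null: np.ndarray
    X_alt: np.ndarray
    spline_dimension: int | None = None
    knots: np.ndarray | None = None
    column_roles_null: list = field(default_factory=list)
    column_roles_alt: list = field(default_factory=list)
    basis: SplineBasis | None = None

    def __post_init__(self):
        self.X_null = np.atleast_2d(np.asarray(self.X_null, dtype=float))
        self.X_alt = np.atleast_2d(np.asarray(self.X_alt, dtype=float))
        if self.X_null.shape[0] != self.X_alt.shape[0]:
            raise ValueError("null/alternative designs have different row counts")
        if self.p_alt <= self.p_null:
            raise ValueError("alternative model must have more columns than null")
        if np.linalg.matrix_rank(self.X_alt) < self.p_alt:
            raise ValueError("alternative design matrix is rank deficient")
        resid = self.nesting_residual()
        if resid > _NEST_TOL:
            raise ValueError(
                f"null model is not nested in the alternative "
                f"(projection residual {resid:.3g})"
            )

    @property
    def n(self) -> int:
        return self.X_alt.shape[0]

    @property
    def p_null(self) -> int:
        return self.X_null.shape[1]

    @property
    def p_alt(self) -> int:
        return self.X_alt.shape[1]

    def nesting_residual(self) -> float:
        """Max column-wise residual norm of projecting X_null onto span(X_alt)."""
        q, _ = np.linalg.qr(self.X_alt)
        proj = q @ (q.T @ self.X_null)
        return float(np.linalg.norm(self.X_null - proj, axis=0).max())


def _group_indicators(groups: np.ndarray):
    levels = sorted(pd.unique(groups).astype(str).tolist())
    if len(levels) < 2:
        raise ValueError(f"group factor needs >= 2 levels, got {levels}")
    # treatment contrasts, first (lexicographic) level as reference
    cols = [(np.asarray(groups).astype(str) == lev).astype(float)
            for lev in levels[1:]]
    return np.column_stack(cols), levels


def build_study(
    sample_meta: pd.DataFrame,
    design_kind: str,
    spline_dimension: int | None = None,
    test: str = "group-difference",
) -> ModelPair:
    """Build the nested null/alternative design pair for a study.

    Parameters
    ----------
    sample_meta : DataFrame
        One row per measurement; needs ``group`` for static designs,
        ``covariate`` for non-static designs, and both (plus ``individual``)
        for longitudinal designs.
    design_kind : {"static", "independent", "longitudinal"}
    spline_dimension : int
        Dimension d of the natural cubic spline basis (non-static designs).
    test : {"group-difference", "any-effect"}
        For longitudinal designs, ``group-difference`` tests separate
        per-class curves against one shared curve; ``any-effect`` tests a
        shared curve against a flat response.
    """
    if design_kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design kind {design_kind!r}")
    n = len(sample_meta)
    ones = np.ones((n, 1))

    if design_kind == "static":
        groups = sample_meta["group"].to_numpy()
        ind, levels = _group_indicators(groups)
        X_alt = np.hstack([ones, ind])
        return ModelPair(
            design_kind,
            X_null=ones,
            X_alt=X_alt,
            column_roles_null=["intercept"],
            column_roles_alt=["intercept"] + [f"group:{g}" for g in levels[1:]],
        )

    x = pd.to_numeric(sample_meta["covariate"]).to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-static designs require a finite covariate for every measurement")
    d = spline_dimension
    if d is None:
        raise ValueError("non-static designs require a spline dimension")
    n_distinct = np.unique(x).size
    if d > n_distinct - 1:
        raise ValueError(
            f"spline dimension {d} too large for {n_distinct} distinct covariate values"
        )
    basis = spline_basis(x, d)
    S = basis.matrix

    if design_kind == "independent":
        X_alt = np.hstack([ones, S])
        return ModelPair(
            design_kind,
            X_null=ones,
            X_alt=X_alt,
            spline_dimension=d,
            knots=basis.knots,
            column_roles_null=["intercept"],
            column_roles_alt=["intercept"] + [f"basis:{l + 1}" for l in range(d)],
            basis=basis,
        )

    # longitudinal
    if test == "any-effect":
        return ModelPair(
            design_kind,
            X_null=ones,
            X_alt=np.hstack([ones, S]),
            spline_dimension=d,
            knots=basis.knots,
            column_roles_null=["intercept"],
            column_roles_alt=["intercept"] + [f"basis:{l + 1}" for l in range(d)],
            basis=basis,
        )
    groups = sample_meta["group"].to_numpy()
    _, levels = _group_indicators(groups)
    per_class = [
        S * (np.asarray(groups).astype(str) == lev).astype(float)[:, None]
        for lev in levels
    ]
    X_alt = np.hstack([ones] + per_class)
    roles = ["intercept"] + [
        f"basis:{l + 1}|group:{lev}" for lev in levels for l in range(d)
    ]
    return ModelPair(
        design_kind,
        X_null=np.hstack([ones, S]),
        X_alt=X_alt,
        spline_dimension=d,
        knots=basis.knots,
        column_roles_null=["intercept"] + [f"basis:{l + 1}" for l in range(d)],
        column_roles_alt=roles,
        basis=basis,
    )
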