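"""Model/Results objects orchestrating the full mODP significance analysis.

``ODPStudy`` is built from an expression matrix plus a study design and its
``fit`` method runs the whole procedure — spline-dimension selection by
eigen-gene cross-validation, per-gene least-squares fits, the null-model
data transform, Kullback-Leibler module clustering, the modular ODP
statistic, a residual-bootstrap empirical null, and the p-value / pi0 /
q-value / local-FDR machinery — returning an ``ODPResults`` object.
``ODPStudy.compare`` runs the F-type benchmark procedures on the same data
with shared bootstrap seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators as cmp_mod
from .core import ModuleSet, cluster_modules, modp_statistics
from .data import ExpressionMatrix, read_expression, read_metadata
from .design import ModelPair, build_study
from .fitting import GeneFitTable, fit_all, null_transform, select_dimension
from .significance import (
    SignificanceTable,
    bootstrap_pool,
    significance_from_pool,
    studentized_residuals,
)
from .simulate import evaluate
from .weights import WeightMatrix, estimate_weights, filter_low_counts, logcpm

logger = logging.getLogger(__name__)

__all__ = ["ODPStudy", "ODPResults", "RunConfig"]

#: default numbers of modules and bootstrap iterations; at least 200 modules
#: are recommended for complex designs
DEFAULT_K = 800
DEFAULT_B = 500
DEFAULT_E = 4

COMPARE_METHODS = ("modp", "f", "moderated-f", "bootstrap-f", "bootstrap-moderated-f")


@dataclass
class RunConfig:
    """Reproducibility record of one pipeline run."""

    design_kind: str
    d: object = "auto"
    K: int = DEFAULT_K
    B: int = DEFAULT_B
    E: int = DEFAULT_E
    seed: object = None
    weights: str = "none"
    min_count: int = 10
    test: str = "group-difference"

    def to_dict(self) -> dict:
        return {
            "design_kind": self.design_kind,
            "d": self.d,
            "K": self.K,
            "B": self.B,
            "E": self.E,
            "seed": self.seed,
            "weights": self.weights,
            "min_count": self.min_count,
            "test": self.test,
        }

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _batched_hat_diag(X: np.ndarray, sw: np.ndarray) -> np.ndarray:
    """Per-gene leverages diag(H_i) for row-scaled designs X_i = sw_i * X."""
    Xg = sw[:, :, None] * X[None, :, :]
    xtx = np.einsum("gnp,gnq->gpq", Xg, Xg)
    sol = np.linalg.solve(xtx, np.transpose(Xg, (0, 2, 1)))
    return np.einsum("gnp,gpn->gn", Xg, sol)


def _batched_null_project(X0: np.ndarray, sw: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual of projecting each row of Y on its own scaled null design."""
    Xg = sw[:, :, None] * X0[None, :, :]
    xtx = np.einsum("gnp,gnq->gpq", Xg, Xg)
    xty = np.einsum("gnp,gn->gp", Xg, Y)
    coef = np.linalg.solve(xtx, xty[..., None])[..., 0]
    return Y - np.einsum("gnp,gp->gn", Xg, coef)


class ODPStudy:
    """A gene expression study prepared for mODP significance analysis.

    Parameters
    ----------
    expression : ExpressionMatrix
        Log-scale expression, or raw counts with ``counts=True`` (then the
        logCPM transform, low-count filtering and precision-weight
        estimation are applied).
    design_kind : {"static", "independent", "longitudinal"}
    d : int or "auto"
        Spline dimension; "auto" selects it by eigen-gene LOOCV.
    test : {"group-difference", "any-effect"}
    weights : None, "estimate", or WeightMatrix / array
        Inverse-variance precision weights.
    counts : bool
        Treat the expression values as raw counts.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        design_kind: str = "static",
        d="auto",
        test: str = "group-difference",
        weights=None,
        counts: bool = False,
        min_count: int = 10,
        D: int = 4,
        E: int = DEFAULT_E,
    ):
        self.design_kind = design_kind
        self.test = test
        self.requested_d = d
        self.D = D
        self.E = E
        self.min_count = min_count
        self._weights_mode = (
            "estimate" if (isinstance(weights, str) and weights == "estimate")
            else ("file" if weights is not None else "none")
        )
        if counts:
            mask = filter_low_counts(expression.values, min_count)
            logger.info("count filter: keeping %d/%d genes", int(mask.sum()),
                        expression.n_genes)
            expression = expression.subset_genes(mask)
            self.counts = expression.values.copy()
            expression = ExpressionMatrix(
                logcpm(self.counts), expression.gene_ids, expression.sample_meta
            )
        else:
            self.counts = None
        self.expression = expression
        self._user_weights = None
        if self._weights_mode == "file":
            w = weights.weights if isinstance(weights, WeightMatrix) else np.asarray(weights)
            self._user_weights = WeightMatrix(w, provenance="user-supplied")

    @classmethod
    def from_files(
        cls, expression_path, metadata_path, format: str = "tsv", **kwargs
    ) -> "ODPStudy":
        em = read_expression(expression_path, format=format)
        meta = read_metadata(metadata_path, em)
        em = ExpressionMatrix(em.values, em.gene_ids, meta)
        return cls(em, **kwargs)

    # ------------------------------------------------------------------
    def select_spline_dimension(self) -> int:
        """Eigen-gene LOOCV choice of the spline dimension for this study."""
        if self.design_kind == "static":
            raise ValueError("static designs have no spline dimension")
        splits = None
        if self.design_kind == "longitudinal" and "group" in self.expression.sample_meta:
            splits = self.expression.group
        return select_dimension(
            self.expression.values,
            self.expression.covariate,
            D=self.D,
            E=self.E,
            splits=splits,
        )

    def design(self) -> ModelPair:
        d = self.requested_d
        if self.design_kind != "static" and (d == "auto" or d is None):
            d = self.select_spline_dimension()
            logger.info("selected spline dimension d=%d", d)
        self._d = None if self.design_kind == "static" else int(d)
        return build_study(
            self.expression.sample_meta,
            self.design_kind,
            spline_dimension=self._d,
            test=self.test,
        )

    # ------------------------------------------------------------------
    def _prepare(self, pair: ModelPair):
        """Fits, working-scale data and the null-transformed matrix."""
        Y = self.expression.values
        if self._weights_mode == "none":
            self._W = None
        elif self._weights_mode == "file":
            self._W = self._user_weights.weights
        else:
            if self.counts is None:
                raise ValueError("weights='estimate' requires counts=True")
            self._W = estimate_weights(self.counts, pair).weights
        if self._W is None:
            fits = fit_all(Y, pair, gene_ids=self.expression.gene_ids)
            Ywork = Y
        else:
            fits = fit_all(Y, pair, weights=self._W, gene_ids=self.expression.gene_ids)
            Ywork = np.sqrt(np.broadcast_to(self._W, Y.shape)) * Y
        Yt = null_transform(Ywork, fits)
        return fits, Ywork, Yt

    def _bootstrap_modp(self, Yt, pair, fits, modules, B, seed):
        from .significance import bootstrap_null

        if self._W is None:
            return bootstrap_null(Yt, pair, modules, B=B, seed=seed, fits=fits)
        # weighted path: per-gene designs, so leverage, the null projection
        # and the alternative refits are applied gene by gene (batched)
        from .core import modp_statistics_bootstrap

        sw = np.sqrt(np.broadcast_to(self._W, Yt.shape))
        h1 = _batched_hat_diag(pair.X_alt, sw)
        resid = (Yt - (fits.mu1 - fits.mu0)) / np.sqrt(np.maximum(1 - h1, 1e-12))
        rng = np.random.default_rng(seed)
        m, n = resid.shape
        pool = np.empty((B, m))
        # the weights belong to the measurement positions, not the resampled
        # residual values: on the sqrt(w)-transformed scale the studentized
        # residuals are exchangeable while position j keeps design row
        # sqrt(w_ij) x_j, so the per-gene projections are fixed across
        # iterations
        # signal-free per-gene scale target; see significance.bootstrap_null
        scale_target = (
            np.square(fits.sigma1) * n / (n - pair.p_alt) * (n - pair.p_null) / n
        )
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            ystar = _batched_null_project(pair.X_null, sw, resid[:, idx])
            var0_raw = np.square(ystar).sum(axis=1) / n
            ystar = ystar * np.sqrt(
                scale_target / np.maximum(var0_raw, 1e-300)
            )[:, None]
            mu1s = ystar - _batched_null_project(pair.X_alt, sw, ystar)
            var1s = np.square(ystar - mu1s).sum(axis=1) / n
            var0s = np.square(ystar).sum(axis=1) / n
            pool[b] = modp_statistics_bootstrap(
                ystar, modules, mu1s, var1s, var0s,
            )
        return pool.ravel()

    # ------------------------------------------------------------------
    def fit(
        self,
        K: int = DEFAULT_K,
        B: int = DEFAULT_B,
        seed=None,
        max_iter: int = 100,
        pair: ModelPair | None = None,
    ) -> "ODPResults":
        """Run the full mODP procedure and return the results object."""
        t0 = time.perf_counter()
        if pair is None:
            pair = self.design()
        ss = np.random.SeedSequence(seed)
        seed_cluster, seed_boot = ss.spawn(2)

        fits, Ywork, Yt = self._prepare(pair)
        mu1t = fits.mu1 - fits.mu0
        degenerate = fits.degenerate
        K_eff = min(K, int((~degenerate).sum()))
        if K_eff < K:
            logger.warning("reducing K from %d to %d clusterable genes", K, K_eff)
        modules = cluster_modules(
            mu1t, fits.sigma1, fits.sigma0, K=K_eff,
            seed=seed_cluster, max_iter=max_iter, exclude=degenerate,
        )
        logger.info(
            "clustering: K=%d, %d iterations, converged=%s",
            K_eff, modules.iterations_run, modules.converged,
        )
        observed = modp_statistics(Yt, modules)
        pool = self._bootstrap_modp(Yt, pair, fits, modules, B, seed_boot)
        sig = significance_from_pool(
            self.expression.gene_ids, observed, pool, B=B,
            method="modp", degenerate=degenerate,
        )
        config = RunConfig(
            design_kind=self.design_kind,
            d=self._d if self.design_kind != "static" else None,
            K=K_eff,
            B=B,
            E=self.E,
            seed=seed,
            weights=self._weights_mode,
            min_count=self.min_count,
            test=self.test,
        )
        logger.info(
            "mODP fit complete in %.2fs: pi0=%.3f, d=%s, K=%d, B=%d",
            time.perf_counter() - t0, sig.pi0, config.d, K_eff, B,
        )
        return ODPResults(
            study=self,
            pair=pair,
            fits=fits,
            modules=modules,
            significance=sig,
            config=config,
            transformed=Yt,
        )

    # ------------------------------------------------------------------
    def compare(
        self,
        K: int = DEFAULT_K,
        B: int = DEFAULT_B,
        seed=None,
        max_iter: int = 100,
    ) -> dict:
        """Run mODP and the four F-type benchmarks on identical inputs.

        Returns a dict mapping method name to its SignificanceTable; the
        bootstrap-based methods share the fanned-out seed stream.
        """
        ss = np.random.SeedSequence(seed)
        seed_modp, seed_fboot, seed_mfboot = ss.spawn(3)
        pair = self.design()
        results = {}
        res = self.fit(K=K, B=B, seed=seed, max_iter=max_iter, pair=pair)
        results["modp"] = res.significance

        Y = self.expression.values
        fits = res.fits if self._W is None else fit_all(
            Y, pair, gene_ids=self.expression.gene_ids
        )
        f = cmp_mod.f_statistics(fits)
        p_f = cmp_mod.f_pvalues(f, fits)
        results["f"] = _parametric_table(fits.gene_ids, f, p_f, "f")
        prior = cmp_mod.fit_variance_prior(fits.rss1 / (fits.n - fits.df1),
                                           fits.n - fits.df1)
        f_mod, p_mod = cmp_mod.moderated_f(fits, prior)
        results["moderated-f"] = _parametric_table(
            fits.gene_ids, f_mod, p_mod, "moderated-f"
        )
        results["bootstrap-f"] = cmp_mod.bootstrap_comparator(
            cmp_mod.f_statistics, Y, pair, B=B, seed=seed_fboot,
            gene_ids=fits.gene_ids, method="bootstrap-f",
        )
        results["bootstrap-moderated-f"] = cmp_mod.bootstrap_comparator(
            lambda ft: cmp_mod.moderated_f(ft, prior)[0], Y, pair, B=B,
            seed=seed_mfboot, gene_ids=fits.gene_ids,
            method="bootstrap-moderated-f",
        )
        return results


def _parametric_table(gene_ids, stat, p, method) -> SignificanceTable:
    from .significance import estimate_pi0, local_fdr, qvalues

    pi0 = estimate_pi0(p)
    return SignificanceTable(
        table=pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "stat": stat,
                "p_value": p,
                "q_value": qvalues(p, pi0),
                "lfdr": local_fdr(p, pi0),
            }
        ),
        pi0=pi0,
        B=0,
        pool_size=0,
        method=method,
    )


@dataclass
class ODPResults:
    """Results of a fitted mODP analysis.

    Carries the per-gene significance table (statistic, empirical p-value,
    q-value, local FDR), the global pi0 estimate, the module assignments and
    parameters, the per-gene model fits, and the run configuration.
    """

    study: ODPStudy
    pair: ModelPair
    fits: GeneFitTable
    modules: ModuleSet
    significance: SignificanceTable
    config: RunConfig
    transformed: np.ndarray = field(repr=False, default=None)

    @property
    def table(self) -> pd.DataFrame:
        return self.significance.table

    @property
    def pi0(self) -> float:
        return self.significance.pi0

    @property
    def d(self):
        return self.config.d

    def n_significant(self, q_cutoff: float = 0.1) -> int:
        return self.significance.n_significant(q_cutoff)

    def evaluate(self, truth, cutoffs=(0.0001, 0.001, 0.01, 0.05, 0.1)):
        return evaluate(self.table, truth, cutoffs)

    def module_table(self) -> pd.DataFrame:
        """Gene-to-module assignments (kl_clust-style output)."""
        return pd.DataFrame(
            {
                "gene_id": self.fits.gene_ids,
                "module": self.modules.assignment,
            }
        )

    def module_parameters(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": np.arange(self.modules.K),
                "size": self.modules.sizes,
                "upsilon1": self.modules.upsilon1,
                "upsilon0": self.modules.upsilon0,
            }
        )

    def summary(self) -> str:
        c = self.config
        sig = self.significance
        lines = [
            "Modular Optimal Discovery Procedure results",
            "===========================================",
            f"design:            {c.design_kind} ({c.test})",
            f"genes:             {len(self.fits.gene_ids)}",
            f"measurements:      {self.pair.n}",
            f"spline dimension:  {c.d if c.d is not None else '-'}",
            f"modules K:         {c.K} (converged={self.modules.converged}, "
            f"{self.modules.iterations_run} iterations)",
            f"bootstrap B:       {c.B} (null pool {sig.pool_size})",
            f"weights:           {c.weights}",
            f"pi0 estimate:      {sig.pi0:.4f}",
            f"significant genes: q<=0.05: {self.n_significant(0.05)}, "
            f"q<=0.10: {self.n_significant(0.10)}",
            f"config hash:       {c.hash}",
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the significance, module, fit and config artifacts as TSV/JSON."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        c = self.config
        header = (
            f"config_hash={c.hash} seed={c.seed} K={c.K} B={c.B} "
            f"d={c.d} pi0={self.pi0:.6g}"
        )
        self.significance.to_tsv(out / "significance.tsv", header_comment=header)
        self.module_table().to_csv(out / "modules.tsv", sep="\t", index=False)
        self.module_parameters().to_csv(
            out / "module_parameters.tsv", sep="\t", index=False
        )
        self.fits.to_tsv(out / "gene_fits.tsv")
        payload = self.config.to_dict()
        payload["config_hash"] = c.hash
        payload["pi0"] = self.pi0
        payload["converged"] = bool(self.modules.converged)
        (out / "config.json").write_text(json.dumps(payload, indent=2, default=str))
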