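import numpy as np
import pytest

from modp import empirical_pvalues, estimate_pi0, local_fdr, qvalues
from modp.significance import (
    bootstrap_pool,
    significance_from_pool,
    studentized_residuals,
)


def test_empirical_pvalues_hand_case():
    pool = np.array([1.0, 2.0, 3.0, 4.0])
    obs = np.array([5.0, 2.5, 0.0, 3.0])
    # counts of pool >= s: 0, 2, 4, 2 (ties count); add-one over size+1
    np.testing.assert_allclose(
        empirical_pvalues(obs, pool), [1 / 5, 3 / 5, 5 / 5, 3 / 5]
    )


def test_empirical_pvalues_strictly_positive_and_monotone(rng):
    pool = rng.standard_normal(1000)
    obs = rng.standard_normal(50)
    p = empirical_pvalues(obs, pool)
    assert np.all(p > 0) and np.all(p <= 1)
    order = np.argsort(obs)
    assert np.all(np.diff(p[order]) <= 0)  # larger statistic, smaller p


def test_qvalues_hand_case():
    p = np.array([0.04, 0.04, 0.04, 0.5])
    q = qvalues(p, pi0=1.0)
    # step-up: min over t >= p of m*t/#{p<=t}; the three ties get 4*0.04/3
    np.testing.assert_allclose(q, [0.16 / 3, 0.16 / 3, 0.16 / 3, 0.5])
    np.testing.assert_allclose(qvalues(p, pi0=0.5), [0.08 / 3] * 3 + [0.25])


def test_qvalues_monotone_and_capped(rng):
    p = rng.uniform(size=400)
    q = qvalues(p, pi0=0.9)
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_estimate_pi0_uniform_near_one(rng):
    p = rng.uniform(1e-12, 1.0, 5000)
    pi0 = estimate_pi0(p)
    assert 0.9 <= pi0 <= 1.0


def test_estimate_pi0_mixture_detects_signal(rng):
    p_null = rng.uniform(1e-12, 1.0, 3000)
    p_alt = rng.beta(0.2, 5.0, 1000) + 1e-12
    pi0 = estimate_pi0(np.concatenate([p_null, p_alt]))
    assert 0.6 <= pi0 <= 0.9


def test_estimate_pi0_small_sample_uses_fixed_lambda(rng):
    p = np.concatenate([np.full(30, 0.8), np.full(20, 0.2)])
    # #{p > 0.5} / (m * 0.5) = 30 / 25 -> clamped to 1
    assert estimate_pi0(p) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        estimate_pi0(np.array([0.0, 0.5]))


def test_local_fdr_monotone_and_bounded(rng):
    p = np.concatenate([rng.beta(0.2, 5.0, 500) + 1e-12, rng.uniform(1e-12, 1, 1500)])
    lfdr = local_fdr(p, pi0=0.75)
    assert np.all((lfdr >= 0) & (lfdr <= 1))
    order = np.argsort(p)
    assert np.all(np.diff(lfdr[order]) >= -1e-12)
    assert lfdr[order][:50].mean() < lfdr[order][-50:].mean()


def test_bootstrap_pool_shape_and_reproducibility(rng):
    resid = rng.standard_normal((30, 10))
    fn = lambda ystar: ystar.sum(axis=1)
    a = bootstrap_pool(resid, fn, B=7, seed=3)
    b = bootstrap_pool(resid, fn, B=7, seed=3)
    assert a.shape == (30 * 7,)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, bootstrap_pool(resid, fn, B=7, seed=4))
    with pytest.raises(ValueError):
        bootstrap_pool(resid, fn, B=0, seed=1)


def test_studentized_residuals_restore_error_scale(independent_pair, rng):
    from modp import fit_all, null_transform

    sigma = 1.7
    Y = sigma * rng.standard_normal((4000, independent_pair.n))
    fits = fit_all(Y, independent_pair)
    Yt = null_transform(Y, fits)
    r = studentized_residuals(Yt, independent_pair, fits)
    # leverage adjustment restores the per-observation error variance
    col_var = r.var(axis=0)
    np.testing.assert_allclose(col_var.mean(), sigma ** 2, rtol=0.05)


def test_significance_from_pool_degenerate_genes(rng):
    obs = np.array([3.0, 1.0, 2.5])
    pool = rng.standard_normal(500)
    degen = np.array([False, True, False])
    tab = significance_from_pool(["a", "b", "c"], obs, pool, B=5, degenerate=degen)
    row = tab.table.set_index("gene_id").loc["b"]
    assert row["p_value"] == 1.0
    assert row["stat"] == -np.inf
    assert tab.pool_size == 500


def test_global_null_pvalues_near_uniform():
    """End-to-end: on pure-noise data the pipeline's p-values are close to
    uniform (pi0 near 1 and no pile-up of small p-values)."""
    from modp import ODPStudy, simulate_study

    em, _ = simulate_study("independent", m=400, N=12, pi0=1.0, U=1, seed=10)
    res = ODPStudy(em, design_kind="independent", d=2).fit(K=40, B=40, seed=10)
    p = res.table["p_value"].to_numpy()
    assert res.pi0 > 0.8
    assert (p <= 0.05).mean() < 0.12
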