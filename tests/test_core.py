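import numpy as np
import pytest

from modp import (
    ModuleSet,
    cluster_modules,
    modp_statistic,
    modp_statistics,
    odp_statistic_full,
    symmetric_kl,
)
from modp.core import (
    clustering_objective,
    likelihood_evaluations,
    modp_statistics_bootstrap,
    reset_likelihood_counter,
)


def test_symmetric_kl_hand_case():
    # equal unit scales, mean difference (1, 0): distance = sum d_j^2 / 1 = 1
    assert symmetric_kl(np.array([1.0, 0.0]), 1.0, np.array([0.0, 0.0]), 1.0) == pytest.approx(1.0)


def test_symmetric_kl_identity_and_symmetry(rng):
    mu_a = rng.standard_normal(6)
    mu_b = rng.standard_normal(6)
    assert symmetric_kl(mu_a, 1.3, mu_a, 1.3) == pytest.approx(0.0)
    assert symmetric_kl(mu_a, 1.3, mu_b, 0.7) == pytest.approx(
        symmetric_kl(mu_b, 0.7, mu_a, 1.3)
    )
    with pytest.raises(ValueError):
        symmetric_kl(mu_a, 0.0, mu_b, 1.0)


def _toy_parameters(rng, m=120, n=8, groups=3):
    """Well-separated planted clusters of fitted gene models."""
    centers = rng.standard_normal((groups, n)) * 5.0
    labels = rng.integers(0, groups, m)
    mu1 = centers[labels] + 0.1 * rng.standard_normal((m, n))
    sigma1 = np.full(m, 1.0) + 0.01 * rng.uniform(size=m)
    sigma0 = sigma1 * 1.5
    return mu1, sigma1, sigma0, labels


def test_cluster_modules_recovers_planted_partition(rng):
    mu1, sigma1, sigma0, labels = _toy_parameters(rng)
    modules = cluster_modules(mu1, sigma1, sigma0, K=3, seed=11)
    assert modules.converged
    # assignment matches the planted labels up to relabeling
    for k in range(3):
        members = modules.assignment == k
        assert members.sum() > 0
        assert np.unique(labels[members]).size == 1
    assert modules.sizes.sum() == 120


def test_cluster_modules_seed_reproducible(rng):
    mu1, sigma1, sigma0, _ = _toy_parameters(rng)
    a = cluster_modules(mu1, sigma1, sigma0, K=5, seed=2)
    b = cluster_modules(mu1, sigma1, sigma0, K=5, seed=2)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    np.testing.assert_allclose(a.centers, b.centers)


def test_cluster_modules_objective_nonincreasing_in_k(rng):
    mu1, sigma1, sigma0, _ = _toy_parameters(rng, m=200)
    objs = []
    for K in (2, 5, 10):
        modules = cluster_modules(mu1, sigma1, sigma0, K=K, seed=4)
        objs.append(clustering_objective(mu1, sigma1, modules))
    assert objs[0] >= objs[1] >= objs[2]


def test_cluster_modules_excluded_genes(rng):
    mu1, sigma1, sigma0, _ = _toy_parameters(rng)
    exclude = np.zeros(120, dtype=bool)
    exclude[:7] = True
    modules = cluster_modules(mu1, sigma1, sigma0, K=4, seed=1, exclude=exclude)
    assert np.all(modules.assignment[:7] == -1)
    assert modules.sizes.sum() == 113
    with pytest.raises(ValueError):
        cluster_modules(mu1, sigma1, sigma0, K=200, seed=1)


def test_module_set_validation():
    with pytest.raises(ValueError):
        ModuleSet(
            K=1,
            assignment=np.array([0, 0]),
            centers=np.zeros((1, 3)),
            upsilon1=np.array([1.0]),
            upsilon0=np.array([1.0]),
            sizes=np.array([5]),
        )


def test_singleton_modules_reproduce_full_odp(rng):
    """K = m with one gene per module must equal the full estimated ODP."""
    m, n = 40, 10
    mu1 = rng.standard_normal((m, n))
    sigma1 = rng.uniform(0.5, 2.0, m)
    sigma0 = sigma1 * rng.uniform(1.0, 1.5, m)
    Yt = rng.standard_normal((m, n))
    modules = ModuleSet(
        K=m,
        assignment=np.arange(m),
        centers=mu1.copy(),
        upsilon1=sigma1.copy(),
        upsilon0=sigma0.copy(),
        sizes=np.ones(m, dtype=int),
    )
    stats_mod = modp_statistics(Yt, modules)
    stats_full = odp_statistic_full(Yt, mu1, sigma1, sigma0)
    np.testing.assert_allclose(stats_mod, stats_full, atol=1e-10, rtol=0)


def test_modp_statistic_scalar_matches_vectorized(rng):
    mu1, sigma1, sigma0, _ = _toy_parameters(rng)
    modules = cluster_modules(mu1, sigma1, sigma0, K=4, seed=9)
    Yt = rng.standard_normal((5, 8))
    stats = modp_statistics(Yt, modules)
    assert modp_statistic(Yt[2], modules) == pytest.approx(stats[2])


def test_likelihood_evaluation_count_is_2km(rng):
    mu1, sigma1, sigma0, _ = _toy_parameters(rng)
    modules = cluster_modules(mu1, sigma1, sigma0, K=6, seed=3)
    Yt = rng.standard_normal((120, 8))
    reset_likelihood_counter()
    modp_statistics(Yt, modules)
    assert likelihood_evaluations() == 2 * 120 * 6
    reset_likelihood_counter()
    odp_statistic_full(Yt, mu1, sigma1, sigma0)
    assert likelihood_evaluations() == 2 * 120 * 120


def test_bootstrap_statistic_is_identity_on_observed_fit(rng):
    """At clustering convergence, feeding the observed refits back through
    the bootstrap statistic must reproduce the plain statistic exactly."""
    mu1, sigma1, sigma0, _ = _toy_parameters(rng)
    modules = cluster_modules(mu1, sigma1, sigma0, K=4, seed=21)
    Yt = mu1 + rng.standard_normal(mu1.shape)
    plain = modp_statistics(Yt, modules)
    mirrored = modp_statistics_bootstrap(
        Yt, modules, mu1, np.square(sigma1), np.square(sigma0)
    )
    np.testing.assert_allclose(mirrored, plain, atol=1e-12)
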