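import numpy as np
import pytest
from scipy import stats

from modp import build_study, fit_all, fit_gene
from modp.comparators import (
    ModeratedVariancePrior,
    bootstrap_comparator,
    f_pvalues,
    f_statistic,
    f_statistics,
    fit_variance_prior,
    moderated_f,
)


def _pair_2x2():
    import pandas as pd

    meta = pd.DataFrame(
        {"sample_id": ["s0", "s1", "s2", "s3"], "group": ["a", "a", "b", "b"]}
    )
    return build_study(meta, "static")


def test_f_statistic_hand_case():
    # y = (1,3,5,7), groups (a,a,b,b): rss0 = 20, rss1 = 4,
    # F = ((20-4)/1) / (4/2) = 8
    pair = _pair_2x2()
    fit = fit_gene(np.array([1.0, 3.0, 5.0, 7.0]), pair)
    assert f_statistic(fit) == pytest.approx(8.0)
    fits = fit_all(np.array([[1.0, 3.0, 5.0, 7.0]]), pair)
    np.testing.assert_allclose(f_statistics(fits), [8.0])


def test_f_statistics_degenerate_gene():
    pair = _pair_2x2()
    fits = fit_all(np.array([[1.0, 1.0, 2.0, 2.0]]), pair)  # exact fit
    assert f_statistics(fits)[0] == np.inf


def test_f_pvalues_uniform_under_null(static_pair, rng):
    Y = rng.standard_normal((4000, 6))
    fits = fit_all(Y, static_pair)
    p = f_pvalues(f_statistics(fits), fits)
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.03


def test_fit_variance_prior_recovers_hyperparameters(rng):
    d0, s0_sq, df = 4.0, 1.3, 10
    m = 5000
    sigma_sq = d0 * s0_sq / rng.chisquare(d0, m)
    s_sq = sigma_sq * rng.chisquare(df, m) / df
    prior = fit_variance_prior(s_sq, df)
    assert 3.0 <= prior.d0 <= 5.5
    assert 0.9 * s0_sq <= prior.s0_sq <= 1.1 * s0_sq


def test_fit_variance_prior_degenerate_branch(rng):
    # identical variances: zero spread below the sampling-noise floor
    s_sq = np.full(200, 2.0)
    prior = fit_variance_prior(s_sq, 200)
    assert np.isinf(prior.d0)
    assert prior.s0_sq == pytest.approx(2.0, rel=0.05)
    with pytest.raises(ValueError):
        fit_variance_prior(s_sq[:10], 200)
    with pytest.raises(ValueError):
        ModeratedVariancePrior(d0=-1.0, s0_sq=1.0)


def test_moderated_f_shrinks_toward_prior(static_pair, rng):
    Y = rng.standard_normal((500, 6))
    fits = fit_all(Y, static_pair)
    prior = fit_variance_prior(fits.rss1 / (fits.n - fits.df1), fits.n - fits.df1)
    f_mod, p = moderated_f(fits, prior)
    f_raw = f_statistics(fits)
    # moderation dampens the extremes: fewer huge statistics than raw F
    assert f_mod.max() < f_raw.max()
    assert np.all((p > 0) & (p <= 1))


def test_moderated_f_infinite_prior_uses_pooled_variance(static_pair, rng):
    Y = rng.standard_normal((200, 6))
    fits = fit_all(Y, static_pair)
    prior = ModeratedVariancePrior(d0=np.inf, s0_sq=2.0)
    f_mod, p = moderated_f(fits, prior)
    np.testing.assert_allclose(f_mod, (fits.rss0 - fits.rss1) / 2.0)


def test_bootstrap_comparator_reproducible_and_calibrated(static_pair, rng):
    Y = rng.standard_normal((300, 6))
    a = bootstrap_comparator(f_statistics, Y, static_pair, B=30, seed=5)
    b = bootstrap_comparator(f_statistics, Y, static_pair, B=30, seed=5)
    np.testing.assert_array_equal(
        a.table["p_value"].to_numpy(), b.table["p_value"].to_numpy()
    )
    p = a.table["p_value"].to_numpy()
    # pure-noise data: no pile-up of small p-values
    assert (p <= 0.05).mean() < 0.12
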