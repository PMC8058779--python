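import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modp import evaluate, simulate_counts, simulate_study


def test_simulate_study_truth_bookkeeping():
    em, truth = simulate_study("independent", m=500, N=14, pi0=0.8, U=6, seed=1)
    assert em.values.shape == (500, 14)
    assert truth.m1 == 100
    assert truth.is_alternative.sum() == 100
    # every alternative gene carries one of the U profile labels
    prof = truth.table.loc[truth.is_alternative, "profile"]
    assert prof.between(0, 5).all()
    assert (truth.table.loc[~truth.is_alternative, "profile"] == -1).all()


def test_simulate_study_seed_reproducible():
    em1, t1 = simulate_study("static", m=100, N=10, pi0=0.5, U=2, seed=9)
    em2, t2 = simulate_study("static", m=100, N=10, pi0=0.5, U=2, seed=9)
    np.testing.assert_array_equal(em1.values, em2.values)
    pd.testing.assert_frame_equal(t1.table, t2.table)


def test_simulate_study_snr_is_realized():
    em, truth = simulate_study(
        "independent", m=400, N=20, pi0=0.5, U=4, snr=2.0, seed=3
    )
    # reconstruct the signal norms: ||signal|| = snr * sigma * sqrt(N)
    alt = truth.is_alternative
    sig = truth.table["sigma"].to_numpy()[alt]
    # mean expression of alternative genes deviates from flat by the signal;
    # check the aggregate energy matches the prescription within noise
    Y = em.values[alt]
    energy = np.square(Y - Y.mean(axis=1, keepdims=True)).sum(axis=1)
    expected = (2.0 * sig) ** 2 * 20 + sig ** 2 * 19  # signal + noise energy
    assert np.median(energy / expected) == pytest.approx(1.0, rel=0.2)


def test_simulate_study_validation():
    with pytest.raises(ValueError):
        simulate_study("independent", m=100, N=10, pi0=0.9, U=50, seed=1)
    with pytest.raises(ValueError):
        simulate_study("independent", m=100, N=10, snr=0.0, seed=1)


def test_simulate_counts_depth_balanced():
    """Alternative effects must not shift aggregate expected depth between
    groups, or column-sum CPM would corrupt the null genes."""
    counts, meta, truth = simulate_counts(m=2000, N=16, pi0=0.8, U=10, seed=2)
    grp = meta["group"].to_numpy()
    lib_a = counts[:, grp == "a"].sum(axis=0).mean()
    lib_b = counts[:, grp == "b"].sum(axis=0).mean()
    assert abs(np.log2(lib_a / lib_b)) < 0.05


def test_simulate_counts_null_f_test_calibrated():
    from modp import build_study, fit_all, logcpm
    from modp.comparators import f_pvalues, f_statistics

    counts, meta, truth = simulate_counts(m=3000, N=16, pi0=0.8, U=10, seed=4)
    pair = build_study(meta, "static")
    fits = fit_all(logcpm(counts), pair)
    p = f_pvalues(f_statistics(fits), fits)
    null_rej = (p[~truth.is_alternative] <= 0.05).mean()
    assert null_rej < 0.08


def test_simulate_counts_overdispersion():
    counts, _, _ = simulate_counts(m=4000, N=16, pi0=1.0, U=1, phi=0.3, seed=6)
    mu = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    big = mu > 100
    phi_hat = np.median((var[big] - mu[big]) / np.square(mu[big]))
    assert phi_hat == pytest.approx(0.3, rel=0.25)
    # Poisson mode
    pcounts, _, _ = simulate_counts(m=4000, N=16, pi0=1.0, U=1, phi=0.0, seed=6)
    pmu = pcounts.mean(axis=1)
    pvar = pcounts.var(axis=1, ddof=1)
    assert np.median(pvar / np.maximum(pmu, 1)) == pytest.approx(1.0, rel=0.2)
    with pytest.raises(ValueError):
        simulate_counts(m=100, N=8, phi=-0.1, seed=1)


def test_evaluate_fdp_and_power_hand_case():
    truth_table = pd.DataFrame(
        {
            "gene_id": ["g0", "g1", "g2", "g3"],
            "status": ["alternative", "null", "alternative", "null"],
            "profile": [0, -1, 0, -1],
            "sigma": [1.0] * 4,
        }
    )
    from modp import SimulationTruth

    truth = SimulationTruth(
        table=truth_table, m=4, pi0=0.5, U=1, design_kind="static"
    )
    calls = pd.DataFrame(
        {"gene_id": ["g0", "g1", "g2", "g3"], "q_value": [0.01, 0.04, 0.2, 0.9]}
    )
    res = evaluate(calls, truth, cutoffs=(0.05, 0.5))
    row = res.set_index("cutoff")
    assert row.loc[0.05, "discoveries"] == 2
    assert row.loc[0.05, "fdp"] == pytest.approx(0.5)
    assert row.loc[0.05, "power"] == pytest.approx(0.5)
    assert row.loc[0.5, "power"] == pytest.approx(1.0)
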