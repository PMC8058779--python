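"""Shared fixtures: small deterministic studies used across test modules."""

import numpy as np
import pandas as pd
import pytest

from modp import ExpressionMatrix, build_study, simulate_study


@pytest.fixture(scope="session")
def static_pair():
    """Two-group static design, 3 + 3 measurements."""
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["a", "a", "a", "b", "b", "b"],
        }
    )
    return build_study(meta, "static")


@pytest.fixture(scope="session")
def independent_pair():
    rng = np.random.default_rng(7)
    x = np.sort(rng.uniform(0.0, 1.0, 16))
    meta = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(16)], "covariate": x}
    )
    return build_study(meta, "independent", spline_dimension=2)


@pytest.fixture(scope="session")
def small_study():
    """A small independent-design simulated study with known truth."""
    em, truth = simulate_study(
        "independent", m=300, N=16, pi0=0.7, U=4, snr=2.0, seed=42
    )
    return em, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
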