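import numpy as np
import pandas as pd
import pytest

import cropclim as cc


@pytest.fixture(scope="session")
def small_truth():
    """A small simulated study shared by design/inference tests."""
    cfg = cc.SimConfig(n_municipalities=20, n_years=6, seed=42)
    yearly, monthly = cc.simulate_climate(cfg)
    truth = cc.simulate_panel(cfg, yearly)
    return truth


@pytest.fixture(scope="session")
def small_design(small_truth):
    return cc.build_design(
        small_truth.panel, small_truth.climate, "coffee", "avg_temperature"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_model_data(rng, n_max=12):
    """A random tiny ModelData instance for oracle tests."""
    N = int(rng.integers(1, 4))
    T = int(rng.integers(1, 4))
    n = int(rng.integers(1, n_max))
    return cc.ModelData(
        y=rng.integers(0, 30, size=n),
        offset_eps=rng.integers(1, 50, size=n),
        x=rng.normal(0.0, 1.0, size=n),
        muni_index=rng.integers(0, N, size=n),
        year_index=rng.integers(0, T, size=n),
        N=N,
        T=T,
    )


def random_params(rng, N, T):
    delta = rng.normal(0.0, 0.5, size=T)
    delta -= delta.mean()
    return cc.Params(
        alpha=float(rng.normal(0.0, 0.3)),
        beta=float(rng.normal(0.0, 0.3)),
        gamma=rng.normal(0.0, 0.5, size=N),
        delta=delta,
        tau_gamma=float(rng.gamma(2.0, 1.0) + 0.1),
        tau_delta=float(rng.gamma(2.0, 1.0) + 0.1),
    )
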