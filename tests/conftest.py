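import warnings

import numpy as np
import pytest

import quadcount as qc
from quadcount.datasets import crowd_table, penguin_table

# Fixture geometry shared by the Monte Carlo acceptance checks: a 1796x1200
# picture, grid t=50/T=250 tilted 60 deg, 32x32 systematic offsets.
MC_WIDTH, MC_HEIGHT = 1796.0, 1200.0
MC_N = 1120
MC_SPEC = qc.GridSpec(t=50.0, T=250.0, theta_deg=60.0)
MC_K = 32


@pytest.fixture(scope="session")
def crowd_summary() -> qc.StripeSummary:
    return qc.StripeSummary.from_table(crowd_table(), tau=0.2)


@pytest.fixture(scope="session")
def penguin_summary() -> qc.StripeSummary:
    return qc.StripeSummary.from_table(penguin_table(), tau=0.15)


@pytest.fixture(scope="session")
def homogeneous_pattern() -> qc.PointPattern:
    cfg = qc.PatternConfig(
        kind="homogeneous", width=MC_WIDTH, height=MC_HEIGHT, n_points=MC_N, seed=7
    )
    return qc.generate(cfg)


@pytest.fixture(scope="session")
def two_density_pattern() -> qc.PointPattern:
    """Crowd-like stand-in: a wide sparse front block and a dense back block."""
    cfg = qc.PatternConfig(
        kind="two_density",
        width=MC_WIDTH,
        height=MC_HEIGHT,
        n_points=MC_N,
        seed=7,
        density_ratio=30.0,
        split_fraction=0.8,
    )
    return qc.generate(cfg)


@pytest.fixture(scope="session")
def homogeneous_sweep(homogeneous_pattern) -> qc.McResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return qc.run_sweep(homogeneous_pattern, MC_SPEC, k_side=MC_K, seed=1)


@pytest.fixture(scope="session")
def two_density_sweep(two_density_pattern) -> qc.McResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return qc.run_sweep(two_density_pattern, MC_SPEC, k_side=MC_K, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
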