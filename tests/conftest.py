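"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigscreen import (
    ExpressionDataset,
    SimulationConfig,
    simulate_survival_dataset,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signal_cfg() -> SimulationConfig:
    """Moderate-size signal configuration used by most end-to-end tests."""
    return SimulationConfig(n_genes=2000, n_samples=150, program_size=50, seed=7)


@pytest.fixture(scope="session")
def signal_dataset(signal_cfg):
    return simulate_survival_dataset(signal_cfg, dataset_id="SIGNAL", seed=7)


@pytest.fixture(scope="session")
def null_dataset(signal_cfg):
    return simulate_survival_dataset(signal_cfg.null(), dataset_id="NULL", seed=8)


@pytest.fixture()
def two_block_dataset() -> ExpressionDataset:
    """20 samples in two blocks; within a block every profile is identical.

    Block membership is recoverable exactly by any correlation-based
    clustering, which makes the expected stratification unambiguous.
    """
    rng = np.random.default_rng(0)
    profile_a = rng.normal(size=30)
    profile_b = -profile_a
    X = np.column_stack([profile_a] * 10 + [profile_b] * 10)
    X += rng.normal(0, 1e-6, size=X.shape)  # break exact rank ties
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
    rng2 = np.random.default_rng(1)
    clinical = pd.DataFrame(
        {
            "time": rng2.uniform(1, 10, 20),
            "event": rng2.integers(0, 2, 20),
        },
        index=pd.Index(samples, name="sample"),
    )
    clinical.iloc[0, clinical.columns.get_loc("event")] = 1  # ensure >= 1 event
    return ExpressionDataset(
        id="TWOBLOCK", matrix=pd.DataFrame(X, index=genes, columns=samples),
        clinical=clinical, endpoint="RFS",
    )
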