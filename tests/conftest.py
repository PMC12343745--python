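"""Shared fixtures.

Heavy end-to-end runs (one 1R and one 2R replicate at the reduced profile)
are session-scoped so the origin-accuracy, environmental-imputation and
demography tests share a single simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from geaplus.evaluation import run_experiment
from geaplus.io import RunConfig

PREDICTOR = {
    "batch_size": 32,
    "n_folds": 5,
    "n_replicates": 2,
    "hidden_layer_sizes": (128, 64),
    "dropout": 0.1,
    "learning_rate": 5e-3,
    "max_epochs": 600,
    "patience": 50,
}


def _accuracy_config(scenario: str) -> RunConfig:
    # schemes=[] trains the predictor and imputes environments without the
    # scan stage; the scheme pipeline is exercised in test_evaluation
    return RunConfig(scenario=scenario, seeds=[1], schemes=[], predictor=PREDICTOR)


@pytest.fixture(scope="session")
def run_2r():
    """Full 2R replicate: simulate, mask, predict origins, impute env."""
    return run_experiment(_accuracy_config("2R"), keep_artifacts=True)


@pytest.fixture(scope="session")
def run_1r():
    """Full 1R replicate, paired with run_2r (same seed and landscape)."""
    return run_experiment(_accuracy_config("1R"), keep_artifacts=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
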