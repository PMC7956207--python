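import dataclasses

import numpy as np
import pytest

from p300gomoku.bnn import TrainConfig
from p300gomoku.session import (
    SessionConfig, run_training_session, train_model,
)


def small_train_cfg(**kw):
    defaults = dict(n_epochs=12, mc_test=8)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """A noiseless, reduced-size study: perfectly separable by construction."""
    return SessionConfig(
        n_training_trials=10,
        n_exp1_trials=4,
        noise_sd_uV=0.0,
        mc_test=4,
        train=small_train_cfg(),
    )


@pytest.fixture(scope="session")
def noiseless_model(noiseless_cfg):
    dataset = run_training_session(noiseless_cfg, seed=101)
    model, trace = train_model(dataset, noiseless_cfg, seed=101)
    return model


@pytest.fixture(scope="session")
def moderate_cfg():
    """Moderate-SNR study at reduced size, for stochastic-regime tests."""
    return SessionConfig(
        n_training_trials=14,
        n_exp1_trials=6,
        mc_test=8,
        train=small_train_cfg(n_epochs=20),
    )


@pytest.fixture(scope="session")
def moderate_model(moderate_cfg):
    dataset = run_training_session(moderate_cfg, seed=202)
    model, _ = train_model(dataset, moderate_cfg, seed=202)
    return model


@pytest.fixture(scope="session")
def noiseless_exp2(noiseless_model, noiseless_cfg):
    """One full closed-loop noiseless game (shared: it is the expensive
    end-to-end run)."""
    from p300gomoku.session import run_experiment2

    return run_experiment2(noiseless_model, noiseless_cfg, seed=303)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
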