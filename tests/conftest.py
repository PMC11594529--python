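"""Shared fixtures.

The expensive objects (the default 266-measurement scheme and trained
amortized estimators) are session-scoped so the whole suite pays for
them once. Estimator scales are desk scale: large enough for the
statistical properties under test, small enough for a single CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from dmipost.experiments import BS_DEGENERACY_RECIPE, train_estimator
from dmipost.protocol_io import make_default_scheme
from dmipost.simulation_engine import generate_training_set


@pytest.fixture(scope="session")
def scheme():
    return make_default_scheme()


@pytest.fixture(scope="session")
def bs_train_small(scheme):
    """Small noise-free Ball&Stick training set for cheap checks."""
    return generate_training_set("ball_stick", scheme, 4000, None, seed=11)


@pytest.fixture(scope="session")
def bs_ap_full(scheme):
    """Ball&Stick estimator trained with the degeneracy-count recipe
    (noise-free, 4e5 simulations, early stopping)."""
    return train_estimator("ball_stick", scheme, snr=None, seed=0,
                           **BS_DEGENERACY_RECIPE)


@pytest.fixture(scope="session")
def bs_ap_snr50(scheme):
    """Ball&Stick estimator trained on Rician SNR-50 simulations, for
    noise-matched comparisons against the MCMC reference."""
    return train_estimator(
        "ball_stick", scheme, n_train=50_000, snr=50.0, seed=1,
        n_features=6, max_epochs=60, patience=30,
    )


@pytest.fixture(scope="session")
def bs_ap_snr25(scheme):
    """As ``bs_ap_snr50`` but at SNR 25 (matched training scale)."""
    return train_estimator(
        "ball_stick", scheme, n_train=50_000, snr=25.0, seed=1,
        n_features=6, max_epochs=60, patience=30,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
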