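import numpy as np
import pytest

from riskcoh.task_synth import SessionConfig, simulate_session


@pytest.fixture(scope="session")
def small_bundle():
    """Small full session (spikes + LFP + coupling) shared across tests."""
    cfg = SessionConfig(n_trials=135, n_units=6, n_electrodes=3)
    return simulate_session(cfg, seed=7)


@pytest.fixture(scope="session")
def spiking_bundle():
    """Spike-only session with disjoint EV/variance coding populations."""
    cfg = SessionConfig(
        n_trials=360, n_units=40, make_lfp=False,
        coding_mixture={"ev+": 0.2, "ev-": 0.2, "variance+": 0.2, "variance-": 0.2},
        ev_effect=0.8, variance_effect=1.0,
    )
    return simulate_session(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
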