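import numpy as np
import pytest

from dynafc import synthetic as syn


@pytest.fixture(scope="session")
def garch_default():
    return syn.GarchParams(omega=0.05, alpha=0.10, beta=0.85)


@pytest.fixture(scope="session")
def dcc_dynamic():
    return syn.DccParams(a=0.05, b=0.90, rho_bar=0.30)


@pytest.fixture(scope="session")
def dcc_constant():
    return syn.DccParams(a=0.0, b=0.0, rho_bar=0.30)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort reused by shape/IO tests."""
    cfg = syn.CohortConfig(n_participants=6, n_nodes=5, n_trs=120, seed=7)
    return syn.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
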