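import numpy as np
import pytest

import seizprop as sp


@pytest.fixture(scope="session")
def default_q():
    return sp.DEFAULT_TRUE_Q


@pytest.fixture(scope="session")
def small_net():
    return sp.generate_network(8, density=0.6, seed=42)


@pytest.fixture(scope="session")
def wellposed_seizure():
    """A partially observed noisy seizure on a 20-region network with its
    ground truth; the standard well-posed fitting problem used across tests."""
    W = sp.generate_network(20, seed=7)
    obs, truth = sp.generate_seizure(W, sp.DEFAULT_TRUE_Q, hidden_fraction=0.3,
                                     noise_sd=5.0, seed=8)
    return W, obs, truth


@pytest.fixture(scope="session")
def wellposed_fit(wellposed_seizure):
    W, obs, truth = wellposed_seizure
    fit = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, chains=2, warmup=500,
                           draws=500, seed=43)
    return W, obs, truth, fit


@pytest.fixture(scope="session")
def prior_fit():
    """Sampling with every region hidden: the posterior is the N(0,1) prior."""
    n = 10
    W = sp.generate_network(n, seed=1)
    obs = sp.SeizureObservation(
        list(W.region_ids),
        np.array(["hidden"] * n, dtype=object),
        np.full(n, np.inf),
    )
    fit = sp.sample_single(obs, W, sp.DEFAULT_TRUE_Q, chains=2, warmup=500,
                           draws=500, seed=42)
    return fit
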