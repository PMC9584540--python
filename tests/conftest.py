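"""Shared fixtures: cached configurations, connectivities, and baselines.

Baseline profiles come from noiseless, driveless relaxations and are cached
per (N, M, l, mode) for the whole session since many theory tests reuse
them.
"""

import numpy as np
import pytest
from hypothesis import settings

from ringbump import ModelConfig, baseline_profile, build_connectivity

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def network_cache():
    cache = {}

    def get(N, M, l=None, mode="rate", mapping="linear"):
        key = (N, M, l, mode, mapping)
        if key not in cache:
            cfg = ModelConfig(N=N, M=M, l=l, mode=mode, mapping=mapping)
            conn = build_connectivity(cfg)
            g = baseline_profile(cfg, conn, seed=1)
            cache[key] = (cfg, conn, g)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def net203(network_cache):
    """200-neuron, 3-bump reference network with inhibition distance l=29."""
    return network_cache(200, 3, l=29.0)


@pytest.fixture(scope="session")
def net201(network_cache):
    """200-neuron single-bump network."""
    return network_cache(200, 1)


@pytest.fixture(scope="session")
def net601(network_cache):
    """600-neuron single-bump network (connectivity-noise experiments)."""
    return network_cache(600, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
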