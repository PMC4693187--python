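"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from pathforge import bst, netcore


@pytest.fixture
def chain3():
    """Symmetric 3-step pathway fixture (network, reference)."""
    return netcore.make_unbranched_pathway(n=3, feedback_order=-0.5)


@pytest.fixture
def chain3_model(chain3):
    net, ref = chain3
    return bst.build_model(net, ref)


@pytest.fixture
def ammonia():
    return netcore.make_ammonia_network()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pathway(rng, n=None):
    """Random unbranched-pathway fixture used by round-trip/property tests."""
    n = n or int(rng.integers(1, 6))
    theta = {i: float(rng.uniform(0.0, 0.95)) if rng.random() < 0.5 else 0.0
             for i in range(1, n + 1)}
    keq = {i: float(rng.uniform(0.2, 5.0)) for i in range(1, n + 1)}
    fb = float(-rng.uniform(0.1, 2.0))
    return netcore.make_unbranched_pathway(n=n, feedback_order=fb, theta=theta, keq=keq)
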