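"""Shared fixtures: sessions are generated once per test run."""
from __future__ import annotations

import numpy as np
import pytest

from viscotact.session import SessionConfig, generate_dataset


@pytest.fixture(scope="session")
def default_session():
    """Full default session: 40 neurons (15 FA-1, 15 SA-1, 10 SA-2), seed 1."""
    return generate_dataset(SessionConfig(seed=1))


@pytest.fixture(scope="session")
def small_session():
    """Six-neuron session for structural and I/O tests."""
    return generate_dataset(SessionConfig(seed=3, n_fa1=2, n_sa1=2, n_sa2=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
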