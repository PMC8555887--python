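import numpy as np
import pytest

from cascadenet.connectome import Connectome
from cascadenet.hemodynamics import BoldSeries


@pytest.fixture
def motif3():
    """Tiny 3-region ring with distinct tract lengths."""
    W = np.array([[0.0, 0.5, 0.2],
                  [0.3, 0.0, 0.4],
                  [0.1, 0.6, 0.0]])
    L = np.array([[0.0, 8.0, 16.0],
                  [8.0, 0.0, 24.0],
                  [16.0, 24.0, 0.0]])
    return Connectome(weights=W, tract_lengths=L, labels=["a", "b", "c"])


@pytest.fixture
def symmetric_pair():
    """Two identical regions, symmetric coupling, zero-length tracts."""
    W = np.array([[0.0, 0.5], [0.5, 0.0]])
    L = np.zeros((2, 2))
    return Connectome(weights=W, tract_lengths=L)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_bold(X, TR=2.0):
    return BoldSeries(B=np.asarray(X, dtype=float), TR=TR)


@pytest.fixture
def correlated_bold(rng):
    """Correlated multi-region BOLD toy: shared slow signal + noise."""
    n, T = 8, 240
    t = np.arange(T)
    shared = np.sin(2 * np.pi * t / 40.0)
    B = 0.8 * shared[None, :] * rng.uniform(0.5, 1.5, size=(n, 1))
    B += 0.5 * rng.normal(size=(n, T))
    return make_bold(B)
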