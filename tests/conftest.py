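import numpy as np
import pytest

from insightews import SimConfig, generate_corpus
from insightews.observation import EventSeries, with_recomputed_is_new


def make_series(session_id, times, labels):
    """EventSeries with is_new derived from first occurrences."""
    return with_recomputed_is_new(session_id, times, labels)


@pytest.fixture(scope="session")
def small_corpus():
    """A short synthetic corpus for pipeline tests (fast, insights present)."""
    sim = SimConfig(n_steps=800, noise_sigma=0.02, gamma_start=0.1, gamma_end=0.3)
    return generate_corpus(n_sessions=6, n_symbols=10, sim=sim, master_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
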