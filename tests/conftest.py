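import numpy as np
import pytest

from srtlearn.sequence_stats import LocationSequence


@pytest.fixture(scope="session")
def worked_seq() -> LocationSequence:
    """The canonical eight-trial repetitive sequence a-b-a-b-c-d-c-d."""
    return LocationSequence.from_string("a-b-a-b-c-d-c-d")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def exp1_sim():
    """Full-design Experiment-1-style dataset shared across tests
    (6 groups x 8 subjects, fixed seed)."""
    from srtlearn import rt_synth
    return rt_synth.simulate_experiment1(n_per_group=8, seed=101)
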