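import numpy as np
import pytest

from callstack.data_model import CallDataset, Site
from callstack.simulate import SimConfig, simulate_dataset


def make_dataset(calls, labels=None, caller_names=None, features=None):
    """Build a small CallDataset from a call matrix, inventing site keys."""
    calls = np.asarray(calls, dtype=np.int8)
    n, k = calls.shape
    caller_names = list(caller_names or "ABC"[:k])
    sites = [Site("1", 100 + i, "A", "G") for i in range(n)]
    return CallDataset(
        sites=sites,
        caller_names=caller_names,
        calls=calls,
        labels=None if labels is None else np.asarray(labels, dtype=np.int8),
        features=features,
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """A default-conditions simulated dataset, sized for fast unit tests."""
    return simulate_dataset(SimConfig(n_candidate_sites=4000), seed=7)


@pytest.fixture(scope="session")
def seven_status_dataset():
    """Seven sites covering every nonzero 3-caller combination status."""
    rows = [(1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    return make_dataset(rows, labels=[1, 1, 1, 0, 1, 0, 0])
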