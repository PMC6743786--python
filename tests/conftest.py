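"""Shared fixtures: packaged example networks and reusable SSA datasets.

Simulation is the expensive step, so datasets are session-scoped and shared
across tests; every test that mutates data works on copies.
"""

import numpy as np
import pytest

from trajinfo import PathLikelihoodModel, make_example
from trajinfo.simulate import discrete_matrix, simulate_dataset

T_DEFAULT = 2000.0


@pytest.fixture(scope="session")
def examples():
    """(network, ensemble, x0, likelihood model) per packaged example."""
    out = {}
    for ex in (1, 2, 3):
        net, ens, x0 = make_example(ex)
        out[ex] = (net, ens, x0, PathLikelihoodModel(net, ens, x0, T_DEFAULT))
    return out


@pytest.fixture(scope="session")
def small_datasets(examples):
    """150 paths per input and example at T=2000; fast shared workhorse."""
    out = {}
    for ex, (net, ens, x0, _) in examples.items():
        out[ex] = simulate_dataset(net, ens.labels, x0, T_DEFAULT, 150, seed=100 + ex)
    return out


@pytest.fixture(scope="session")
def ex3_discrete(small_datasets):
    """Example 3 resampled at d=100 as (X, y)."""
    X, _, labels = discrete_matrix(small_datasets[3], 100)
    return X, np.asarray(labels)
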