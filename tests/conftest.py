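import numpy as np
import pytest

from glvnet import AbundanceSeries, GLVParameters, RunConfig


@pytest.fixture
def two_taxon_params():
    return GLVParameters(
        ("A", "B"), np.array([1.0, 1.0]), np.zeros((2, 2)), 100.0
    )


@pytest.fixture
def config():
    return RunConfig(carrying_capacity=1e11, master_seed=0, n_bootstraps=10)


@pytest.fixture
def simple_series():
    """A small hand-made compositional series (3 times, 2 taxa)."""
    times = np.array([0.0, 1.0, 2.0])
    P = np.array([[0.5, 0.5], [0.6, 0.4], [0.7, 0.3]])
    return AbundanceSeries(("A", "B"), times, P)
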