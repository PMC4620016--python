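import numpy as np
import pytest

from hemolc import ModelParameters, SimScenario, TraumaData, simulate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Hand-set two-class parameters with both submodels informative."""
    return ModelParameters(
        alpha=np.array([[0.3, -0.7]]),
        betas=np.array([[2.5, -1.0, 0.8], [1.2, 0.9, -0.5]]),
        gammas=np.array([[0.8, -1.1], [-0.6, 0.9]]),
        sigma=0.6,
    )


@pytest.fixture(scope="session")
def tiny_data():
    """Three hand-constructed records, one censored, matching small_params dims."""
    return TraumaData(
        y_obs=np.array([2.1, 0.4, 1.3]),
        died=np.array([0, 0, 1]),
        V=np.array([[1.0, 0.5], [1.0, -1.2], [1.0, 0.1]]),
        X_marker=np.array([[1.0, 0.5, 1.0], [1.0, -1.2, 0.0], [1.0, 0.1, 1.0]]),
        X_death=np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0]]),
        ids=np.array(["a", "b", "c"], dtype=object),
    )


@pytest.fixture(scope="session")
def benchmark_data():
    """One n=500, sigma=0.5 benchmark dataset with ground-truth labels."""
    return simulate_dataset(SimScenario(n=500, sigma=0.5, seed=7))
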