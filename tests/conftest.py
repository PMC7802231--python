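import numpy as np
import pandas as pd
import pytest

from idfrail.likelihood import ModelSpec, ParameterVector
from idfrail.simulate import reference_design, simulate_dataset


@pytest.fixture(scope="session")
def small_design():
    return reference_design(n=400, seed=11)


@pytest.fixture(scope="session")
def small_data(small_design):
    df, _ = simulate_dataset(small_design)
    return df


@pytest.fixture(scope="session")
def weibull_spec():
    return ModelSpec.weibull(["x"])


@pytest.fixture(scope="session")
def random_phi(weibull_spec):
    """A fixed, arbitrary-but-plausible parameter vector for the Weibull model."""
    rng = np.random.default_rng(42)
    arr = np.array(
        [0.9, -9.5, 1.2, -10.3, 1.0, -5.5, -0.1, -0.4, 0.2, -1.0]
    ) + 0.05 * rng.standard_normal(10)
    return ParameterVector.from_array(arr, ModelSpec.weibull(["x"]))
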