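import numpy as np
import pytest

from ramanglu import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Fast generator settings for unit tests: short axis, two bands."""
    return GeneratorParams(
        n_points=256,
        shift_range=(200.0, 3200.0),
        peak_centers=(1060.0, 1366.0),
        peak_widths=40.0,
        noise_sd=2.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """10 levels x 3 replicates on the short axis."""
    return generate_dataset(replicates=3, params=small_params, seed=5)


@pytest.fixture(scope="session")
def study_dataset():
    """The standard design: 10 levels x 5 replicates x 2048 points."""
    from ramanglu import default_study_dataset

    return default_study_dataset(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
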