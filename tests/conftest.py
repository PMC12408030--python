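import numpy as np
import pytest

import neuroridge as nr


@pytest.fixture(scope="session")
def small_cohort():
    """Two-timepoint cohort with default generative structure, small n."""
    config = nr.GenerativeConfig(n_participants=400, seed=11)
    cohort, truth = nr.generate_cohort(config)
    return cohort, truth, config


@pytest.fixture(scope="session")
def fast_config():
    """Reduced resampling settings used throughout the tests."""
    return nr.ModelConfig(
        lambda_grid=tuple(float(x) for x in np.logspace(-2, 4, 4)),
        n_outer_splits=10,
        n_inner_folds=3,
        seed=0,
    )
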