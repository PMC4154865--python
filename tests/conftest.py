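import dataclasses

import numpy as np
import pytest

from crcpanel.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def dev_cohort():
    """One Table-calibrated development cohort (81 cases / 51 controls)."""
    return generate_cohort(default_config("development", seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (25 cases / 20 controls) for fast fitting tests."""
    cfg = dataclasses.replace(default_config("development", seed=5),
                              n_cases=25, n_controls=20)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
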