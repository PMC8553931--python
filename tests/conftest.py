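import numpy as np
import pytest

import dynfc


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def atlas12():
    """Atlas on the small analysis grid used throughout the tests."""
    return dynfc.build_atlas((12, 12, 12))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small planted-effect cohort shared by read-only tests."""
    spec = dynfc.dynamic_effect_spec(rng_seed=42, n_per_group=4,
                                     n_volumes=120)
    subjects, atlas, clinical = dynfc.generate_cohort(spec)
    return spec, subjects, atlas, clinical
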