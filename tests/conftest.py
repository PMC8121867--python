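import warnings

import numpy as np
import pytest

from aplsmear.experiments import make_planted_cohort, synthetic_patients
from aplsmear.nn import ArchitectureConfig


@pytest.fixture(scope="session")
def tiny_arch():
    """Small but fully-shaped backbone (default 68-dim FC head)."""
    return ArchitectureConfig(conv_filters=(4, 6, 6, 8))


@pytest.fixture(scope="session")
def planted_cohort_dir(tmp_path_factory):
    """Small on-disk planted-morphology cohort shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    make_planted_cohort(seed=7, out_dir=out, n_apl=2, n_nonapl=2,
                        cells_per_patient=100, image_size=48)
    return out


@pytest.fixture(scope="session")
def mini_patients():
    """In-memory 8-patient cohort of 32-px blast images."""
    return synthetic_patients(n_per_class=4, cells_per_patient=10, image_size=32, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield
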