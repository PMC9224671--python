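import numpy as np
import pytest

from atriosync import CohortConfig, generate_patient, patient_seeds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, fully featured cohort: 4 patients, 60 beats."""
    return CohortConfig(n_patients=4, n_beats=60, seed=7)


@pytest.fixture
def one_patient(small_config):
    """One rendered patient-phase triple (surface, cs, truth)."""
    seeds = patient_seeds(small_config)
    return generate_patient(small_config, "pre", int(seeds[0]))
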