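import numpy as np
import pytest

from mbcomtopt.ann import TrainingConfig, multistart_fit
from mbcomtopt.dataset import (
    calibration_subset,
    inputs_matrix,
    load_reference_experiments,
    observed_vector,
)


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_experiments()


@pytest.fixture(scope="session")
def calibration_records(reference_records):
    """The 25 observed, non-outlier runs used to calibrate the final model."""
    return calibration_subset(reference_records)


@pytest.fixture(scope="session")
def final_fit(calibration_records):
    """Full-conditions refit: 200 seeded restarts on the calibration set."""
    X = inputs_matrix(calibration_records)
    y = observed_vector(calibration_records)
    return multistart_fit(X, y, TrainingConfig(n_restarts=200, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
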