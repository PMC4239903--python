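import numpy as np
import pytest

import mimufuse as mf


@pytest.fixture(scope="session")
def default_model() -> mf.SensorModel:
    return mf.SensorModel()


@pytest.fixture(scope="session")
def quiet_model() -> mf.SensorModel:
    """Noise-free, bias-free sensor model (deterministic synthesis)."""
    return mf.SensorModel(gyro_noise_sd=0.0, accel_noise_sd=0.0, mag_noise_sd=0.0,
                          gyro_rate_drift_frac=0.0)


@pytest.fixture(scope="session")
def manual_truth() -> mf.GroundTruth:
    return mf.make_manual_routine(60.0, seed=1)


@pytest.fixture(scope="session")
def locomotion_truth() -> mf.GroundTruth:
    return mf.make_locomotion(180.0, seed=1)


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
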