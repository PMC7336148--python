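"""Shared fixtures: small meshes, sensor arrays, gains and studies.

Everything is generated programmatically and deterministically; no fixture
files are read from disk.
"""

import numpy as np
import pytest

from dmsi.anatomy import CorticalMesh
from dmsi.forward import GainMatrix, SensorArray, spherical_meg_gain
from dmsi.preprocess import AveragedStudy, NoiseCovariance
from dmsi.synthetic import helmet_sensor_array, wavy_cortex_mesh


@pytest.fixture(scope="session")
def small_mesh() -> CorticalMesh:
    """300-vertex wavy cortical surface (deterministic)."""
    return wavy_cortex_mesh(300, radius_mm=70.0)


@pytest.fixture(scope="session")
def small_sensors() -> SensorArray:
    return helmet_sensor_array(60, radius_mm=120.0)


@pytest.fixture(scope="session")
def small_gain(small_mesh, small_sensors) -> GainMatrix:
    return spherical_meg_gain(small_mesh, small_sensors)


@pytest.fixture(scope="session")
def mesh500() -> CorticalMesh:
    """500-vertex surface for metric oracle tests."""
    return wavy_cortex_mesh(500, radius_mm=70.0)


def make_study(peak_vector, fs=600.0, n_epochs=10, study_id="S1", patient_id="P1"):
    """AveragedStudy whose peak sample is ``peak_vector`` and whose baseline
    is zero (valid 2 s epoch at the given rate)."""
    peak_vector = np.atleast_1d(np.asarray(peak_vector, dtype=float))
    n_t = int(round(2 * fs))
    avg = np.zeros((len(peak_vector), n_t))
    avg[:, n_t // 2] = peak_vector
    return AveragedStudy(
        avg,
        sampling_rate_hz=fs,
        peak_index=n_t // 2,
        n_epochs=n_epochs,
        spike_type="spike1",
        patient_id=patient_id,
        study_id=study_id,
    )


def identity_cov(n: int, scale: float = 1.0) -> NoiseCovariance:
    return NoiseCovariance(scale * np.eye(n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
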