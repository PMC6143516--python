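import numpy as np
import pytest

import tracereval as te
from tracereval.synthetic import NoiseModel


@pytest.fixture
def noiseless_config():
    """Small study conditions with the detector noise switched off."""
    return te.CohortConfig(image_size_px=(64, 64),
                           noise_model=NoiseModel(read_sigma=0.0, shot_noise=False),
                           seed=7)


@pytest.fixture
def default_config():
    return te.CohortConfig(image_size_px=(64, 64), seed=7)


def make_patient(dose=25.0, mult=1.0, pid="P01", seed=11, n_slices=3):
    return te.PatientRecord(patient_id=pid, dose_mg=dose, uptake_multiplier=mult,
                            margin_status="negative", cavity_signal_truth=False,
                            n_slices=n_slices, tissue_geometry_seed=seed)


@pytest.fixture
def patient():
    return make_patient()


def uniform_image(value, shape=(16, 16), level="fresh_slice"):
    return te.FluorImage(np.full(shape, value, dtype=np.uint16), level=level)
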