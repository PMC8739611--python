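import numpy as np
import pytest

from cardiotrait import (
    EcgSimConfig,
    delineate,
    detect_r_peaks,
    generate_ecg,
    preprocess,
)


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless 70 bpm record with mild LF/HF modulation, 60 s at 500 Hz."""
    cfg = EcgSimConfig(hr_mean=70, duration_s=70.0, fs=500.0,
                       lf_amp=0.02, hf_amp=0.02, noise_sd=0.0, seed=42)
    record, truth = generate_ecg(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def clean_fiducials(clean_record):
    _, record, _ = clean_record
    rpeaks = detect_r_peaks(preprocess(record))
    return rpeaks, delineate(record, rpeaks)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
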