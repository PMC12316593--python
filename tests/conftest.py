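import numpy as np
import pytest

from pulsebp.simulate import SimulationConfig, simulate_subject_record


@pytest.fixture(scope="session")
def clean_record():
    """120 s clean record with HR variability and BP drift."""
    cfg = SimulationConfig(
        duration_s=120.0, hr_bpm=62.0, hr_variability_bpm=3.0,
        hr_jitter_sd_ms=10.0, seed=42)
    cfg.bp.drift_amp = 10.0
    cfg.bp.beat_noise_sd = 1.0
    record, truth = simulate_subject_record(cfg, 0)
    return record, truth


@pytest.fixture(scope="session")
def steady_record():
    """60 s record at fixed HR 60 and constant BP 120/80."""
    cfg = SimulationConfig(duration_s=60.0, hr_bpm=60.0, seed=7)
    record, truth = simulate_subject_record(cfg, 0)
    return record, truth


def nearest_errors(detected, true):
    """Signed error of the detected fiducial closest to each true one."""
    detected = np.asarray(detected)
    out = np.empty(len(true))
    for i, t in enumerate(true):
        out[i] = detected[np.argmin(np.abs(detected - t))] - t
    return out
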