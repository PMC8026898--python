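import numpy as np
import pytest

from grfwave import CohortConfig, SubjectMeta, WaveformTemplate


@pytest.fixture
def template():
    return WaveformTemplate()


@pytest.fixture
def subject_meta():
    return SubjectMeta(subject_id="F01", sex="female", body_mass=60.0, speed=2.7)


@pytest.fixture
def quiet_config():
    """Noiseless single-mode-free cohort config for exact round trips."""
    return CohortConfig(
        n_per_sex=2,
        steps_per_condition=5,
        noise_sd=0.0,
        medlat_sd=0.0,
        mode_sds={},
        sex_effect={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_rect_recording(meta, level=800.0, start=100, stop=350, n=1000, fs=1000.0):
    """Rectangular vertical pulse; handy for exact event-detection checks."""
    from grfwave import ForceRecording

    vertical = np.zeros(n)
    vertical[start:stop] = level
    forces = np.column_stack([vertical, np.zeros(n), np.zeros(n)])
    return ForceRecording(
        meta=meta, sampling_rate=fs, time=np.arange(n) / fs, forces=forces
    )
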