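import numpy as np
import pytest

from mpeeg.core.types import Group, Recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=100.0, channels=None, subject_id="s01", group=Group.HC):
    data = np.asarray(data, dtype=np.float64)
    if channels is None:
        channels = tuple(f"Ch{i + 1}" for i in range(data.shape[0]))
    return Recording(subject_id=subject_id, group=group, fs=fs,
                     channels=channels, data=data)


def sine_recording(freq_hz, fs=512.0, duration_s=2.0, n_channels=1, amplitude=1.0,
                   phase=0.0, **kwargs):
    t = np.arange(int(round(fs * duration_s))) / fs
    row = amplitude * np.cos(2 * np.pi * freq_hz * t + phase)
    return make_recording(np.tile(row, (n_channels, 1)), fs=fs, **kwargs)


@pytest.fixture()
def small_cohort():
    """A tiny two-group cohort for smoke/integration tests (8 channels)."""
    from mpeeg.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(
        groups=(("HC", 2), ("PD", 2)),
        fs=128.0,
        duration_s=8.0,
        channels=tuple(f"Ch{i + 1}" for i in range(8)),
        seed=7,
    )
    return spec, generate_cohort(spec)
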