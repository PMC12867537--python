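import numpy as np
import pytest

from strokerecovnet.core import ROI_CHANNELS, EEGRecording, Epoch, ROILayout

ALL_LATERAL = [ch for roi in ROI_CHANNELS.values() for ch in roi]


@pytest.fixture(scope="session")
def layout():
    return ROILayout()


@pytest.fixture
def recording_factory():
    """Build a recording from a per-channel signal function f(label, t)."""

    def make(channel_fn=None, fs=256.0, duration=190.0,
             lesion_side="right", subject_id="s0", extra_labels=()):
        n = int(round(fs * duration))
        t = np.arange(n) / fs
        labels = ALL_LATERAL + list(extra_labels)
        if channel_fn is None:
            rng = np.random.default_rng(0)
            data = rng.standard_normal((len(labels), n))
        else:
            data = np.vstack([channel_fn(ch, t) for ch in labels])
        return EEGRecording(
            subject_id=subject_id, fs=fs, channel_labels=labels,
            data=data, lesion_side=lesion_side,
        )

    return make


@pytest.fixture
def epoch_factory():
    """Build a single 10-s epoch from a per-channel signal function."""

    def make(channel_fn, fs=256.0, subject_id="s0"):
        n = int(round(10.0 * fs))
        t = np.arange(n) / fs
        labels = list(ALL_LATERAL)
        data = np.vstack([channel_fn(ch, t) for ch in labels])
        return Epoch(subject_id=subject_id, epoch_index=0, start_s=0.0,
                     fs=fs, channel_labels=labels, data=data)

    return make


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two simulated subjects, shared across feature-level tests."""
    from strokerecovnet.synthetic import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_subjects=2, seed=11, duration_s=185.0))
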