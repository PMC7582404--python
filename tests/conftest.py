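"""Shared fixtures: short simulated sessions so unit tests stay fast.

The default protocol produces 30–40 minute sessions; tests that only need a
structurally complete session use a fast exertion curve (RPE 11 → 17 in
6 minutes) instead.
"""

import numpy as np
import pytest

from runfatigue import garment_sim, segmentation, signal_io
from runfatigue.features import build_feature_matrix


def fast_protocol() -> garment_sim.ProtocolParams:
    """Protocol whose exertion curve climbs from 11 to 17 in six minutes."""
    p = garment_sim.ProtocolParams()
    p.response_curve = lambda t: 11.0 + t / 60.0
    return p


@pytest.fixture(scope="session")
def garment():
    return signal_io.default_garment()


@pytest.fixture(scope="session")
def short_session(garment):
    """~7-minute default-preset session: (recording, rpe trace)."""
    gait, effect, _, sensor = garment_sim.preset("default")
    rec, trace = garment_sim.simulate_session(
        gait, effect, fast_protocol(), sensor, seed=7, garment=garment
    )
    return rec, trace


@pytest.fixture(scope="session")
def short_dataset(short_session, garment):
    """Feature matrix + labels of the short session (1-s windows)."""
    rec, trace = short_session
    segments = segmentation.segment_windows(rec, garment, window_s=1.0)
    matrix = build_feature_matrix(rec, segments, garment)
    labels = signal_io.label_segments(
        segments, trace, rec.sampling_rate, rec.start_time
    )[matrix.segment_indices]
    return matrix, labels


@pytest.fixture(scope="session")
def null_session(garment):
    """Drift-free, jitter-free, noise-free session with integer-sample strides.

    Cadence 1.25 Hz at 100 Hz sampling gives exactly 80 samples per cycle,
    so every stride's sampled waveform is identical and per-stride features
    are constant up to float rounding.
    """
    gait, effect, _, sensor = garment_sim.preset("null-drift")
    gait.stride_frequency_at_8kmh = 1.25
    gait.stride_frequency_slope = 0.0
    sensor.noise_sd = 0.0
    rec, trace = garment_sim.simulate_session(
        gait, effect, fast_protocol(), sensor, seed=7, garment=garment
    )
    return rec, trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
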