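"""Feature extraction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from runfatigue.features import (
    FEATURES_PER_CHANNEL,
    FeatureError,
    InsufficientDataError,
    STRIDE_DURATION_COL,
    build_feature_matrix,
    channel_feature_names,
    first_derivative,
    rolling_variation,
    segment_features,
    _subsegment_bounds,
)
from runfatigue.segmentation import Segment, segment_windows
from runfatigue.signal_io import SensorRecording, default_garment


def naive_segment_features(values):
    """Pure-python oracle: no numpy reductions, explicit partition loops."""
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    lo, hi = min(vals), max(vals)
    out = {"whole__mean": mean, "whole__min": lo, "whole__max": hi, "whole__rom": hi - lo}
    base, rem = divmod(n, 5)
    start = 0
    for s in range(5):
        length = base + (1 if s < rem else 0)
        part = vals[start : start + length]
        start += length
        out[f"subseg_{s + 1}__mean"] = sum(part) / len(part)
        out[f"subseg_{s + 1}__min"] = min(part)
        out[f"subseg_{s + 1}__max"] = max(part)
    return out


class TestFirstDerivative:
    def test_constant_is_zero(self):
        np.testing.assert_array_equal(first_derivative(np.ones(10), 100.0), np.zeros(10))

    def test_unit_slope(self):
        t = np.arange(0, 1, 0.01)
        np.testing.assert_allclose(first_derivative(t, 100.0), np.ones(100))

    def test_sinusoid_amplitude(self):
        t = np.arange(0, 10, 0.01)
        d = first_derivative(np.sin(2 * np.pi * 1.5 * t), 100.0)
        assert d.max() == pytest.approx(2 * np.pi * 1.5, rel=0.01)

    def test_too_short(self):
        with pytest.raises(FeatureError):
            first_derivative(np.array([1.0, 2.0]), 100.0)

    def test_matches_naive_differences(self, rng):
        x = rng.normal(size=50)
        d = first_derivative(x, 100.0)
        naive = [(x[1] - x[0]) * 100] + [
            (x[i + 1] - x[i - 1]) * 50 for i in range(1, 49)
        ] + [(x[-1] - x[-2]) * 100]
        np.testing.assert_allclose(d, naive, atol=1e-10)


class TestSegmentFeatures:
    def test_hand_computed_five_values(self):
        out = segment_features(np.array([1.0, 2, 3, 4, 5]))
        assert out["whole__mean"] == 3 and out["whole__min"] == 1
        assert out["whole__max"] == 5 and out["whole__rom"] == 4
        assert [out[f"subseg_{s}__mean"] for s in range(1, 6)] == [1, 2, 3, 4, 5]

    def test_constant_segment(self):
        out = segment_features(np.full(20, 2.5))
        assert out["whole__rom"] == 0
        assert all(v == 2.5 for k, v in out.items() if k != "whole__rom")

    def test_partition_of_103(self):
        bounds = _subsegment_bounds(103)
        assert list(np.diff(bounds)) == [21, 21, 21, 20, 20]

    @given(st.integers(min_value=5, max_value=400))
    @settings(deadline=None, max_examples=40)
    def test_partition_contiguous_near_equal(self, n):
        lengths = np.diff(_subsegment_bounds(n))
        assert lengths.sum() == n and len(lengths) == 5
        assert lengths.max() - lengths.min() <= 1
        assert np.all(np.diff(lengths) <= 0)  # remainder goes to the earliest

    def test_matches_oracle_on_random_segments(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 300))
            x = rng.normal(size=n)
            got = segment_features(x)
            expected = naive_segment_features(x)
            assert got.keys() == expected.keys()
            for k in got:
                assert got[k] == pytest.approx(expected[k], abs=1e-10)

    def test_too_short_segment(self):
        with pytest.raises(FeatureError):
            segment_features(np.array([1.0, 2, 3, 4]))


class TestRollingVariation:
    def test_constant_series_zero(self):
        out = rolling_variation(np.full(30, 7.0))
        assert np.all(out[9:] == 0)

    def test_hand_computed_sample_sd(self):
        out = rolling_variation(np.arange(1.0, 11.0))
        # sample sd of 1..10 = sqrt(82.5/9)
        assert out[9] == pytest.approx(3.0276503540974917, abs=1e-10)

    def test_warm_up_rows_incomplete(self):
        out = rolling_variation(np.arange(20.0))
        assert np.isnan(out[:9]).all() and np.isfinite(out[9:]).all()

    def test_window_of_one_rejected(self):
        with pytest.raises(ValueError):
            rolling_variation(np.arange(5.0), window=1)


def _random_recording(rng, n=6000, garment=None):
    garment = garment or default_garment()
    samples = rng.uniform(0.5, 2.5, size=(n, len(garment.channels)))
    return SensorRecording(samples, list(garment.channels), sampling_rate=100.0), garment


def _random_segments(rng, n_samples, count):
    anchors = np.sort(rng.choice(np.arange(120, n_samples), size=count, replace=False))
    return [Segment(int(a) - 100, int(a), int(a), "window") for a in anchors]


class TestBuildFeatureMatrix:
    def test_shape_default_garment(self, rng):
        rec, garment = _random_recording(rng)
        segs = _random_segments(rng, rec.n_samples, 50)
        m = build_feature_matrix(rec, segs, garment)
        assert m.frame.shape == (40, 369)
        assert m.columns[-1] == STRIDE_DURATION_COL

    def test_shape_hip_only_garment(self, rng):
        garment = default_garment()
        for c in garment.channels:
            if c.joint != "hip":
                object.__setattr__(c, "excluded", True)
        rec, _ = _random_recording(rng, garment=garment)
        segs = _random_segments(rng, rec.n_samples, 50)
        m = build_feature_matrix(rec, segs, garment)
        assert m.frame.shape == (40, 4 * FEATURES_PER_CHANNEL + 1)

    def test_channel_order_permutation_invariant(self, rng):
        rec, garment = _random_recording(rng)
        segs = _random_segments(rng, rec.n_samples, 30)
        m1 = build_feature_matrix(rec, segs, garment)

        perm = np.array([3, 1, 0, 2, 5, 4, 7, 8, 6])
        garment2 = default_garment()
        garment2.channels = [garment.channels[i] for i in perm]
        rec2 = SensorRecording(
            rec.samples[:, perm], garment2.channels, sampling_rate=100.0
        )
        m2 = build_feature_matrix(rec2, segs, garment2)
        common = sorted(m1.columns)
        np.testing.assert_array_equal(
            m1.frame[common].to_numpy(), m2.frame[common].to_numpy()
        )

    def test_drop_channel_removes_exactly_46_columns(self, rng):
        rec, garment = _random_recording(rng)
        segs = _random_segments(rng, rec.n_samples, 30)
        m = build_feature_matrix(rec, segs, garment)
        reduced = m.drop_channel("ankle_2")
        assert len(m.columns) - len(reduced.columns) == 46
        assert not any(c.startswith("ankle_2__") for c in reduced.columns)

    def test_rows_match_segment_and_oracle(self, rng):
        """Whole-matrix check against the naive per-segment oracle."""
        rec, garment = _random_recording(rng, n=3000)
        segs = _random_segments(rng, rec.n_samples, 15)
        m = build_feature_matrix(rec, segs, garment)
        row = m.frame.iloc[-1]
        seg = segs[m.segment_indices[-1]]
        for cid in ("hip_2", "ankle_3"):
            x = seg.values(rec.channel_values(cid))
            expected = naive_segment_features(x)
            for stat, val in expected.items():
                assert row[f"{cid}__raw__{stat}"] == pytest.approx(val, abs=1e-10)

    def test_derivative_windowed_from_full_signal(self, rng):
        # edge samples of a segment see the neighbouring samples' slopes
        rec, garment = _random_recording(rng, n=2000)
        segs = _random_segments(rng, rec.n_samples, 12)
        m = build_feature_matrix(rec, segs, garment)
        seg = segs[m.segment_indices[-1]]
        full_deriv = first_derivative(rec.channel_values("hip_1"), 100.0)
        expected = naive_segment_features(seg.values(full_deriv))
        row = m.frame.iloc[-1]
        for stat, val in expected.items():
            assert row[f"hip_1__deriv__{stat}"] == pytest.approx(val, abs=1e-10)

    def test_too_few_segments(self, rng):
        rec, garment = _random_recording(rng)
        segs = _random_segments(rng, rec.n_samples, 10)
        with pytest.raises(InsufficientDataError):
            build_feature_matrix(rec, segs, garment)

    def test_column_names_deterministic(self):
        names = channel_feature_names("hip_1")
        assert len(names) == FEATURES_PER_CHANNEL == 46
        assert names[0] == "hip_1__raw__whole__mean"
        assert names[19] == "hip_1__deriv__whole__mean"
        assert names[-1] == "hip_1__deriv__var10__rom"

    def test_null_session_features_constant(self, null_session, garment):
        """Drift-free, noise-free gait: every feature column is constant."""
        rec, _ = null_session
        segs = segment_windows(rec, garment, window_s=1.0)
        m = build_feature_matrix(rec, segs, garment)
        values = m.values()
        spread = values.max(axis=0) - values.min(axis=0)
        np.testing.assert_allclose(spread, 0.0, atol=1e-9)
        var_cols = [i for i, c in enumerate(m.columns) if "__var10__" in c]
        np.testing.assert_allclose(values[:, var_cols], 0.0, atol=1e-9)
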