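"""Per-segment feature engineering for strain-sensor gait signals.

For every segment and every included channel the extractor computes, on the
raw signal and on its first time-derivative:

* whole-segment mean, minimum, maximum and range of motion (max − min);
* the segment split into five contiguous near-equal sub-segments, each
  contributing mean, minimum and maximum (15 statistics);
* the trailing-10-segment sample standard deviation ("variation") of the
  whole-segment mean, min, max and ROM.

That is 19 + 19 + 4 + 4 = 46 columns per channel, plus one global stride
duration column (anchor-to-anchor time in seconds), shared across channels.
The default 8-included-channel garment therefore yields 369 columns. The
first ten rows, whose rolling-variation history is incomplete, are dropped.

Derivative features are computed on the derivative of the full channel
signal, then windowed by the segment bounds, so segment edges introduce no
differentiation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import Segment
from .signal_io import GarmentConfig, SensorRecording

__all__ = [
    "FeatureError",
    "InsufficientDataError",
    "FeatureMatrix",
    "first_derivative",
    "segment_features",
    "rolling_variation",
    "build_feature_matrix",
    "channel_feature_names",
    "STRIDE_DURATION_COL",
    "VARIATION_WINDOW",
    "N_SUBSEGMENTS",
    "FEATURES_PER_CHANNEL",
]

STRIDE_DURATION_COL = "stride_duration_s"
VARIATION_WINDOW = 10
N_SUBSEGMENTS = 5

_WHOLE_STATS = ("mean", "min", "max", "rom")
_SUBSEG_STATS = ("mean", "min", "max")
_VAR_STATS = ("mean", "min", "max", "rom")

# 19 per signal view (raw/deriv) + 4 rolling variations per view
FEATURES_PER_CHANNEL = 2 * (len(_WHOLE_STATS) + N_SUBSEGMENTS * len(_SUBSEG_STATS)) + 2 * len(_VAR_STATS)


class FeatureError(ValueError):
    """A segment cannot yield the feature set (too short, bad shape)."""


class InsufficientDataError(ValueError):
    """Too few segments to produce any complete-history feature row."""


def channel_feature_names(channel_id: str) -> list[str]:
    """Canonical column names of one channel, in deterministic order."""
    names: list[str] = []
    for view in ("raw", "deriv"):
        for stat in _WHOLE_STATS:
            names.append(f"{channel_id}__{view}__whole__{stat}")
        for s in range(1, N_SUBSEGMENTS + 1):
            for stat in _SUBSEG_STATS:
                names.append(f"{channel_id}__{view}__subseg_{s}__{stat}")
    for view in ("raw", "deriv"):
        for stat in _VAR_STATS:
            names.append(f"{channel_id}__{view}__var{VARIATION_WINDOW}__{stat}")
    return names


def first_derivative(signal: np.ndarray, rate: float) -> np.ndarray:
    """First time-derivative, same length as the input.

    Central differences in the interior, one-sided at the endpoints,
    scaled to units per second.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise FeatureError("first_derivative needs at least 3 samples")
    return np.gradient(x) * rate


def _subsegment_bounds(n: int, k: int = N_SUBSEGMENTS) -> np.ndarray:
    """Boundaries of k contiguous near-equal parts; remainder to the earliest."""
    base, rem = divmod(n, k)
    lengths = np.full(k, base, dtype=int)
    lengths[:rem] += 1
    return np.concatenate([[0], np.cumsum(lengths)])


def segment_features(values: np.ndarray) -> dict[str, float]:
    """The 19 per-(channel, view) statistics of one segment.

    Whole-segment mean/min/max/ROM plus mean/min/max of each of five
    contiguous sub-segments (remainder samples go to the earliest
    sub-segments).
    """
    x = np.asarray(values, dtype=float)
    if x.size < N_SUBSEGMENTS:
        raise FeatureError(
            f"segment of {x.size} samples is shorter than {N_SUBSEGMENTS} sub-segments"
        )
    lo, hi = float(x.min()), float(x.max())
    out = {
        "whole__mean": float(x.mean()),
        "whole__min": lo,
        "whole__max": hi,
        "whole__rom": hi - lo,
    }
    bounds = _subsegment_bounds(x.size)
    for s in range(N_SUBSEGMENTS):
        part = x[bounds[s] : bounds[s + 1]]
        out[f"subseg_{s + 1}__mean"] = float(part.mean())
        out[f"subseg_{s + 1}__min"] = float(part.min())
        out[f"subseg_{s + 1}__max"] = float(part.max())
    return out


def rolling_variation(history: np.ndarray, window: int = VARIATION_WINDOW) -> np.ndarray:
    """Trailing sample standard deviation of a per-segment statistic.

    Inclusive of the current segment; rows with fewer than ``window − 1``
    predecessors are NaN (incomplete history).
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    return (
        pd.Series(np.asarray(history, dtype=float))
        .rolling(window)
        .std(ddof=1)
        .to_numpy()
    )


@dataclass
class FeatureMatrix:
    """Named per-segment feature table plus alignment back to the recording.

    ``frame`` rows are segments in temporal order after the warm-up drop;
    ``segment_indices[i]`` is the position of row i in the original segment
    list, and ``anchor_times[i]`` its anchor-peak time in seconds (used for
    label alignment).
    """

    frame: pd.DataFrame
    segment_indices: np.ndarray
    anchor_times: np.ndarray
    channel_ids: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def channel_columns(self, channel_id: str) -> list[str]:
        if channel_id not in self.channel_ids:
            raise KeyError(f"channel {channel_id!r} not in feature matrix")
        return channel_feature_names(channel_id)

    def drop_channel(self, channel_id: str) -> "FeatureMatrix":
        """New matrix without one channel's 46 columns (ablation helper)."""
        cols = self.channel_columns(channel_id)
        return FeatureMatrix(
            frame=self.frame.drop(columns=cols),
            segment_indices=self.segment_indices,
            anchor_times=self.anchor_times,
            channel_ids=[c for c in self.channel_ids if c != channel_id],
        )

    def restrict_to_channels(self, channel_ids: list[str]) -> "FeatureMatrix":
        """Matrix restricted to the given channels plus the stride-duration column."""
        cols: list[str] = []
        for c in channel_ids:
            cols.extend(self.channel_columns(c))
        cols.append(STRIDE_DURATION_COL)
        return FeatureMatrix(
            frame=self.frame[cols].copy(),
            segment_indices=self.segment_indices,
            anchor_times=self.anchor_times,
            channel_ids=list(channel_ids),
        )


def build_feature_matrix(
    rec: SensorRecording,
    segments: list[Segment],
    garment: GarmentConfig,
) -> FeatureMatrix:
    """Full feature table of a segmented recording.

    Channels flagged excluded in the garment contribute no columns. The
    first ``VARIATION_WINDOW`` rows are dropped so every retained row has a
    complete rolling-variation history and a defined stride duration.
    """
    included = garment.included_channels
    if not included:
        raise ValueError("all channels excluded; nothing to extract")
    if len(segments) < VARIATION_WINDOW + 1:
        raise InsufficientDataError(
            f"need at least {VARIATION_WINDOW + 1} segments, got {len(segments)}"
        )
    n_seg = len(segments)
    rate = rec.sampling_rate

    whole_names = ["whole__mean", "whole__min", "whole__max", "whole__rom"]
    columns: dict[str, np.ndarray] = {}
    for ch in included:
        cid = ch.channel_id
        raw = rec.channel_values(cid)
        deriv = first_derivative(raw, rate)
        for view, signal in (("raw", raw), ("deriv", deriv)):
            stats: dict[str, np.ndarray] = {}
            rows = [segment_features(seg.values(signal)) for seg in segments]
            for key in rows[0]:
                stats[key] = np.array([r[key] for r in rows])
            for key, arr in stats.items():
                columns[f"{cid}__{view}__{key}"] = arr
            for stat in _VAR_STATS:
                columns[f"{cid}__{view}__var{VARIATION_WINDOW}__{stat}"] = rolling_variation(
                    stats[f"whole__{stat}"]
                )

    anchors = np.array([s.anchor_peak_index for s in segments], dtype=float)
    duration = np.empty(n_seg)
    duration[1:] = np.diff(anchors) / rate
    duration[0] = duration[1] if n_seg > 1 else np.nan
    columns[STRIDE_DURATION_COL] = duration

    # deterministic column order: garment channel order, then stride duration
    ordered = []
    for ch in included:
        ordered.extend(channel_feature_names(ch.channel_id))
    ordered.append(STRIDE_DURATION_COL)
    frame = pd.DataFrame({name: columns[name] for name in ordered})

    keep = np.arange(VARIATION_WINDOW, n_seg)
    frame = frame.iloc[keep].reset_index(drop=True)
    if frame.isna().any().any():
        raise FeatureError("retained feature rows contain missing values")
    anchor_times = rec.start_time + anchors[keep] / rate
    return FeatureMatrix(
        frame=frame,
        segment_indices=keep,
        anchor_times=anchor_times,
        channel_ids=[c.channel_id for c in included],
    )
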