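"""Stride- and window-based segmentation of garment recordings.

Both methods are anchored on peaks of a single reference channel (by default
the first hip sensor, which carries the clearest periodicity):

* stride segmentation: one segment per consecutive peak pair [p_i, p_{i+1}),
  i.e. one full gait cycle;
* window segmentation: a fixed-length window ending at each detected peak,
  [peak − window, peak). Window lengths of 0.5, 1, 1.5 and 2 s are the
  supported sweep; 1 s is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal_io import GarmentConfig, SensorRecording

__all__ = [
    "Segment",
    "PeakParams",
    "SegmentationError",
    "detect_peaks",
    "segment_strides",
    "segment_windows",
    "WINDOW_LENGTH_SWEEP_S",
    "segments_to_frame",
    "segments_from_frame",
]

WINDOW_LENGTH_SWEEP_S = (0.5, 1.0, 1.5, 2.0)


class SegmentationError(ValueError):
    """Recording cannot be segmented under the given parameters."""


@dataclass(frozen=True)
class Segment:
    """Half-open index interval [start_index, end_index) into a recording.

    anchor_peak_index is the reference-channel peak that produced the
    segment: the closing peak for stride segments, the window's right edge
    for window segments.
    """

    start_index: int
    end_index: int
    anchor_peak_index: int
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_index < self.end_index):
            raise ValueError("need 0 <= start_index < end_index")
        if self.method not in ("stride", "window"):
            raise ValueError("method must be 'stride' or 'window'")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def values(self, signal: np.ndarray) -> np.ndarray:
        return signal[self.start_index : self.end_index]


@dataclass
class PeakParams:
    """Reference-channel peak detector settings.

    min_distance_s rejects sub-stride ripples (0.4 s allows cadences up to
    150 strides/min per leg); prominence_fraction is relative to the robust
    signal range (5th–95th percentile), making the detector amplitude-scale
    free.
    """

    min_distance_s: float = 0.4
    prominence_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.min_distance_s <= 0:
            raise ValueError("min_distance_s must be positive")
        if not (0 < self.prominence_fraction < 1):
            raise ValueError("prominence_fraction must lie in (0, 1)")


def detect_peaks(
    signal: np.ndarray, rate: float, params: PeakParams | None = None
) -> np.ndarray:
    """Indices of gait peaks in a 1-D signal, sorted ascending.

    Local maxima separated by at least min_distance_s, with prominence at
    least prominence_fraction of the robust (5th–95th percentile) signal
    range. A constant signal yields an empty result. Distance pruning keeps
    the higher of two competing maxima; among equal-height maxima the
    earliest index wins (deterministic tie-break).
    """
    params = params or PeakParams()
    x = np.asarray(signal, dtype=float)
    min_dist = max(1, int(round(params.min_distance_s * rate)))
    if x.size < 2 * min_dist:
        raise SegmentationError(
            f"signal of {x.size} samples is too short for min_distance "
            f"{params.min_distance_s} s at {rate} Hz"
        )
    lo, hi = np.percentile(x, [5, 95])
    robust_range = hi - lo
    if robust_range <= 0:
        return np.array([], dtype=int)
    prominence = params.prominence_fraction * robust_range
    candidates, _ = find_peaks(x, prominence=prominence)
    if candidates.size == 0:
        return candidates.astype(int)
    # greedy pruning by (height desc, index asc) so equal heights keep the
    # earliest peak; scipy's own `distance` pruning breaks ties the other way
    heights = x[candidates]
    order = np.lexsort((candidates, -heights))
    removed = np.zeros(candidates.size, dtype=bool)
    for i in order:
        if removed[i]:
            continue
        p = candidates[i]
        lo_i = np.searchsorted(candidates, p - min_dist + 1, side="left")
        hi_i = np.searchsorted(candidates, p + min_dist - 1, side="right")
        removed[lo_i:hi_i] = True
        removed[i] = False
    return candidates[~removed].astype(int)


def _reference_peaks(
    rec: SensorRecording, garment: GarmentConfig, params: PeakParams | None
) -> np.ndarray:
    signal = rec.channel_values(garment.reference_channel)
    return detect_peaks(signal, rec.sampling_rate, params)


def segment_strides(
    rec: SensorRecording,
    garment: GarmentConfig,
    params: PeakParams | None = None,
) -> list[Segment]:
    """One segment per consecutive reference-channel peak pair."""
    peaks = _reference_peaks(rec, garment, params)
    if len(peaks) < 2:
        raise SegmentationError(
            f"need at least 2 reference peaks for stride segmentation, found {len(peaks)}"
        )
    return [
        Segment(int(a), int(b), anchor_peak_index=int(b), method="stride")
        for a, b in zip(peaks[:-1], peaks[1:])
    ]


def segment_windows(
    rec: SensorRecording,
    garment: GarmentConfig,
    params: PeakParams | None = None,
    window_s: float = 1.0,
) -> list[Segment]:
    """A fixed-length window [peak − window_s, peak) per reference peak.

    Peaks too close to the start of the recording to admit a full window are
    dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * rec.sampling_rate))
    peaks = _reference_peaks(rec, garment, params)
    segments = [
        Segment(int(p - win), int(p), anchor_peak_index=int(p), method="window")
        for p in peaks
        if p - win >= 0
    ]
    if not segments:
        raise SegmentationError(
            f"no reference peak admits a full {window_s} s window"
        )
    return segments


def segments_to_frame(segments: list[Segment]):
    """Segment table as a DataFrame (`start,end,anchor,method`)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "start": [s.start_index for s in segments],
            "end": [s.end_index for s in segments],
            "anchor": [s.anchor_peak_index for s in segments],
            "method": [s.method for s in segments],
        }
    )


def segments_from_frame(df) -> list[Segment]:
    return [
        Segment(int(r.start), int(r.end), int(r.anchor), str(r.method))
        for r in df.itertuples(index=False)
    ]
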