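"""Data model and CSV I/O for instrumented-garment recordings.

A recording is a uniformly sampled multi-channel strain-sensor signal from a
sensor-instrumented running garment. The default garment carries nine
resistive textile strain sensors — four at the hip, two at the knee, three at
the ankle — sampled at 100 Hz through a voltage divider; one knee channel is
flagged as too noisy and excluded from analysis. Perceived-exertion labels
are integer Borg RPE scores (6–20) reported at discrete times (nominally
every 3 minutes).

File formats are deliberately plain: a recording is a CSV with a ``time_s``
column followed by one column per channel; an RPE trace is a two-column CSV
``time_s,rpe``; a garment configuration is a small YAML document.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChannelInfo",
    "SensorRecording",
    "RPETrace",
    "GarmentConfig",
    "SchemaError",
    "FormatError",
    "DataError",
    "LabelingError",
    "default_garment",
    "read_recording",
    "write_recording",
    "read_rpe",
    "write_rpe",
    "read_garment",
    "write_garment",
    "label_segments",
    "RPE_MIN",
    "RPE_MAX",
]

RPE_MIN = 6
RPE_MAX = 20

JOINTS = ("hip", "knee", "ankle")


class SchemaError(ValueError):
    """Input file columns do not match the expected schema."""


class FormatError(ValueError):
    """Input file is structurally valid but violates a format contract."""


class DataError(ValueError):
    """Input values are invalid (non-finite, out of range, mis-ordered)."""


class LabelingError(ValueError):
    """A segment cannot be assigned an RPE label."""


@dataclass(frozen=True)
class ChannelInfo:
    """One sensor channel of a garment.

    Parameters
    ----------
    channel_id : str
        Short unique identifier, e.g. ``"hip_1"``.
    joint : str
        One of ``"hip"``, ``"knee"``, ``"ankle"``.
    index_within_joint : int
        1-based position of the sensor at its joint.
    excluded : bool
        If True the channel is dropped from all analysis (kept in raw files).
    """

    channel_id: str
    joint: str
    index_within_joint: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"joint must be one of {JOINTS}, got {self.joint!r}")
        if self.index_within_joint < 1:
            raise ValueError("index_within_joint must be a positive integer")


@dataclass
class GarmentConfig:
    """Channel layout of a sensor garment plus the peak-detection reference.

    The reference channel drives stride detection and must be an included
    channel.
    """

    channels: list[ChannelInfo]
    reference_channel: str = "hip_1"

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel_id values must be unique within a garment")
        ref = self.channel(self.reference_channel)
        if ref.excluded:
            raise ValueError("reference channel must not be excluded")

    def channel(self, channel_id: str) -> ChannelInfo:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(f"no channel {channel_id!r} in garment")

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def included_channels(self) -> list[ChannelInfo]:
        return [c for c in self.channels if not c.excluded]

    def joint_channels(self, joint: str) -> list[ChannelInfo]:
        if joint not in JOINTS:
            raise ValueError(f"joint must be one of {JOINTS}")
        return [c for c in self.included_channels if c.joint == joint]


def default_garment() -> GarmentConfig:
    """Nine-sensor garment: 4 hip, 2 knee, 3 ankle; ``knee_2`` excluded as noisy."""
    channels = []
    for joint, n in (("hip", 4), ("knee", 2), ("ankle", 3)):
        for i in range(1, n + 1):
            channels.append(
                ChannelInfo(
                    channel_id=f"{joint}_{i}",
                    joint=joint,
                    index_within_joint=i,
                    excluded=(joint == "knee" and i == 2),
                )
            )
    return GarmentConfig(channels=channels, reference_channel="hip_1")


@dataclass
class SensorRecording:
    """Uniformly sampled multi-channel readout.

    ``samples`` is ``[n_samples, n_channels]`` in readout units (volts for
    simulated divider output). Channel order matches ``channels``.
    """

    samples: np.ndarray
    channels: list[ChannelInfo]
    sampling_rate: float = 100.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D array [n_samples, n_channels]")
        if self.samples.shape[0] < 2:
            raise DataError("a recording needs at least 2 samples")
        if self.samples.shape[1] != len(self.channels):
            raise SchemaError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.channels)} channel descriptors"
            )
        if not np.isfinite(self.samples).all():
            raise DataError("recording contains non-finite values")
        if not self.sampling_rate > 0:
            raise DataError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channel_values(self, channel_id: str) -> np.ndarray:
        """1-D signal of one channel."""
        for j, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return self.samples[:, j]
        raise KeyError(f"no channel {channel_id!r} in recording")


@dataclass
class RPETrace:
    """Timestamped Borg RPE reports: ordered ``(time_s, score)`` pairs."""

    reports: list[tuple[float, int]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.reports]
        scores = [s for _, s in self.reports]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DataError("report times must be strictly increasing")
        for s in scores:
            if not (RPE_MIN <= s <= RPE_MAX):
                raise DataError(f"RPE score {s} outside Borg range [{RPE_MIN}, {RPE_MAX}]")
            if int(s) != s:
                raise DataError("RPE scores must be integers")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.reports], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.reports], dtype=int)

    def score_at(self, time_s: float, mode: str = "ffill") -> int:
        """RPE in force at ``time_s``.

        ``ffill`` (default) returns the most recent report at or before the
        query time; ``backfill`` the next report at or after it.
        """
        times = self.times
        scores = self.scores
        if mode == "ffill":
            idx = int(np.searchsorted(times, time_s, side="right")) - 1
            if idx < 0:
                raise LabelingError(f"time {time_s} precedes first report at {times[0]}")
        elif mode == "backfill":
            idx = int(np.searchsorted(times, time_s, side="left"))
            if idx >= len(times):
                raise LabelingError(f"time {time_s} is after last report at {times[-1]}")
        else:
            raise ValueError("mode must be 'ffill' or 'backfill'")
        return int(scores[idx])


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _check_uniform_grid(times: np.ndarray, tolerance: float = 0.01) -> float:
    """Infer the sampling rate from the median time step; reject jittery grids.

    Returns the rate in Hz. Steps may deviate from the median by at most
    ``tolerance`` (fractional).
    """
    steps = np.diff(times)
    if (steps <= 0).any():
        raise FormatError("time_s must be strictly increasing")
    median = float(np.median(steps))
    if np.abs(steps - median).max() > tolerance * median:
        raise FormatError(
            "time grid is not uniform within "
            f"{tolerance:.0%} of the median step {median:g} s"
        )
    return 1.0 / median


def read_recording(path: str | Path, garment: GarmentConfig) -> SensorRecording:
    """Read a recording CSV (``time_s`` + one column per garment channel)."""
    import csv

    with open(path, newline="") as fh:
        cols = next(csv.reader(fh))
    if len(cols) != len(set(cols)):  # before pandas mangles dupes to "x.1"
        raise SchemaError("duplicated header columns")
    expected = ["time_s"] + garment.channel_ids
    if set(cols) != set(expected):
        missing = set(expected) - set(cols)
        extra = set(cols) - set(expected)
        raise SchemaError(f"column mismatch: missing={sorted(missing)} extra={sorted(extra)}")
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise DataError("recording contains NaN values")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise DataError("a recording needs at least 2 samples")
    rate = _check_uniform_grid(times)
    samples = df[garment.channel_ids].to_numpy(dtype=float)
    return SensorRecording(
        samples=samples,
        channels=list(garment.channels),
        sampling_rate=rate,
        start_time=float(times[0]),
    )


def write_recording(path: str | Path, rec: SensorRecording) -> None:
    df = pd.DataFrame(rec.samples, columns=[c.channel_id for c in rec.channels])
    df.insert(0, "time_s", rec.times)
    df.to_csv(path, index=False, float_format="%.6f")


def read_rpe(path: str | Path) -> RPETrace:
    """Read an RPE annotation CSV with header ``time_s,rpe``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "rpe"]:
        raise SchemaError(f"expected columns ['time_s', 'rpe'], got {list(df.columns)}")
    reports = [(float(t), int(s)) for t, s in zip(df["time_s"], df["rpe"])]
    return RPETrace(reports=reports)


def write_rpe(path: str | Path, trace: RPETrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "rpe": trace.scores}
    ).to_csv(path, index=False)


def read_garment(path: str | Path) -> GarmentConfig:
    """Read a garment configuration from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    channels = [
        ChannelInfo(
            channel_id=c["channel_id"],
            joint=c["joint"],
            index_within_joint=int(c["index_within_joint"]),
            excluded=bool(c.get("excluded", False)),
        )
        for c in doc["channels"]
    ]
    return GarmentConfig(channels=channels, reference_channel=doc["reference_channel"])


def write_garment(path: str | Path, garment: GarmentConfig) -> None:
    doc = {
        "reference_channel": garment.reference_channel,
        "channels": [
            {
                "channel_id": c.channel_id,
                "joint": c.joint,
                "index_within_joint": c.index_within_joint,
                "excluded": c.excluded,
            }
            for c in garment.channels
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def label_segments(
    segments: Sequence,
    trace: RPETrace,
    rate: float,
    start_time: float = 0.0,
    mode: str = "ffill",
) -> np.ndarray:
    """Assign an integer RPE to each segment from its anchor-peak time.

    The default rule forward-fills: a segment gets the most recent report at
    or before its anchor time (boundary inclusive), matching the reading that
    a report describes exertion from that moment onward.
    """
    labels = np.empty(len(segments), dtype=int)
    for i, seg in enumerate(segments):
        t = start_time + seg.anchor_peak_index / rate
        labels[i] = trace.score_at(t, mode=mode)
    return labels
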