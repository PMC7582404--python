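"""Synthetic instrumented-garment running sessions with known ground truth.

The study design this package targets — a runner on a treadmill wearing
strain-sensor tights, reporting Borg RPE every three minutes while speed is
ramped until RPE 13 and held until RPE 17 — produced recordings that are not
publicly deposited. This module generates sessions with the same structure so
that every downstream stage (segmentation, features, model, evaluation) can
be exercised against known ground truth.

The generator has three layers:

* **Protocol** (`simulate_protocol`): a latent, monotone exertion curve is
  sampled per participant; rounding it at 180-s report times yields the
  integer Borg reports (plateaus arise naturally). Treadmill speed starts at
  8 km/h and rises 1 km/h per report while the last report is below 13; the
  session ends 60 s after the first report of 17 or more.
* **Gait**: each channel is a two-harmonic periodic strain waveform (offset +
  fundamental + second harmonic) advanced stride by stride. Stride frequency
  follows treadmill speed; the cycle period carries multiplicative jitter
  whose coefficient of variation grows with RPE. Fatigue drifts the waveform
  linearly in (RPE − 13): offset shift, amplitude scale and waveform-shape
  (range-of-motion) scale per channel. The default preset is hip-dominant:
  hip offset drifts by −28 % and amplitude by +7 % over the 8-unit span from
  RPE 9 to 17, mirroring reported fatigue-related hip-kinematics changes,
  while knee and ankle drifts are near zero. Per-stride motor jitter
  (amplitude and offset) sets the noise floor that drift must beat.
* **Transduction** (`strain_to_readout`): resistive strain gauge,
  ΔR/R0 = GF·ε with gauge factor 5, read through a 40 kΩ voltage divider at
  3.3 V, plus Gaussian readout noise. The flagged noisy knee channel gets its
  noise inflated 20-fold so the default exclusion is visible in the data.

All randomness flows from a single integer seed; a session is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .signal_io import (
    GarmentConfig,
    RPETrace,
    SensorRecording,
    default_garment,
    RPE_MAX,
    RPE_MIN,
)

__all__ = [
    "SensorModelParams",
    "ChannelWaveform",
    "GaitParams",
    "ChannelDrift",
    "FatigueEffect",
    "ProtocolParams",
    "SpeedSchedule",
    "StrainRangeError",
    "SimulationTimeoutError",
    "strain_to_readout",
    "simulate_protocol",
    "simulate_session",
    "preset",
    "PRESET_NAMES",
]


class StrainRangeError(ValueError):
    """Strain outside the sensor's linear working range."""


class SimulationTimeoutError(RuntimeError):
    """The exertion response curve never reached the stop threshold."""


@dataclass
class SensorModelParams:
    """Resistive transduction parameters of one sensor type.

    gauge_factor is the relative resistance change per unit strain; the
    divider converts resistance to volts. max_strain bounds the linear
    working range (fractional elongation).
    """

    gauge_factor: float = 5.0
    baseline_resistance_R0: float = 40_000.0
    divider_resistance: float = 40_000.0
    supply_voltage: float = 3.3
    noise_sd: float = 0.005
    max_strain: float = 0.30

    def __post_init__(self) -> None:
        if self.gauge_factor <= 0:
            raise ValueError("gauge_factor must be positive")
        if self.baseline_resistance_R0 <= 0 or self.divider_resistance <= 0:
            raise ValueError("resistances must be positive")
        if not (0 < self.max_strain <= 0.30):
            raise ValueError("max_strain must lie in (0, 0.30] (linear range)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def strain_to_readout(strain, p: SensorModelParams):
    """Transduce strain (fractional elongation) to divider output voltage.

    R = R0·(1 + GF·ε); V = Vcc·R / (R + R_divider). Accepts scalars or
    arrays; raises StrainRangeError outside the linear range. Noise is *not*
    added here — `simulate_session` owns the noise model.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(np.abs(eps) > p.max_strain + 1e-12):
        raise StrainRangeError(
            f"strain beyond linear range ±{p.max_strain} (max |ε| = {np.abs(eps).max():.3f})"
        )
    r = p.baseline_resistance_R0 * (1.0 + p.gauge_factor * eps)
    if np.any(r <= 0):
        raise StrainRangeError("strain drives modeled resistance non-positive")
    v = p.supply_voltage * r / (r + p.divider_resistance)
    if np.isscalar(strain):
        return float(v)
    return v


@dataclass
class ChannelWaveform:
    """Two-harmonic gait waveform of one channel, in strain units.

    ε(φ) = offset + amplitude·[sin(φ + phase) + h2·sin(2(φ + phase))]
    """

    amplitude: float
    phase: float
    offset: float
    h2: float = 0.35

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class GaitParams:
    """Cadence model and per-channel waveforms.

    Stride frequency (full gait cycles of one limb per second) is linear in
    treadmill speed: f(v) = f8 + slope·(v − 8 km/h). Defaults put a
    recreational runner near 1.35 Hz at 8 km/h.
    """

    stride_frequency_at_8kmh: float = 1.35
    stride_frequency_slope: float = 0.007
    waveforms: dict[str, ChannelWaveform] = field(default_factory=dict)

    def waveform(self, channel_id: str) -> ChannelWaveform:
        try:
            return self.waveforms[channel_id]
        except KeyError:
            raise KeyError(f"no waveform for channel {channel_id!r}") from None


@dataclass
class ChannelDrift:
    """Linear fatigue drift coefficients of one channel, per RPE unit above 13.

    offset_rel shifts the waveform offset by that fraction of its baseline
    per RPE unit; amplitude_rel scales the amplitude; rom_rel scales the
    second-harmonic weight (waveform shape / range-of-motion proxy). All are
    zero at RPE 13 by construction.
    """

    offset_rel: float = 0.0
    amplitude_rel: float = 0.0
    rom_rel: float = 0.0

    @property
    def total_magnitude(self) -> float:
        return abs(self.offset_rel) + abs(self.amplitude_rel) + abs(self.rom_rel)


@dataclass
class FatigueEffect:
    """How fatigue perturbs gait: waveform drift plus motor variability.

    Drift is linear in (RPE − 13) and anchored at zero for RPE 13. Stride
    timing variability (CV of the cycle period) grows with RPE. Per-stride
    motor jitter (amplitude fraction, offset in strain units) is drawn
    independently per channel and stride and does not average out within a
    stride — it is the irreducible noise floor of per-stride features.
    """

    drift: dict[str, ChannelDrift] = field(default_factory=dict)
    stride_cv_base: float = 0.012
    stride_cv_slope: float = 0.001
    amplitude_jitter_sd: float = 0.015
    offset_jitter_sd: float = 0.001

    def channel_drift(self, channel_id: str) -> ChannelDrift:
        return self.drift.get(channel_id, ChannelDrift())

    def stride_cv(self, rpe: float) -> float:
        return max(0.0, self.stride_cv_base + self.stride_cv_slope * (rpe - 13.0))

    def joint_drift_magnitude(self, garment: GarmentConfig, joint: str) -> float:
        """Summed |drift| over the joint's channels (includes excluded ones)."""
        return sum(
            self.channel_drift(c.channel_id).total_magnitude
            for c in garment.channels
            if c.joint == joint
        )


@dataclass
class ProtocolParams:
    """Incremental treadmill protocol with 3-minute Borg reports.

    Speed rises by `increment` after each report below `hold_threshold`
    (RPE 13, "somewhat hard"), then holds; the session records
    `post_stop_extra_s` more seconds after the first report at or above
    `stop_threshold` (RPE 17, "very hard"). `response_curve`, if given, maps
    time in seconds to latent exertion on the Borg scale; otherwise a
    monotone participant curve is drawn from the seed with the time of first
    RPE-17 report landing in `target_duration_range_s`.
    """

    start_speed: float = 8.0
    increment: float = 1.0
    report_interval_s: float = 180.0
    hold_threshold: int = 13
    stop_threshold: int = 17
    post_stop_extra_s: float = 60.0
    max_duration_s: float = 3600.0
    target_duration_range_s: tuple[float, float] = (1750.0, 2250.0)
    initial_rpe_range: tuple[float, float] = (9.0, 11.0)
    response_curve: Callable[[float], float] | None = None


@dataclass
class SpeedSchedule:
    """Piecewise-constant treadmill speed; `times[i]` starts `speeds[i]`."""

    times: np.ndarray
    speeds: np.ndarray

    def speed_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        idx = max(idx, 0)
        return float(self.speeds[idx])


def _draw_response_curve(
    params: ProtocolParams, rng: np.random.Generator
) -> Callable[[float], float]:
    e0 = rng.uniform(*params.initial_rpe_range)
    t17 = rng.uniform(*params.target_duration_range_s)
    # slope chosen so the rounded curve first prints stop_threshold near t17
    rate = (params.stop_threshold - 0.49 - e0) / t17
    return lambda t: e0 + rate * t


def simulate_protocol(
    params: ProtocolParams, seed: int
) -> tuple[RPETrace, SpeedSchedule]:
    """Walk the report/speed automaton along a participant's exertion curve.

    Reports occur at t = 0, 180, 360, … as the rounded latent curve, clipped
    to the Borg range. Returns the report trace and the speed schedule; the
    recording is meant to span until last-report time + post_stop_extra_s.
    """
    rng = np.random.default_rng(seed)
    curve = params.response_curve or _draw_response_curve(params, rng)

    times: list[float] = []
    scores: list[int] = []
    speed_times: list[float] = [0.0]
    speeds: list[float] = [params.start_speed]
    t = 0.0
    while True:
        if t > params.max_duration_s:
            raise SimulationTimeoutError(
                f"exertion curve did not reach {params.stop_threshold} within "
                f"{params.max_duration_s} s"
            )
        score = int(np.clip(np.floor(curve(t) + 0.5), RPE_MIN, RPE_MAX))
        if scores and score < scores[-1]:
            score = scores[-1]  # exertion reports never decrease under this protocol
        times.append(t)
        scores.append(score)
        if score >= params.stop_threshold:
            break
        if score < params.hold_threshold:
            speed_times.append(t + params.report_interval_s)
            speeds.append(speeds[-1] + params.increment)
        t += params.report_interval_s

    trace = RPETrace(reports=list(zip(times, scores)))
    schedule = SpeedSchedule(
        times=np.array(speed_times), speeds=np.array(speeds)
    )
    return trace, schedule


def _default_waveforms() -> dict[str, ChannelWaveform]:
    # offsets/amplitudes in strain fraction; margins keep peak strain < 0.30
    # for all RPE in [6, 20] under the default drift preset
    return {
        "hip_1": ChannelWaveform(amplitude=0.130, phase=0.00, offset=0.080),
        "hip_2": ChannelWaveform(amplitude=0.110, phase=0.45, offset=0.070),
        "hip_3": ChannelWaveform(amplitude=0.120, phase=0.90, offset=0.090),
        "hip_4": ChannelWaveform(amplitude=0.100, phase=1.30, offset=0.075),
        "knee_1": ChannelWaveform(amplitude=0.140, phase=2.10, offset=0.060),
        "knee_2": ChannelWaveform(amplitude=0.130, phase=2.40, offset=0.060),
        "ankle_1": ChannelWaveform(amplitude=0.100, phase=3.40, offset=0.050),
        "ankle_2": ChannelWaveform(amplitude=0.090, phase=3.80, offset=0.055),
        "ankle_3": ChannelWaveform(amplitude=0.110, phase=4.20, offset=0.050),
    }


def _hip_dominant_drift() -> dict[str, ChannelDrift]:
    # hip: −28 % offset and +7 % amplitude over the 8-unit RPE 9→17 span
    hip = ChannelDrift(offset_rel=-0.035, amplitude_rel=0.00875, rom_rel=0.004)
    knee = ChannelDrift(offset_rel=0.001, amplitude_rel=0.0015, rom_rel=-0.0015)
    ankle = ChannelDrift(offset_rel=0.0005, amplitude_rel=0.002, rom_rel=0.001)
    return {
        "hip_1": hip,
        "hip_2": hip,
        "hip_3": hip,
        "hip_4": hip,
        "knee_1": knee,
        "knee_2": knee,
        "ankle_1": ankle,
        "ankle_2": ankle,
        "ankle_3": ankle,
    }


PRESET_NAMES = ("default", "null-drift", "knee-dominant")


def preset(
    name: str = "default",
) -> tuple[GaitParams, FatigueEffect, ProtocolParams, SensorModelParams]:
    """Named generator parameter bundles.

    ``default`` is the hip-dominant study emulation; ``null-drift`` zeroes
    every fatigue effect and all motor jitter (features become constant
    across strides in the absence of readout noise); ``knee-dominant`` moves
    the large drift to the knee channels for ablation-order testing.
    """
    gait = GaitParams(waveforms=_default_waveforms())
    protocol = ProtocolParams()
    sensor = SensorModelParams()
    if name == "default":
        effect = FatigueEffect(drift=_hip_dominant_drift())
    elif name == "null-drift":
        effect = FatigueEffect(
            drift={},
            stride_cv_base=0.0,
            stride_cv_slope=0.0,
            amplitude_jitter_sd=0.0,
            offset_jitter_sd=0.0,
        )
    elif name == "knee-dominant":
        drift = _hip_dominant_drift()
        big, small = drift["hip_1"], drift["knee_1"]
        for c in ("hip_1", "hip_2", "hip_3", "hip_4"):
            drift[c] = small
        for c in ("knee_1", "knee_2"):
            drift[c] = big
        effect = FatigueEffect(drift=drift)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return gait, effect, protocol, sensor


def _validate_strain_envelope(
    gait: GaitParams, effect: FatigueEffect, sensor: SensorModelParams
) -> None:
    """Peak |strain| must stay in the linear range for every Borg level."""
    for cid, wf in gait.waveforms.items():
        drift = effect.channel_drift(cid)
        for rpe in (RPE_MIN, RPE_MAX):
            d = rpe - 13.0
            off = wf.offset * (1.0 + drift.offset_rel * d)
            amp = wf.amplitude * (1.0 + drift.amplitude_rel * d)
            h2 = wf.h2 * (1.0 + drift.rom_rel * d)
            peak = abs(off) + abs(amp) * (1.0 + abs(h2))
            if peak > sensor.max_strain:
                raise StrainRangeError(
                    f"channel {cid}: peak strain {peak:.3f} exceeds "
                    f"{sensor.max_strain} at RPE {rpe}"
                )


def simulate_session(
    gait: GaitParams | None = None,
    effect: FatigueEffect | None = None,
    protocol: ProtocolParams | None = None,
    sensor: SensorModelParams | None = None,
    seed: int = 0,
    garment: GarmentConfig | None = None,
    sampling_rate: float = 100.0,
) -> tuple[SensorRecording, RPETrace]:
    """Generate one full instrumented running session.

    Returns a 9-channel voltage recording at `sampling_rate` spanning the
    protocol duration, and the Borg report trace that generated it. Waveform
    drift follows the *reported* (piecewise-constant) RPE so that the
    generator's ground truth coincides with the labels a study would have.
    Deterministic for a fixed seed.
    """
    if gait is None or effect is None or protocol is None or sensor is None:
        d_gait, d_eff, d_proto, d_sensor = preset("default")
        gait = gait or d_gait
        effect = effect or d_eff
        protocol = protocol or d_proto
        sensor = sensor or d_sensor
    garment = garment or default_garment()
    _validate_strain_envelope(gait, effect, sensor)

    rng = np.random.default_rng(seed)
    trace, schedule = simulate_protocol(protocol, seed=int(rng.integers(2**31)))
    duration = float(trace.times[-1] + protocol.post_stop_extra_s)

    # stride clock: successive cycle periods with RPE-dependent CV jitter
    starts: list[float] = []
    periods: list[float] = []
    stride_rpe: list[int] = []
    t = 0.0
    while t < duration:
        rpe = trace.score_at(t)
        v = schedule.speed_at(t)
        f = gait.stride_frequency_at_8kmh + gait.stride_frequency_slope * (v - 8.0)
        cv = effect.stride_cv(rpe)
        jitter = rng.normal(0.0, cv) if cv > 0 else 0.0
        period = float(np.clip((1.0 / f) * (1.0 + jitter), 0.5 / f, 2.0 / f))
        starts.append(t)
        periods.append(period)
        stride_rpe.append(rpe)
        t += period
    starts_a = np.array(starts)
    periods_a = np.array(periods)
    d_units = np.array(stride_rpe, dtype=float) - 13.0
    n_strides = len(starts)

    n = int(round(duration * sampling_rate))
    t_samp = np.arange(n) / sampling_rate
    k = np.clip(np.searchsorted(starts_a, t_samp, side="right") - 1, 0, n_strides - 1)
    phase = 2.0 * np.pi * (t_samp - starts_a[k]) / periods_a[k]

    samples = np.empty((n, len(garment.channels)))
    for j, ch in enumerate(garment.channels):
        wf = gait.waveform(ch.channel_id)
        drift = effect.channel_drift(ch.channel_id)
        amp_jit = (
            rng.normal(0.0, effect.amplitude_jitter_sd, n_strides)
            if effect.amplitude_jitter_sd > 0
            else np.zeros(n_strides)
        )
        off_jit = (
            rng.normal(0.0, effect.offset_jitter_sd, n_strides)
            if effect.offset_jitter_sd > 0
            else np.zeros(n_strides)
        )
        off = wf.offset * (1.0 + drift.offset_rel * d_units) + off_jit
        amp = wf.amplitude * (1.0 + drift.amplitude_rel * d_units) * (1.0 + amp_jit)
        h2 = wf.h2 * (1.0 + drift.rom_rel * d_units)
        ph = phase + wf.phase
        strain = off[k] + amp[k] * (np.sin(ph) + h2[k] * np.sin(2.0 * ph))
        np.clip(strain, -sensor.max_strain, sensor.max_strain, out=strain)
        volts = strain_to_readout(strain, sensor)
        sd = sensor.noise_sd * (20.0 if ch.excluded else 1.0)
        if sd > 0:
            volts = volts + rng.normal(0.0, sd, n)
        np.clip(volts, 0.0, sensor.supply_voltage, out=volts)
        samples[:, j] = volts

    rec = SensorRecording(
        samples=samples,
        channels=list(garment.channels),
        sampling_rate=sampling_rate,
        start_time=0.0,
    )
    return rec, trace


def session_metadata(
    gait: GaitParams, effect: FatigueEffect, protocol: ProtocolParams,
    sensor: SensorModelParams, seed: int,
) -> dict:
    """JSON-serializable sidecar of the true generator parameters."""
    return {
        "seed": seed,
        "gait": {
            "stride_frequency_at_8kmh": gait.stride_frequency_at_8kmh,
            "stride_frequency_slope": gait.stride_frequency_slope,
            "waveforms": {k: asdict(v) for k, v in gait.waveforms.items()},
        },
        "fatigue_effect": {
            "drift": {k: asdict(v) for k, v in effect.drift.items()},
            "stride_cv_base": effect.stride_cv_base,
            "stride_cv_slope": effect.stride_cv_slope,
            "amplitude_jitter_sd": effect.amplitude_jitter_sd,
            "offset_jitter_sd": effect.offset_jitter_sd,
        },
        "protocol": {
            k: v for k, v in asdict(protocol).items() if k != "response_curve"
        },
        "sensor": asdict(sensor),
    }
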