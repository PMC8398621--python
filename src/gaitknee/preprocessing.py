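"""Signal conditioning and gait-cycle extraction for insole pressure trials.

The chain mirrors a standard treadmill protocol: trim a trial to its central
minute, denoise each channel (trailing moving average, then a zero-phase
4th-order Butterworth low-pass at 15 Hz), sum the ten channels into the total
plantar pressure, segment gait cycles with the Zero-To-Zero rule (toe-off =
first at-or-below-threshold sample after a loaded run), time-normalize every
cycle to 100 points, re-reference toe-off-start cycles to heel strike by
circular rotation, and min-max scale for the regressor.

Knee-angle streams (30 Hz) share the trial clock with the pressure stream;
angle cycles are sliced at the pressure-derived heel-strike times and
resampled the same way, so pressure and angle cycles pair one-to-one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np
from scipy import signal


# ---------------------------------------------------------------------------
# containers

@dataclass
class GaitCycle:
    """One stride as a 100-point heel-strike-referenced waveform.

    ``values`` holds kPa for pressure cycles or degrees for angle cycles
    (lateral-marker convention, ~180 deg at full knee extension).
    ``stance_fraction`` is the loaded fraction of the cycle.
    """

    values: np.ndarray
    modality: str  # "pressure" | "angle"
    reference_event: str = "heel_strike"
    source_index: int = 0
    stance_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (100,):
            raise ValueError(f"a gait cycle has exactly 100 samples, "
                             f"got shape {self.values.shape}")
        if self.modality not in ("pressure", "angle"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class TotalPressureSeries:
    """Sum of the 10 insole channels over time, in kPa."""

    sampling_rate: float
    values: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("total pressure series must be a non-empty 1-D array")


@dataclass(frozen=True)
class NormalizationParams:
    """Min-max scaling bounds: x_norm = (x - x_min) / (x_max - x_min)."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError(
                f"x_max ({self.x_max}) must exceed x_min ({self.x_min})")


@dataclass
class RawCycle:
    """A variable-length toe-off-to-toe-off segment of the total pressure."""

    values: np.ndarray
    start: int  # sample index of the opening toe-off within the series
    stop: int   # sample index of the closing toe-off (exclusive)


# ---------------------------------------------------------------------------
# conditioning

def trim_to_mid_minute(trial):
    """Return the centered 60 s window of a pressure or angle trial."""
    fs = trial.sampling_rate
    needed = int(round(60.0 * fs))
    if hasattr(trial, "channels"):
        n = trial.channels.shape[0]
    else:
        n = trial.angle.shape[0]
    if n < needed:
        raise ValueError(
            f"trial has {n / fs:.1f} s of data; at least 60.0 s are required "
            f"to trim to the middle minute")
    start = (n - needed) // 2
    stop = start + needed
    if hasattr(trial, "channels"):
        return replace(trial, channels=trial.channels[start:stop],
                       duration=needed / fs)
    return replace(trial, angle=trial.angle[start:stop],
                   duration=needed / fs)


def moving_average(values, window: int = 10):
    """Trailing flat-kernel mean; leading edge uses the partial window.

    Output length equals input length.  ``window=1`` is the identity.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    if v.size < window:
        raise ValueError(f"series of length {v.size} is shorter than the "
                         f"{window}-point window")
    if window == 1:
        return v.copy()
    c = np.concatenate(([0.0], np.cumsum(v, axis=0)))
    out = np.empty_like(v)
    idx = np.arange(v.shape[0])
    lo = np.maximum(idx - window + 1, 0)
    out = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    return out


def butterworth_lowpass(values, sampling_rate: float, cutoff: float = 15.0,
                        order: int = 4, zero_phase: bool = True):
    """Digital Butterworth low-pass, applied forward-backward by default.

    Zero-phase filtering keeps gait-event timing intact, which the
    segmentation downstream depends on; a single causal pass is available
    with ``zero_phase=False``.
    """
    nyquist = sampling_rate / 2.0
    if not cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist "
                         f"frequency {nyquist} Hz")
    sos = signal.butter(order, cutoff / nyquist, btype="low", output="sos")
    v = np.asarray(values, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, v, axis=0)
    return signal.sosfilt(sos, v, axis=0)


def total_plantar_pressure(trial) -> TotalPressureSeries:
    """Elementwise sum over the 10 pressure channels."""
    ch = np.asarray(trial.channels, dtype=float)
    if ch.ndim != 2 or ch.shape[1] != 10:
        raise ValueError(f"expected a [n_samples x 10] channel matrix, got "
                         f"shape {ch.shape}")
    prov = {"subject_id": getattr(trial, "subject_id", None),
            "shoe": getattr(trial, "shoe", None),
            "speed": getattr(trial, "speed", None)}
    return TotalPressureSeries(sampling_rate=trial.sampling_rate,
                               values=ch.sum(axis=1), provenance=prov)


def default_zero_threshold(values, fraction: float = 0.02) -> float:
    """Scale-free zero threshold: ``fraction`` of the 95th percentile."""
    return float(fraction * np.percentile(np.asarray(values, dtype=float), 95))


# ---------------------------------------------------------------------------
# Zero-To-Zero segmentation

def detect_toe_off_events(series, zero_threshold: float,
                          min_loaded_run: int = 1) -> np.ndarray:
    """Toe-off indices under the Zero-To-Zero rule.

    A toe-off is the first index at or below ``zero_threshold`` immediately
    following a run of more than ``min_loaded_run - 1`` consecutive values
    above the threshold.  With the default ``min_loaded_run=1`` this is the
    literal rule; a larger run length rejects noise-floor chatter.
    """
    values = series.values if isinstance(series, TotalPressureSeries) else series
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot detect events in an empty series")
    if not zero_threshold > 0:
        raise ValueError("zero_threshold must be strictly positive")
    loaded = v > zero_threshold
    # run length of consecutive loaded samples ending at each index
    run = np.zeros(v.size, dtype=int)
    for i in range(v.size):  # pragma: no branch
        run[i] = run[i - 1] + 1 if loaded[i] and i > 0 else int(loaded[i])
    drops = np.nonzero(~loaded[1:] & (run[:-1] >= min_loaded_run))[0] + 1
    return drops.astype(int)


def extract_cycles(series, events: Sequence[int], n_cycles: int = 30,
                   max_duration_dev: float = 0.4) -> List[RawCycle]:
    """The ``n_cycles`` event-to-event segments nearest the window center.

    Segments whose length deviates more than ``max_duration_dev`` from the
    median segment length are rejected as artifacts before selection.
    Segments exclude the closing toe-off sample.
    """
    values = series.values if isinstance(series, TotalPressureSeries) else series
    values = np.asarray(values, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.size < n_cycles + 1:
        raise ValueError(
            f"need at least {n_cycles + 1} toe-off events for {n_cycles} "
            f"cycles, found {events.size}")
    lengths = np.diff(events)
    median = np.median(lengths)
    ok = np.abs(lengths - median) <= max_duration_dev * median
    candidates = [(events[i], events[i + 1]) for i in range(len(lengths)) if ok[i]]
    if len(candidates) < n_cycles:
        raise ValueError(
            f"only {len(candidates)} artifact-free segments available, "
            f"{n_cycles} requested")
    center = values.size / 2.0
    mid = np.array([(a + b) / 2.0 for a, b in candidates])
    order = np.argsort(np.abs(mid - center), kind="stable")[:n_cycles]
    chosen = sorted(order)
    return [RawCycle(values=values[candidates[i][0]:candidates[i][1]],
                     start=int(candidates[i][0]), stop=int(candidates[i][1]))
            for i in chosen]


def resample_cycle_to_100(raw) -> np.ndarray:
    """Linear interpolation onto 100 equally spaced points, endpoints kept."""
    v = raw.values if isinstance(raw, RawCycle) else np.asarray(raw, dtype=float)
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to resample a cycle")
    return np.interp(np.linspace(0.0, v.size - 1, 100), np.arange(v.size), v)


def _first_contact_index(values, zero_threshold: float,
                         min_contact_run: int = 1) -> int:
    v = np.asarray(values, dtype=float)
    above = v > zero_threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_contact_run:
            return i - min_contact_run + 1
    return -1


def rotate_to_heel_strike(cycle, zero_threshold: float,
                          source_index: int = 0,
                          min_contact_run: int = 1) -> GaitCycle:
    """Re-reference a toe-off-start pressure cycle to heel strike.

    Heel strike is the first suprathreshold sample; the 100-point cycle is
    circularly rotated so that sample becomes index 0, and the stance
    fraction is the loaded remainder of the cycle.
    """
    v = np.asarray(cycle, dtype=float)
    if v.shape != (100,):
        raise ValueError("rotate_to_heel_strike expects a 100-point cycle")
    hs = _first_contact_index(v, zero_threshold, min_contact_run)
    if hs < 0:
        raise ValueError("no foot contact detected in cycle "
                         f"{source_index}: all samples <= threshold")
    return GaitCycle(values=np.roll(v, -hs), modality="pressure",
                     source_index=source_index,
                     stance_fraction=(100 - hs) / 100.0)


def extract_angle_cycles(trial, heel_strike_times: Sequence[float],
                         n_cycles: int = 30) -> List[GaitCycle]:
    """Slice the 30 Hz angle stream at pressure-derived heel-strike times.

    ``heel_strike_times`` are seconds on the shared trial clock and must
    contain at least ``n_cycles + 1`` entries; slice ``i`` spans heel strike
    ``i`` to heel strike ``i+1`` inclusive and is resampled to 100 points.
    """
    times = np.asarray(heel_strike_times, dtype=float)
    if n_cycles == 0:
        return []
    if times.size < n_cycles + 1:
        raise ValueError(f"need {n_cycles + 1} heel-strike times for "
                         f"{n_cycles} angle cycles, got {times.size}")
    fs = trial.sampling_rate
    n = trial.angle.shape[0]
    idx = np.rint(times * fs).astype(int)
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("heel-strike time outside the angle trial "
                         f"(trial spans 0..{(n - 1) / fs:.2f} s)")
    cycles = []
    for i in range(n_cycles):
        sl = trial.angle[idx[i]:idx[i + 1] + 1]
        cycles.append(GaitCycle(values=resample_cycle_to_100(sl),
                                modality="angle", source_index=i))
    return cycles


# ---------------------------------------------------------------------------
# min-max scaling

def fit_minmax(training) -> NormalizationParams:
    """Global min-max bounds over a training matrix (any shape)."""
    x = np.asarray(training, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if not hi > lo:
        raise ValueError("training data are constant; min-max scaling is "
                         "degenerate")
    return NormalizationParams(x_min=lo, x_max=hi)


def apply_minmax(values, params: NormalizationParams, invert: bool = False):
    """Forward: (x - min)/(max - min); invert: x_norm*(max - min) + min."""
    x = np.asarray(values, dtype=float)
    span = params.x_max - params.x_min
    if invert:
        return x * span + params.x_min
    return (x - params.x_min) / span


# ---------------------------------------------------------------------------
# full chain

@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning + segmentation chain."""

    ma_window: int = 10
    butter_cutoff: float = 15.0
    butter_order: int = 4
    zero_phase: bool = True
    apply_butterworth: bool = True
    n_cycles: int = 30
    threshold_fraction: float = 0.02
    zero_threshold: float | None = None  # explicit override, kPa
    min_loaded_run: int = 25  # samples at 100 Hz
    min_contact_run: int = 5  # samples in the 100-point cycle domain


def preprocess_trial_pair(pressure_trial, angle_trial,
                          config: PreprocessConfig | None = None):
    """Run the full chain on one paired trial.

    Returns ``(pressure_cycles, angle_cycles, info)`` with ``n_cycles`` of
    each, paired by index.  ``info`` carries the threshold and the
    heel-strike times used for the angle slicing.
    """
    cfg = config or PreprocessConfig()
    p = trim_to_mid_minute(pressure_trial)
    a = trim_to_mid_minute(angle_trial)
    ch = np.asarray(p.channels, dtype=float)
    if cfg.ma_window > 1:
        ch = np.column_stack([moving_average(ch[:, j], cfg.ma_window)
                              for j in range(ch.shape[1])])
    if cfg.apply_butterworth:
        ch = butterworth_lowpass(ch, p.sampling_rate, cfg.butter_cutoff,
                                 cfg.butter_order, cfg.zero_phase)
    ch = np.maximum(ch, 0.0)
    total = total_plantar_pressure(replace(p, channels=ch))
    thr = (cfg.zero_threshold if cfg.zero_threshold is not None
           else default_zero_threshold(total.values, cfg.threshold_fraction))
    events = detect_toe_off_events(total, thr, cfg.min_loaded_run)
    # one extra segment so every angle cycle has a closing heel strike
    segments = extract_cycles(total, events, cfg.n_cycles + 1)
    heel_strikes = []
    for seg in segments:
        rel = _first_contact_index(seg.values, thr, cfg.min_loaded_run)
        if rel < 0:
            raise ValueError("no heel strike found in segment "
                             f"[{seg.start}, {seg.stop})")
        heel_strikes.append((seg.start + rel) / p.sampling_rate)
    pressure_cycles = [
        rotate_to_heel_strike(resample_cycle_to_100(seg), thr,
                              source_index=i,
                              min_contact_run=cfg.min_contact_run)
        for i, seg in enumerate(segments[:-1])]
    angle_cycles = extract_angle_cycles(a, heel_strikes, cfg.n_cycles)
    info = {"zero_threshold": thr, "heel_strike_times": np.array(heel_strikes),
            "toe_off_indices": events}
    return pressure_cycles, angle_cycles, info
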