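"""Synthetic paired insole-pressure / knee-angle treadmill trials.

The generator emulates the study conditions of a 2-minute treadmill protocol:
a cohort of young women walks in three shoe types (flat S1, sneaker S2,
stiletto S3) at two self-selected speeds (comfortable C, fast F), with ten
capacitive pressure channels sampled at 100 Hz on the left insole and the
knee joint angle video-tracked at 30 Hz (lateral-marker convention, ~180 deg
at full extension).

Ground-truth structure built into every trial:

* pressure exists only during stance (first 60% of the gait cycle) as a
  double bump (heel-strike and push-off peaks); swing is exactly zero before
  noise;
* load shifts from rearfoot toward forefoot channels as heel height grows;
* swing-phase knee flexion shrinks with heel height and grows with speed;
* cadence and push-off magnitude grow with speed;
* additive Gaussian sensor noise and a >20 Hz treadmill-vibration component
  corrupt the pressure channels only, clipped at zero.

Cycle boundaries are snapped to the 100 Hz grid and stored in the trial
metadata, so segmentation can be validated against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .preprocessing import GaitCycle

SPEED_LABELS = ("C", "F")

#: channel allocation over the three instrumented foot regions
DEFAULT_CHANNEL_GROUPS: Dict[str, List[int]] = {
    "forefoot": [0, 1, 2, 3],
    "midfoot": [4, 5],
    "rearfoot": [6, 7, 8, 9],
}

STANCE_FRACTION = 0.6


@dataclass(frozen=True)
class ShoeSpec:
    """Geometry of one test shoe."""

    name: str
    heel_height: float  # cm
    ball_width: float  # cm
    shoe_size: float  # cm
    heel_base: float  # cm^2

    def __post_init__(self) -> None:
        for f in ("heel_height", "ball_width", "shoe_size", "heel_base"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")


DEFAULT_SHOES: Dict[str, ShoeSpec] = {
    "S1": ShoeSpec("S1", heel_height=1.0, ball_width=8.0, shoe_size=23.5,
                   heel_base=28.5),
    "S2": ShoeSpec("S2", heel_height=3.0, ball_width=9.5, shoe_size=23.5,
                   heel_base=55.3),
    "S3": ShoeSpec("S3", heel_height=9.0, ball_width=8.0, shoe_size=23.5,
                   heel_base=0.9),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait parameters drawn from the cohort distributions."""

    subject_id: str
    body_weight: float  # N
    comfortable_speed: float  # km/h
    fast_speed: float  # km/h
    cadence_comfortable: float  # strides/min
    cadence_fast: float  # strides/min
    rom_scale: float  # range-of-motion multiplier
    noise_sd: float  # kPa, per channel

    def __post_init__(self) -> None:
        if not (self.comfortable_speed > 0 and self.fast_speed > 0):
            raise ValueError("speeds must be positive")
        if not self.fast_speed > self.comfortable_speed:
            raise ValueError("fast_speed must exceed comfortable_speed")
        if not (self.cadence_comfortable > 0 and self.cadence_fast > 0):
            raise ValueError("cadences must be positive")
        if not 0.8 <= self.rom_scale <= 1.2:
            raise ValueError("rom_scale must lie in [0.8, 1.2]")

    def cadence(self, speed: str) -> float:
        _check_speed(speed)
        return self.cadence_comfortable if speed == "C" else self.cadence_fast


@dataclass
class TrialMeta:
    """Ground-truth cycle timing retained for validation."""

    heel_strike_times: np.ndarray  # s, cycle starts within the trial
    toe_off_times: np.ndarray  # s
    cycle_durations: np.ndarray  # s
    seed: int


@dataclass
class PressureTrial:
    """[n_samples x 10] insole pressure matrix in kPa at 100 Hz."""

    sampling_rate: float
    channels: np.ndarray
    subject_id: str
    shoe: str
    speed: str
    duration: float
    meta: TrialMeta | None = None


@dataclass
class AngleTrial:
    """Knee joint angle in degrees at 30 Hz (~180 at full extension)."""

    sampling_rate: float
    angle: np.ndarray
    subject_id: str
    shoe: str
    speed: str
    duration: float
    meta: TrialMeta | None = None


def _check_speed(speed: str) -> None:
    if speed not in SPEED_LABELS:
        raise ValueError(f"unknown speed label {speed!r}; expected one of "
                         f"{SPEED_LABELS}")


# ---------------------------------------------------------------------------
# cohort sampling
#
# Distributions follow the reported cohort and session statistics: body mass
# 50.40 +/- 2.20 kg, comfortable speed 2.40 +/- 0.30 km/h, fast speed
# 5.10 +/- 0.20 km/h.  Cadences (44 +/- 2 and 62 +/- 3 strides/min) follow
# from those speeds at typical stride lengths; range-of-motion and noise
# spreads are plausible wearable-sensor values (see docs/methods.md).

GRAVITY = 9.81

COHORT = {
    "mass_kg": (50.40, 2.20),
    "comfortable_kmh": (2.40, 0.30),
    "fast_kmh": (5.10, 0.20),
    "cadence_comfortable": (44.0, 2.0),
    "cadence_fast": (62.0, 3.0),
    "rom_scale": (1.0, 0.03),
    "noise_sd": (0.05, 0.01),
}


def make_cohort(n_subjects: int, seed: int) -> List[SubjectProfile]:
    """Draw ``n_subjects`` profiles; deterministic given ``seed``."""
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_subjects):
        mass = rng.normal(*COHORT["mass_kg"])
        mass = max(mass, 35.0)
        comfortable = rng.normal(*COHORT["comfortable_kmh"])
        fast = rng.normal(*COHORT["fast_kmh"])
        while not fast > comfortable > 0:
            comfortable = rng.normal(*COHORT["comfortable_kmh"])
            fast = rng.normal(*COHORT["fast_kmh"])
        cad_c = rng.normal(*COHORT["cadence_comfortable"])
        cad_f = rng.normal(*COHORT["cadence_fast"])
        while not cad_f > cad_c > 0:
            cad_c = rng.normal(*COHORT["cadence_comfortable"])
            cad_f = rng.normal(*COHORT["cadence_fast"])
        rom = float(np.clip(rng.normal(*COHORT["rom_scale"]), 0.8, 1.2))
        noise = max(rng.normal(*COHORT["noise_sd"]), 0.01)
        profiles.append(SubjectProfile(
            subject_id=f"SUBJ{i + 1:02d}", body_weight=mass * GRAVITY,
            comfortable_speed=comfortable, fast_speed=fast,
            cadence_comfortable=cad_c, cadence_fast=cad_f,
            rom_scale=rom, noise_sd=noise))
    return profiles


# ---------------------------------------------------------------------------
# continuous cycle templates (functions of phase u in [0, 1), heel strike at 0)

def _bump(u: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-cosine (sin^2) bump supported on (start, start+width).

    Exactly zero outside the open support, so stance-only waveforms carry
    true zeros through the swing phase.
    """
    v = (u - start) / width
    return np.where((v > 0.0) & (v < 1.0),
                    np.sin(np.pi * np.clip(v, 0, 1)) ** 2, 0.0)


def _heel_shift(shoe: ShoeSpec) -> float:
    """Normalized (0..1) forward load shift driven by heel height."""
    return min(0.025 * (shoe.heel_height - 1.0) / 0.2, 1.0)


def _heel_bump(u: np.ndarray, onset: float = 0.05) -> np.ndarray:
    # supported on [0, 0.36]; nonzero at u=0 (heel-strike impact), C1 at 0.36
    v = (u + onset) / (0.36 + onset)
    return np.where(u <= 0.36, np.sin(np.pi * np.clip(v, 0, 1)) ** 2, 0.0)


def _push_bump(u: np.ndarray, start: float = 0.30) -> np.ndarray:
    # push-off, starting at ``start`` and landing smoothly at toe-off (0.60)
    return _bump(u, start, 0.60 - start)


def _shoe_waveform_params(shoe: ShoeSpec) -> Tuple[float, float]:
    """(heel-bump onset, push-bump start) of the total-pressure template.

    Both are shoe-independent: the summed waveform tracks the vertical
    ground reaction force, whose double-bump shape is largely
    footwear-independent; heel height redistributes load across channels
    (see :func:`_channel_weights`) without altering the total.
    """
    return 0.05, 0.30


def _speed_factors(speed: str) -> Tuple[float, float, float]:
    """(push-off amplitude, peak-pressure scale, flexion scale) per speed."""
    _check_speed(speed)
    if speed == "C":
        return 0.95, 1.0, 0.92
    return 1.15, 1.10, 1.08


def _channel_weights(shoe: ShoeSpec, groups: Dict[str, List[int]]
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel shares of the heel-strike and push-off loads.

    Each share vector sums to one for every shoe, so heel height moves load
    between channels without changing the summed (total) waveform — the
    total plantar pressure tracks the vertical ground reaction force, whose
    double-bump shape is largely footwear-independent, while higher heels
    carry a larger fraction of it on the forefoot.
    """
    shift = 0.2 * _heel_shift(shoe)
    heel_share = {"rearfoot": 0.70 - 0.9 * shift,
                  "midfoot": 0.15 + 0.2 * shift,
                  "forefoot": 0.15 + 0.7 * shift}
    push_share = {"rearfoot": 0.15 - 0.3 * shift,
                  "midfoot": 0.15 - 0.1 * shift,
                  "forefoot": 0.70 + 0.4 * shift}
    w_heel = np.zeros(10)
    w_push = np.zeros(10)
    for region, chans in groups.items():
        for c in chans:
            w_heel[c] = heel_share[region] / len(chans)
            w_push[c] = push_share[region] / len(chans)
    return w_heel, w_push


def _pressure_channels_at(u: np.ndarray, shoe: ShoeSpec, speed: str,
                          profile: SubjectProfile,
                          groups: Dict[str, List[int]] | None = None
                          ) -> np.ndarray:
    """Noise-free [len(u) x 10] channel pressures at cycle phases ``u``."""
    groups = groups or DEFAULT_CHANNEL_GROUPS
    push_amp, peak_scale, _ = _speed_factors(speed)
    onset, push_start = _shoe_waveform_params(shoe)
    h = _heel_bump(u, onset)
    g = push_amp * _push_bump(u, push_start)
    # calibrate the summed peak to 0.55 kPa per kg of body mass
    mass = profile.body_weight / GRAVITY
    uu = np.linspace(0.0, 1.0, 2001)
    dense_peak = float((_heel_bump(uu, onset)
                        + push_amp * _push_bump(uu, push_start)).max())
    scale = 0.55 * mass * peak_scale / dense_peak
    w_heel, w_push = _channel_weights(shoe, groups)
    return scale * (np.outer(h, w_heel) + np.outer(g, w_push))


def _flexion_at(u: np.ndarray, shoe: ShoeSpec, speed: str,
                profile: SubjectProfile) -> np.ndarray:
    """Noise-free knee flexion (deg) at cycle phases ``u``.

    Two stance waves (loading response near 15% GC, pre-swing near 50%) and
    one large swing wave peaking near 75% GC.  The swing amplitude grows with
    speed and shrinks with heel height (stiff-knee effect of high heels).
    """
    _, _, flex_scale = _speed_factors(speed)
    heel_factor = 1.0 - 0.025 * (shoe.heel_height - 1.0)
    rom = profile.rom_scale
    return rom * (flex_scale * 16.0 * _bump(u, 0.02, 0.26)
                  + 8.0 * _bump(u, 0.40, 0.22)
                  + flex_scale * heel_factor * 58.0 * _bump(u, 0.53, 0.44)
                  ) + 2.0


def knee_angle_cycle(shoe: ShoeSpec, speed: str,
                     profile: SubjectProfile) -> GaitCycle:
    """Noise-free 100-point knee-angle template (phases k/99, deg)."""
    u = np.arange(100) / 99.0
    angle = 180.0 - _flexion_at(u, shoe, speed, profile)
    return GaitCycle(values=angle, modality="angle")


def pressure_channel_cycle(shoe: ShoeSpec, speed: str,
                           profile: SubjectProfile,
                           groups: Dict[str, List[int]] | None = None
                           ) -> np.ndarray:
    """Noise-free [100 x 10] channel template (phases k/100, kPa)."""
    u = np.arange(100) / 100.0
    return _pressure_channels_at(u, shoe, speed, profile, groups)


# ---------------------------------------------------------------------------
# trial synthesis

PRESSURE_RATE = 100.0
ANGLE_RATE = 30.0


def simulate_trial(profile: SubjectProfile, shoe: ShoeSpec, speed: str,
                   duration: float = 120.0, seed: int = 0,
                   cycle_jitter: float = 0.03,
                   treadmill_amp: float = 0.06,
                   treadmill_freq: float = 27.5
                   ) -> Tuple[PressureTrial, AngleTrial]:
    """One paired treadmill trial with shared ground-truth cycle timing.

    Cycle durations are the profile's cadence plus uniform +/-``cycle_jitter``
    relative jitter, snapped to whole 100 Hz samples.  Gaussian sensor noise
    (``profile.noise_sd``) and a ``treadmill_freq`` vibration component are
    added to the pressure channels only, then clipped at zero.
    """
    _check_speed(speed)
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng(seed)
    period = 60.0 / profile.cadence(speed) * PRESSURE_RATE  # samples
    if period > duration * PRESSURE_RATE:
        raise ValueError("trial too short for a single gait cycle")
    n_p = int(round(duration * PRESSURE_RATE))
    lengths = []
    total = 0
    while total < n_p:
        jit = 1.0 + cycle_jitter * rng.uniform(-1.0, 1.0)
        L = max(int(round(period * jit)), 20)
        lengths.append(L)
        total += L
    lengths = np.array(lengths, dtype=int)
    starts = np.concatenate(([0], np.cumsum(lengths)))  # heel-strike samples

    # phase of every 100 Hz sample within its cycle
    t_idx = np.arange(n_p)
    cyc = np.searchsorted(starts, t_idx, side="right") - 1
    u_p = (t_idx - starts[cyc]) / lengths[cyc]
    clean = _pressure_channels_at(u_p, shoe, speed, profile)

    noise = rng.normal(0.0, profile.noise_sd, size=clean.shape)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=10)
    tread = treadmill_amp * np.sin(
        2.0 * np.pi * treadmill_freq * t_idx[:, None] / PRESSURE_RATE
        + phases[None, :])
    channels = np.maximum(clean + noise + tread, 0.0)

    n_a = int(round(duration * ANGLE_RATE))
    pos = np.arange(n_a) * (PRESSURE_RATE / ANGLE_RATE)
    cyc_a = np.searchsorted(starts, pos, side="right") - 1
    u_a = (pos - starts[cyc_a]) / lengths[cyc_a]
    angle = 180.0 - _flexion_at(u_a, shoe, speed, profile)

    in_trial = starts[:-1] < n_p
    hs = starts[:-1][in_trial]
    toe_off = hs + np.ceil(STANCE_FRACTION * lengths[in_trial] - 1e-9).astype(int)
    meta = TrialMeta(heel_strike_times=hs / PRESSURE_RATE,
                     toe_off_times=toe_off / PRESSURE_RATE,
                     cycle_durations=lengths[in_trial] / PRESSURE_RATE,
                     seed=seed)
    ptrial = PressureTrial(sampling_rate=PRESSURE_RATE, channels=channels,
                           subject_id=profile.subject_id, shoe=shoe.name,
                           speed=speed, duration=duration, meta=meta)
    atrial = AngleTrial(sampling_rate=ANGLE_RATE, angle=angle,
                        subject_id=profile.subject_id, shoe=shoe.name,
                        speed=speed, duration=duration, meta=meta)
    return ptrial, atrial


def generate_cohort_trials(profiles: List[SubjectProfile],
                           duration: float = 120.0, seed: int = 0,
                           shoes: Dict[str, ShoeSpec] | None = None,
                           **trial_kwargs
                           ) -> Dict[Tuple[str, str, str], Tuple[PressureTrial, AngleTrial]]:
    """All subject x shoe x speed trials, seeded independently per trial."""
    shoes = shoes or DEFAULT_SHOES
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles) * len(shoes) * len(SPEED_LABELS))
    out = {}
    k = 0
    for prof in profiles:
        for shoe_name in sorted(shoes):
            for speed in SPEED_LABELS:
                child_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
                out[(prof.subject_id, shoe_name, speed)] = simulate_trial(
                    prof, shoes[shoe_name], speed, duration=duration,
                    seed=child_seed, **trial_kwargs)
                k += 1
    return out
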