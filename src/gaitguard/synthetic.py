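"""Seeded simulators for human gait and auto-walker IMU signals.

The generators are not biomechanical models; their contract is to reproduce
the qualitative contrasts that make the detection problem what it is:

* human walking is quasi-periodic and multi-harmonic, with appreciable
  cycle-to-cycle timing and amplitude variability that differs per subject;
* an auto-walker is a rocking cradle with almost perfectly regular timing,
  whose angular velocity concentrates on one geometry-determined gyro axis
  (device 1 rotates about X, device 2 about Z);
* every phone reports the same motion through its own per-channel gain and
  offset, so unseen phone models shift the raw signal statistics.

All simulators are pure functions of (parameters, seed).  Gravity is a
constant per-axis bias (plus, for the X-rotation device, its slow modulation
by the rocking angle) rather than full orientation dynamics — sufficient for
feature-level contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .signals_io import (
    GaitRecording,
    LabeledDataset,
    TARGET_RATE,
    concat_datasets,
    segment,
    split_by_ratio,
    windows_to_dataset,
)

GRAVITY = 9.80665

#: per-channel harmonic base amplitudes of walking (ax, ay, az, gx, gy, gz);
#: vertical (az) and anterior-posterior (ay) accelerations dominate, as in
#: waist/pocket-worn smartphone recordings
_GAIT_BASE_AMPS = np.array([1.2, 2.5, 3.5, 0.8, 1.2, 0.6])
_HARMONIC_DECAY = np.array([1.0, 0.40, 0.18, 0.08])


def _default_gait_amps(n_harmonics: int) -> np.ndarray:
    decay = _HARMONIC_DECAY[:n_harmonics]
    if len(decay) < n_harmonics:
        decay = np.concatenate([decay, decay[-1] * 0.5 ** np.arange(1, n_harmonics - len(decay) + 1)])
    return np.outer(_GAIT_BASE_AMPS, decay)


@dataclass
class GaitSimParams:
    """One walking subject.

    stride_freq : step frequency in Hz (~1.8 for normal walking)
    n_harmonics : sinusoids per channel at multiples of the stride frequency
    harmonic_amps : (6, n_harmonics) amplitudes (m/s^2 / rad/s); None = defaults
    cycle_jitter_cv : CV of the per-cycle period — the human variability knob
    amp_jitter_cv : CV of the per-cycle amplitude factor
    noise_sd : per-channel additive Gaussian noise sd; None = defaults
    subject_offset : constant per-channel bias; gravity rides on az by default
    orientation : optional 3x3 rotation applied to both sensor triads,
        modelling how the phone sits on the body (pocket, waistband, hand)
    """

    stride_freq: float = 1.8
    n_harmonics: int = 4
    harmonic_amps: np.ndarray | None = None
    cycle_jitter_cv: float = 0.08
    amp_jitter_cv: float = 0.10
    noise_sd: np.ndarray | None = None
    subject_offset: np.ndarray | None = None
    orientation: np.ndarray | None = None
    duration_s: float = 60.0
    seed: int = 0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if not 0.5 < self.stride_freq < 3.0:
            raise ValueError("stride_freq must lie in (0.5, 3.0) Hz")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.cycle_jitter_cv < 0 or self.amp_jitter_cv < 0:
            raise ValueError("jitter CVs must be >= 0")
        if self.harmonic_amps is None:
            self.harmonic_amps = _default_gait_amps(self.n_harmonics)
        self.harmonic_amps = np.asarray(self.harmonic_amps, dtype=float)
        if self.harmonic_amps.shape != (6, self.n_harmonics):
            raise ValueError("harmonic_amps must be (6, n_harmonics)")
        if self.noise_sd is None:
            self.noise_sd = np.array([0.25, 0.25, 0.25, 0.05, 0.05, 0.05])
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.subject_offset is None:
            self.subject_offset = np.array([0.0, 0.0, GRAVITY, 0.0, 0.0, 0.0])
        self.subject_offset = np.asarray(self.subject_offset, dtype=float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != (3, 3):
                raise ValueError("orientation must be a 3x3 rotation matrix")


@dataclass
class PhoneProfile:
    """Per-channel gain and offset of one phone's IMU."""

    gain: np.ndarray = field(default_factory=lambda: np.ones(6))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(6))
    phone_id: str = "phone"

    def apply(self, samples: np.ndarray) -> np.ndarray:
        return samples * np.asarray(self.gain) + np.asarray(self.offset)


@dataclass
class AutoWalkerSimParams:
    """One auto-walker session on one phone.

    device_type : 1 = rotation about the X-axis, 2 = rotation about the Z-axis
    rock_freq : rocking frequency in Hz (default 2.78, i.e. ~10,000
        oscillations per hour)
    dominant_amp : peak angular rate on the dominant gyro axis (rad/s)
    off_axis_leak : fraction of dominant_amp leaking onto the other gyro axes
    pivot_radius : lever arm from the rocking pivot to the phone's IMU (m);
        sets the centripetal (r*omega^2, at twice the rock frequency) and
        tangential (r*domega/dt) accelerations the phone experiences
    cycle_jitter_cv : per-cycle period CV — far below the human range
    """

    device_type: int = 1
    rock_freq: float = 2.78
    dominant_amp: float = 2.5
    off_axis_leak: float = 0.05
    pivot_radius: float = 0.08
    cycle_jitter_cv: float = 0.005
    amp_jitter_cv: float = 0.01
    noise_sd: np.ndarray | None = None
    phone_profile: PhoneProfile = field(default_factory=PhoneProfile)
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.device_type not in (1, 2):
            raise ValueError("device_type must be 1 or 2")
        if self.rock_freq <= 0 or self.dominant_amp <= 0:
            raise ValueError("rock_freq and dominant_amp must be positive")
        if self.pivot_radius < 0:
            raise ValueError("pivot_radius must be >= 0")
        if self.cycle_jitter_cv < 0 or self.off_axis_leak < 0:
            raise ValueError("cycle_jitter_cv and off_axis_leak must be >= 0")
        if self.noise_sd is None:
            self.noise_sd = np.array([0.08, 0.08, 0.08, 0.02, 0.02, 0.02])
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)


def _jittered_phase(rng: np.random.Generator, freq: float, cv: float,
                    duration_s: float, rate: float) -> np.ndarray:
    """Cycle-count phase phi(t): one unit per cycle, per-cycle period jitter.

    Periods are lognormal with mean 1/freq and the given CV; phi is piecewise
    linear between cycle boundaries, so instantaneous frequency is constant
    within a cycle.  cv = 0 gives a perfectly periodic phase (an rng draw is
    still consumed so seeds stay aligned across parameterizations).
    """
    mean_period = 1.0 / freq
    n_cycles = int(np.ceil(duration_s * freq)) + 2
    sigma = np.sqrt(np.log1p(cv ** 2))
    mu = np.log(mean_period) - sigma ** 2 / 2
    periods = rng.lognormal(mu, sigma, size=n_cycles) if sigma > 0 else (
        rng.random(n_cycles) * 0 + mean_period)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(0, duration_s, 1.0 / rate)
    return np.interp(t, boundaries, np.arange(len(boundaries), dtype=float)), t


def _cycle_amp_factor(rng: np.random.Generator, phase: np.ndarray, cv: float) -> np.ndarray:
    n_cycles = int(np.floor(phase.max())) + 1
    sigma = np.sqrt(np.log1p(cv ** 2))
    factors = rng.lognormal(-sigma ** 2 / 2, sigma, size=n_cycles) if sigma > 0 else (
        rng.random(n_cycles) * 0 + 1.0)
    return factors[np.minimum(phase.astype(int), n_cycles - 1)]


def simulate_gait(params: GaitSimParams) -> GaitRecording:
    """Simulate one subject walking at 100 Hz; deterministic under seed."""
    if params.duration_s < 1.0 / params.stride_freq:
        raise ValueError("duration too short for a single gait cycle")
    rng = np.random.default_rng(params.seed)
    phase, t = _jittered_phase(rng, params.stride_freq, params.cycle_jitter_cv,
                               params.duration_s, TARGET_RATE)
    amp_factor = _cycle_amp_factor(rng, phase, params.amp_jitter_cv)
    phases0 = rng.uniform(0, 2 * np.pi, size=(6, params.n_harmonics))
    samples = np.empty((len(t), 6))
    for c in range(6):
        sig = np.zeros(len(t))
        for h in range(params.n_harmonics):
            sig += params.harmonic_amps[c, h] * np.sin(
                2 * np.pi * (h + 1) * phase + phases0[c, h])
        samples[:, c] = sig * amp_factor + params.subject_offset[c]
    if params.orientation is not None:
        # rotate the physical motion (incl. gravity) into the phone frame;
        # sensor noise is added afterwards, in the sensor frame
        samples[:, :3] = samples[:, :3] @ params.orientation.T
        samples[:, 3:] = samples[:, 3:] @ params.orientation.T
    samples += rng.normal(0.0, 1.0, samples.shape) * params.noise_sd
    return GaitRecording(samples, TARGET_RATE, "gait", params.subject_id)


def simulate_autowalker(params: AutoWalkerSimParams) -> GaitRecording:
    """Simulate one auto-walker session at 100 Hz; deterministic under seed.

    The rocking angle is theta(t) = Theta * sin(2*pi*phi(t)); the dominant
    gyro channel carries d(theta)/dt with peak rate ``dominant_amp``.  For the
    X-rotation device gravity is modulated into ay/az; the Z-rotation device
    swings in the horizontal plane, so gravity stays on az and the horizontal
    accelerations carry small oscillatory components.
    """
    if params.duration_s < 1.0 / params.rock_freq:
        raise ValueError("duration too short for a single rocking cycle")
    rng = np.random.default_rng(params.seed)
    phase, t = _jittered_phase(rng, params.rock_freq, params.cycle_jitter_cv,
                               params.duration_s, TARGET_RATE)
    amp_factor = _cycle_amp_factor(rng, phase, params.amp_jitter_cv)

    theta_amp = params.dominant_amp / (2 * np.pi * params.rock_freq)
    theta = theta_amp * np.sin(2 * np.pi * phase)
    omega = params.dominant_amp * np.cos(2 * np.pi * phase) * amp_factor
    # imperfect mounting: the cradle wobbles about a second axis by an angle
    # proportional to the swing, so off-axis channels scale with the leak
    wobble = params.off_axis_leak * theta

    # the phone rides at a lever arm from the pivot: centripetal acceleration
    # r*omega^2 (at twice the rock frequency) along the arm, tangential
    # acceleration r*domega/dt perpendicular to it
    centripetal = params.pivot_radius * omega ** 2
    alpha = -params.dominant_amp * 2 * np.pi * params.rock_freq * np.sin(2 * np.pi * phase)
    tangential = params.pivot_radius * alpha * amp_factor

    samples = np.zeros((len(t), 6))
    leak_omega = params.off_axis_leak * omega
    if params.device_type == 1:
        samples[:, 3] = omega                      # gx dominant
        samples[:, 4] = leak_omega
        samples[:, 5] = leak_omega
        samples[:, 0] = GRAVITY * np.sin(wobble)   # side wobble tips gravity into ax
        samples[:, 1] = GRAVITY * np.sin(theta) + tangential
        samples[:, 2] = GRAVITY * np.cos(theta) + centripetal
        label = "autowalker1"
    else:
        samples[:, 5] = omega                      # gz dominant
        samples[:, 3] = leak_omega
        samples[:, 4] = leak_omega
        # horizontal swing: inertial accelerations stay in the XY plane,
        # plus a small gravity tilt from the wobble
        samples[:, 0] = centripetal
        samples[:, 1] = tangential + GRAVITY * np.sin(wobble)
        samples[:, 2] = GRAVITY * np.cos(wobble)
        label = "autowalker2"
    samples += rng.normal(0.0, 1.0, samples.shape) * params.noise_sd
    samples = params.phone_profile.apply(samples)
    return GaitRecording(samples, TARGET_RATE, label,
                         f"{params.phone_profile.phone_id}-aw{params.device_type}")


@dataclass
class BenchmarkConfig:
    """Composition of the default synthetic benchmark (~3,100 windows).

    Seen subjects/phones populate the train/test pool; unseen ones exist only
    in the generalization sections.  Unseen subjects are drawn from a wider
    biomechanical range and unseen phones from a wider gain/offset range than
    their seen counterparts, emulating cross-corpus and cross-device
    diversity.  ``overtime_sessions`` re-records the seen phones after a
    simulated delay: fresh seeds plus a small (+/-2%) gain drift.
    """

    n_seen_subjects: int = 32
    n_unseen_subjects: int = 12
    n_seen_phones: int = 2
    n_unseen_phones: int = 4
    gait_duration_s: float = 72.0
    aw_duration_s: float = 72.0
    aw_sessions_seen: int = 5
    aw_sessions_unseen: int = 2
    overtime_sessions: int = 2
    overtime_gain_drift: float = 0.02
    train_ratio: float = 0.8
    seen_subject_ids: Sequence[str] | None = None
    unseen_subject_ids: Sequence[str] | None = None
    seen_phone_ids: Sequence[str] | None = None
    unseen_phone_ids: Sequence[str] | None = None

    def resolve_ids(self) -> tuple[list[str], list[str], list[str], list[str]]:
        seen_s = list(self.seen_subject_ids or (f"subj{i:02d}" for i in range(self.n_seen_subjects)))
        unseen_s = list(self.unseen_subject_ids or (f"newsubj{i:02d}" for i in range(self.n_unseen_subjects)))
        seen_p = list(self.seen_phone_ids or (f"phone{i}" for i in range(self.n_seen_phones)))
        unseen_p = list(self.unseen_phone_ids or (f"newphone{i}" for i in range(self.n_unseen_phones)))
        overlap = (set(seen_s) & set(unseen_s)) | (set(seen_p) & set(unseen_p))
        if overlap:
            raise ValueError(f"seen and unseen identifiers overlap: {sorted(overlap)}")
        return seen_s, unseen_s, seen_p, unseen_p


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(axis * angle).as_matrix()


_BASE_DECAY = _HARMONIC_DECAY.copy()


def _draw_subject(rng: np.random.Generator, subject_id: str, duration_s: float,
                  unseen: bool) -> GaitSimParams:
    # Seen subjects cluster around typical walking with modest placement
    # scatter.  Unseen subjects emulate cross-corpus gait diversity: a wider
    # pace range, quiet low-amplitude walkers, near-sinusoidal very regular
    # gaits (steep harmonic decay, low timing jitter) and arbitrary phone
    # placements (free orientation).
    if unseen:
        stride = rng.uniform(1.2, 2.6)
        amp_scale = rng.lognormal(-0.3, 0.5, size=6)
        jitter = rng.uniform(0.015, 0.15)
        decay_pow = rng.uniform(0.5, 3.0)
        orientation = _random_rotation(rng, 90.0)
    else:
        stride = float(np.clip(rng.normal(1.8, 0.12), 1.4, 2.2))
        amp_scale = rng.lognormal(0.0, 0.15, size=6)
        jitter = rng.uniform(0.05, 0.12)
        decay_pow = rng.uniform(0.8, 1.2)
        orientation = _random_rotation(rng, 35.0)
    amps = (_GAIT_BASE_AMPS[:, None] * _BASE_DECAY ** decay_pow)
    amps = amps * amp_scale[:, None]
    offset = np.array([0.0, 0.0, GRAVITY, 0.0, 0.0, 0.0]) + np.concatenate(
        [rng.normal(0, 0.3, 3), rng.normal(0, 0.02, 3)])
    return GaitSimParams(stride_freq=stride, n_harmonics=4, harmonic_amps=amps,
                         cycle_jitter_cv=jitter, amp_jitter_cv=rng.uniform(0.06, 0.14),
                         subject_offset=offset, orientation=orientation,
                         duration_s=duration_s,
                         seed=int(rng.integers(2 ** 31)), subject_id=subject_id)


def _draw_phone(rng: np.random.Generator, phone_id: str,
                unseen: bool) -> tuple[PhoneProfile, dict]:
    """A phone's sensor profile plus its mechanical coupling to a cradle.

    Every phone model reports the same motion differently: per-channel gain
    and offset, broadband vibration it picks up from the rocking mechanism
    (``rattle``), how vigorously the cradle swings it (``swing``, peak rad/s,
    set by phone mass and clamping) and how much of the swing wobbles onto
    off axes (``leak``).  Unseen phone models span a much wider range of all
    four than the two training phones.
    """
    if unseen:
        gain = rng.normal(1.0, 0.15, size=6)
        offset = np.concatenate([rng.normal(0, 0.4, 3), rng.normal(0, 0.03, 3)])
        character = {"rattle": rng.uniform(0.5, 3.0),
                     "swing": rng.uniform(1.5, 4.8),
                     "leak": rng.uniform(0.05, 0.35),
                     "radius": rng.uniform(0.03, 0.15)}
    else:
        gain = rng.normal(1.0, 0.05, size=6)
        offset = np.concatenate([rng.normal(0, 0.15, 3), rng.normal(0, 0.01, 3)])
        character = {"rattle": rng.uniform(0.5, 1.5),
                     "swing": float(rng.lognormal(np.log(2.5), 0.1)),
                     "leak": rng.uniform(0.03, 0.08),
                     "radius": rng.uniform(0.05, 0.10)}
    return PhoneProfile(np.clip(gain, 0.6, 1.4), offset, phone_id), character


_AW_BASE_NOISE = np.array([0.08, 0.08, 0.08, 0.02, 0.02, 0.02])


def _aw_params(rng: np.random.Generator, device_type: int, profile: PhoneProfile,
               character: dict, duration_s: float) -> AutoWalkerSimParams:
    return AutoWalkerSimParams(
        device_type=device_type,
        rock_freq=float(np.clip(rng.normal(2.78, 0.05), 2.0, 3.5)),
        dominant_amp=character["swing"] * float(rng.lognormal(0.0, 0.05)),
        off_axis_leak=character["leak"],
        pivot_radius=character["radius"],
        noise_sd=_AW_BASE_NOISE * character["rattle"],
        phone_profile=profile,
        duration_s=duration_s,
        seed=int(rng.integers(2 ** 31)),
    )


def make_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> LabeledDataset:
    """Build the full labeled benchmark: windows, labels, groups, splits, sections.

    Seen gait subjects and seen phones are split train/test at the configured
    ratio within each subject/device; unseen subjects, unseen phones and
    over-time sessions land in the ``unseen`` split under their own section
    tags.  Deterministic under (config, seed).
    """
    config = config or BenchmarkConfig()
    seen_s, unseen_s, seen_p, unseen_p = config.resolve_ids()
    rng = np.random.default_rng(seed)

    parts: list[LabeledDataset] = []

    def add(recording: GaitRecording, section: str) -> None:
        wins = segment(recording)
        if not wins:
            return
        # placeholder; the real split assignment happens once all parts exist
        split = np.full(len(wins), "unseen", dtype=object)
        parts.append(windows_to_dataset(wins, split, np.full(len(wins), section, dtype=object)))

    for sid in seen_s:
        add(simulate_gait(_draw_subject(rng, sid, config.gait_duration_s, unseen=False)), "seen")
    for sid in unseen_s:
        add(simulate_gait(_draw_subject(rng, sid, config.gait_duration_s, unseen=True)),
            "unseen_subject")

    seen_phones = [_draw_phone(rng, pid, unseen=False) for pid in seen_p]
    unseen_phones = [_draw_phone(rng, pid, unseen=True) for pid in unseen_p]

    for profile, character in seen_phones:
        for device in (1, 2):
            for _ in range(config.aw_sessions_seen):
                add(simulate_autowalker(_aw_params(rng, device, profile, character,
                                                   config.aw_duration_s)), "seen")
    for profile, character in unseen_phones:
        for device in (1, 2):
            for _ in range(config.aw_sessions_unseen):
                add(simulate_autowalker(_aw_params(rng, device, profile, character,
                                                   config.aw_duration_s)), "unseen_phone")

    # over-time sessions: same seen phones two weeks on — fresh seeds, small gain drift
    for profile, character in seen_phones:
        drift = rng.uniform(1 - config.overtime_gain_drift, 1 + config.overtime_gain_drift, size=6)
        drifted = PhoneProfile(np.asarray(profile.gain) * drift, np.asarray(profile.offset),
                               profile.phone_id)
        for device in (1, 2):
            for _ in range(config.overtime_sessions):
                add(simulate_autowalker(_aw_params(rng, device, drifted, character,
                                                   config.aw_duration_s)), "overtime")

    dataset = concat_datasets(parts)
    seen_mask = dataset.section == "seen"
    split = np.full(len(dataset), "unseen", dtype=object)
    split[seen_mask] = split_by_ratio(dataset.groups[seen_mask], config.train_ratio, seed)
    dataset.split = split
    return dataset
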