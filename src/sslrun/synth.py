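"""Synthetic running cohorts with dual-IMU streams, vGRF and ground-truth loads.

The generator emulates a treadmill running study: each subject runs at a set
of fixed belt speeds while a pelvis- and a right-foot-mounted IMU record
free acceleration (m/s^2) and orientation quaternions at 240 Hz, an
instrumented treadmill records the right-belt vertical ground reaction force
(vGRF, N) at 1,200 Hz, and four structure-specific load (SSL) signals --
Achilles tendon, patellar tendon, ankle and knee contact force -- are emitted
directly in newtons on the vGRF clock (standing in for the musculoskeletal
modelling chain that produces them on real data).

Every stance-phase load follows a piecewise raised-cosine template
``A * rc(u; tau)`` (peak amplitude ``A`` in BW, time-to-peak fraction
``tau``), which is smooth, unimodal, zero at initial contact and toe-off,
and integrable in closed form: the mean of ``rc`` over stance is exactly 1/2
regardless of ``tau``, so the true impulse is ``A * stance_duration / 2``.
The peak amplitude is a deterministic function of belt speed, subject mass
and two latent gait factors (one per subject, one per step) that *also*
scale the IMU waveform amplitudes, so the IMU -> SSL regression task is
identifiable by construction.  The time-to-peak fraction is coupled to the
timing of a foot-sensor waveform for the same reason.

Axis conventions (documented, fixed): acceleration channel index 2 is the
vertical axis; the generator emits gravity-free acceleration oscillating
around 0 so the g-relative gait-event thresholds apply directly.  Foot
angular velocity lives on the sensor y axis (sagittal), pelvis angular
velocity on the sensor z axis.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

G = 9.81  # m/s^2, gravity constant used throughout

STRUCTURES = ("achilles", "patellar", "ankle", "knee")

# Cohort anthropometrics: per-sex mean/SD of mass (kg), age (yr), height (cm),
# shoe length (cm), sole thickness (cm).
ANTHROPOMETRICS = {
    "male": {
        "mass": (79.8, 9.5),
        "age": (24.4, 6.7),
        "height": (186.3, 7.4),
        "shoe_length": (31.0, 1.2),
        "sole_thickness": (3.3, 0.8),
    },
    "female": {
        "mass": (63.2, 2.9),
        "age": (22.6, 3.5),
        "height": (173.1, 5.9),
        "shoe_length": (28.4, 1.0),
        "sole_thickness": (3.1, 1.2),
    },
}

# Physiologic truncation ranges for anthropometric draws.
ANTHRO_RANGES = {
    "mass": (45.0, 110.0),
    "age": (18.0, 60.0),
    "height": (150.0, 210.0),
    "shoe_length": (24.0, 36.0),
    "sole_thickness": (0.5, 6.0),
}

# SSL template parameters per structure: base peak amplitude (BW) at the
# reference condition (2.78 m/s, 75 kg, zero latents) and base time-to-peak
# fraction.  Peaks near mid-stance for Achilles/ankle/knee, earlier for the
# patellar tendon, mirroring where running loads culminate.
STRUCTURE_PARAMS = {
    "achilles": {"base": 5.5, "tau0": 0.47},
    "patellar": {"base": 4.0, "tau0": 0.38},
    "ankle": {"base": 8.0, "tau0": 0.46},
    "knee": {"base": 6.5, "tau0": 0.42},
}

# Relative amplitude model: A_rel = 1 + SPEED_SLOPE*(v - 2.78)
#   + MASS_SLOPE*(mass-75)/10 + LATENT_SCALE*(0.8 z_subj + 0.6 z_step),
# clipped to AMP_REL_RANGE.  Chosen so that speed and mass dominate the
# amplitude variance (peak regressed on speed+mass gives R^2 well above 0.5
# across a default cohort) while the latent factors leave the mean-curve
# regressor clearly beatable.
SPEED_SLOPE = 0.35
MASS_SLOPE = 0.20
LATENT_SCALE = 0.15
STRUCT_LATENT_SCALE = 0.05
STRUCT_FACTOR_RANGE = (0.85, 1.15)
# the clip keeps every clean peak inside the (0.5, 15] BW acceptance band:
# max 8.0 * 1.6 * 1.15 = 14.7 BW, min 4.0 * 0.25 * 0.85 = 0.85 BW
AMP_REL_RANGE = (0.25, 1.6)

TAU_SPEED_SLOPE = 0.05
TAU_LATENT_SCALE = 0.04
TAU_RANGE = (0.25, 0.65)

ARTIFACT_KINDS = ("dropout", "stance_inflation", "ssl_out_of_range")


def raised_cosine(u: np.ndarray, tau: float) -> np.ndarray:
    """Unit-peak piecewise raised-cosine on u in [0, 1], peaking at u = tau.

    Rising half-cosine on [0, tau], falling half-cosine on [tau, 1]; zero and
    C1-smooth at both endpoints.  Its mean over [0, 1] is exactly 1/2.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    rise = (u >= 0) & (u <= tau)
    fall = (u > tau) & (u <= 1)
    if tau > 0:
        out[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / tau))
    out[fall] = 0.5 * (1.0 + np.cos(np.pi * (u[fall] - tau) / (1.0 - tau)))
    return out


def structure_tau(structure: str, tau_offset: float) -> float:
    """Effective time-to-peak fraction of a structure's template."""
    return float(np.clip(STRUCTURE_PARAMS[structure]["tau0"] + tau_offset, *TAU_RANGE))


def template_curve(structure: str, amp_bw: float, tau_offset: float, n: int) -> np.ndarray:
    """Evaluate the noise-free SSL template (BW) on n stance samples."""
    u = np.arange(n) / (n - 1)
    return amp_bw * raised_cosine(u, structure_tau(structure, tau_offset))


@dataclass
class SubjectProfile:
    """Anthropometrics and shoe descriptors for one participant."""

    subject_id: str
    mass: float  # kg
    sex: str  # "male" | "female"
    age: float  # years
    height: float  # cm
    shoe_length: float  # cm
    sole_thickness: float  # cm

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("mass", "age", "height", "shoe_length", "sole_thickness"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18, got {self.age}")

    @property
    def body_weight(self) -> float:
        """Body weight in newtons (mass * g)."""
        return self.mass * G


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; the seed fully determines the output."""

    n_subjects: int = 10
    speeds: tuple[float, ...] = (2.22, 2.50, 2.78, 3.33)
    trial_duration: float = 120.0  # s
    imu_rate: float = 240.0  # Hz
    grf_rate: float = 1200.0  # Hz
    noise_scale: float = 1.0  # scales all additive signal noise
    corrupt_fraction: float = 0.0
    coupling: float = 1.0  # latent -> IMU-waveform coupling strength
    sex_ratio: float = 36.0 / 43.0  # proportion of males
    imu_lag_samples: int = 0  # known lag of IMU streams vs vGRF clock
    seed: int = 0

    def __post_init__(self) -> None:
        self.speeds = tuple(self.speeds)
        if self.imu_rate <= 0 or self.grf_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if not 0.0 <= self.corrupt_fraction <= 1.0:
            raise ValueError("corrupt_fraction must be in [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for v in self.speeds:
            if not 2.0 <= v <= 4.0:
                raise ValueError(f"speed {v} m/s outside the supported 2-4 m/s band")


@dataclass
class StepTruth:
    """Generative ground truth for one right-foot step (for recovery tests)."""

    index: int
    ic_grf: int  # sample index of the 50 N upward crossing, vGRF clock
    to_grf: int  # sample index of the 50 N downward crossing, vGRF clock
    ic_imu: int  # IC mapped onto the IMU clock (before any injected lag)
    amp_rel: float  # shared relative amplitude factor
    amps: dict  # structure -> peak amplitude in BW
    tau: float  # time-to-peak *offset* shared across structures (see structure_tau)
    stance_duration: float  # s, from the 50 N crossings
    has_next: bool  # False for the trial's final step (step duration undefined)
    template_start: int = 0  # constructed stance start on the vGRF clock
    template_len: int = 0  # constructed stance length in vGRF samples
    corrupted: bool = False
    artifact: str | None = None


@dataclass
class TrialRecording:
    """Synchronized multi-rate streams for one subject x speed."""

    subject_id: str
    speed: float
    pelvis_acc: np.ndarray  # (3, T_imu) m/s^2, free acceleration
    pelvis_quat: np.ndarray  # (4, T_imu) unit quaternions, scalar-first
    foot_acc: np.ndarray  # (3, T_imu)
    foot_quat: np.ndarray  # (4, T_imu)
    vgrf: np.ndarray  # (T_grf,) N
    ssl_truth: dict  # structure -> (T_grf,) N
    imu_rate: float
    grf_rate: float
    lag_samples: int  # known IMU-vs-GRF lag on the IMU clock
    steps: list = field(default_factory=list)  # list[StepTruth]

    def validate(self) -> None:
        for name, q in (("pelvis", self.pelvis_quat), ("foot", self.foot_quat)):
            norms = np.linalg.norm(q, axis=0)
            if np.max(np.abs(norms - 1.0)) > 1e-6:
                raise ValueError(f"{name} quaternion stream is not unit-norm")
        if np.any(self.vgrf < 0):
            raise ValueError("vGRF must be non-negative")
        for s in STRUCTURES:
            if s not in self.ssl_truth:
                raise ValueError(f"missing SSL stream for {s}")


def _subject_rng(seed: int, subject_id: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode()), salt])


def _subject_latent(seed: int, subject_id: str) -> float:
    return float(_subject_rng(seed, subject_id, salt=1).standard_normal())


def generate_subject(
    rng: np.random.Generator,
    sex_ratio: float = 36.0 / 43.0,
    subject_id: str = "S00",
    anthro_noise_scale: float = 1.0,
) -> SubjectProfile:
    """Draw one participant from per-sex truncated normal distributions.

    ``anthro_noise_scale`` scales the anthropometric SDs (0 gives the per-sex
    means exactly); it is deliberately independent of the signal-noise knob.
    """
    sex = "male" if rng.random() < sex_ratio else "female"
    stats = ANTHROPOMETRICS[sex]
    values = {}
    for name, (mu, sd) in stats.items():
        lo, hi = ANTHRO_RANGES[name]
        v = mu + sd * anthro_noise_scale * rng.standard_normal()
        # redraw instead of clipping so the distribution stays smooth
        for _ in range(100):
            if lo <= v <= hi:
                break
            v = mu + sd * anthro_noise_scale * rng.standard_normal()
        values[name] = float(np.clip(v, lo, hi))
    return SubjectProfile(subject_id=subject_id, sex=sex, **values)


def _step_amplitudes(
    speed: float, mass: float, z_subj: float, z_step: float, eps: np.ndarray
) -> tuple[float, dict]:
    """Shared relative amplitude and per-structure peak amplitudes (BW)."""
    v_n = speed - 2.78
    m_n = (mass - 75.0) / 10.0
    amp_rel = 1.0 + SPEED_SLOPE * v_n + MASS_SLOPE * m_n + LATENT_SCALE * (
        0.8 * z_subj + 0.6 * z_step
    )
    amp_rel = float(np.clip(amp_rel, *AMP_REL_RANGE))
    amps = {
        s: STRUCTURE_PARAMS[s]["base"]
        * amp_rel
        * float(np.clip(1.0 + STRUCT_LATENT_SCALE * eps[i], *STRUCT_FACTOR_RANGE))
        for i, s in enumerate(STRUCTURES)
    }
    return amp_rel, amps


def generate_trial(
    subject: SubjectProfile,
    speed: float,
    config: GeneratorConfig,
    n_steps: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrialRecording:
    """Generate one treadmill trial for ``subject`` at ``speed`` m/s.

    ``n_steps`` overrides ``config.trial_duration`` with a step-count budget.
    Cadence rises and ground-contact time falls with speed; every stream is
    deterministic given the config seed.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if rng is None:
        rng = _subject_rng(config.seed, subject.subject_id, salt=int(round(speed * 1000)))

    imu_rate, grf_rate = config.imu_rate, config.grf_rate
    noise = config.noise_scale
    v_n = speed - 2.78
    cadence = 2.75 + 0.25 * v_n  # steps/s, both feet
    stride = 2.0 / cadence  # ipsilateral IC-to-IC interval, s
    stance0 = 0.30 - 0.045 * v_n  # s

    if n_steps is None:
        duration = config.trial_duration
        n_steps = int((duration - 0.8) / stride)
    else:
        duration = 0.8 + n_steps * stride
    if n_steps < 1:
        raise ValueError("trial too short to contain a single step")

    T_grf = int(round(duration * grf_rate))
    T_imu = int(round(duration * imu_rate))
    vgrf = np.zeros(T_grf)
    ssl = {s: np.zeros(T_grf) for s in STRUCTURES}
    foot_acc = np.zeros((3, T_imu))
    pelvis_acc = np.zeros((3, T_imu))
    foot_omega = np.zeros(T_imu)  # rad/s about sensor y
    pelvis_omega = np.zeros(T_imu)  # rad/s about sensor z

    z_subj = _subject_latent(config.seed, subject.subject_id)
    bw_n = subject.body_weight

    steps: list[StepTruth] = []
    t0 = 0.4  # settle-in margin before the first IC
    for k in range(n_steps):
        ic_time = t0 + k * stride + 0.003 * rng.standard_normal()
        stance = stance0 * (1.0 + 0.03 * rng.standard_normal())
        stance = float(np.clip(stance, 0.16, 0.45))
        z_step = float(rng.standard_normal())
        eps = rng.standard_normal(len(STRUCTURES))
        z_tau = float(rng.standard_normal())
        amp_rel, amps = _step_amplitudes(speed, subject.mass, z_subj, z_step, eps)
        imu_amp = 1.0 + config.coupling * (amp_rel - 1.0)
        tau = float(
            np.clip(
                TAU_SPEED_SLOPE * v_n + TAU_LATENT_SCALE * z_tau + 0.0, -0.2, 0.2
            )
        )

        ic_g = int(round(ic_time * grf_rate))
        n_st = int(round(stance * grf_rate))
        u = np.arange(n_st) / (n_st - 1)

        # vGRF: a contact offset (~0.12 BW, safely above the 50 N threshold)
        # plus an active raised-cosine peak and an early impact transient; the
        # offset pins the 50 N crossings to the constructed stance window so
        # measured stance and template stance coincide
        f_active = 2.5 * (1.0 + 0.12 * v_n) * amp_rel ** 0.5
        grf_curve = 0.12 + f_active * raised_cosine(u, 0.45)
        grf_curve += 0.45 * imu_amp * np.exp(-0.5 * ((u - 0.13) / 0.05) ** 2)
        vgrf[ic_g : ic_g + n_st] = bw_n * grf_curve

        # structure loads
        for i, s in enumerate(STRUCTURES):
            tau_s = float(np.clip(STRUCTURE_PARAMS[s]["tau0"] + tau, *TAU_RANGE))
            curve = amps[s] * raised_cosine(u, tau_s)
            if noise > 0:
                curve = curve + 0.03 * noise * rng.standard_normal(n_st)
            ssl[s][ic_g : ic_g + n_st] = bw_n * curve

        # foot IMU waveforms on the IMU clock
        ic_i = int(round(ic_time * imu_rate))
        to_i = int(round((ic_time + stance) * imu_rate))
        n_sti = to_i - ic_i
        peak_g = 2.0 * imu_amp + 0.6 * v_n
        # vertical channel: pre-contact dip, impact spike through +0.18 g at
        # IC, decay to a mid-stance plateau, push-off dip through -0.25 g at
        # TO, recovery in flight
        tau_i = float(np.clip(STRUCTURE_PARAMS["achilles"]["tau0"] + tau, *TAU_RANGE))
        key_t = np.array(
            [
                ic_i - 12,
                ic_i - 2,
                ic_i - 1,
                ic_i,
                ic_i + 3,
                ic_i + 10,
                ic_i + int(0.5 * n_sti),
                to_i - 8,
                to_i - 1,
                to_i,
                to_i + 2,
                to_i + 10,
            ],
            dtype=float,
        )
        key_v = np.array(
            [0.0, -0.40, -0.45, 0.30, peak_g, 0.8, 0.35, 0.30, -0.10, -0.40, -0.55, 0.0]
        )
        seg = slice(max(ic_i - 12, 0), min(to_i + 11, T_imu))
        idx = np.arange(seg.start, seg.stop, dtype=float)
        foot_acc[2, seg] = np.interp(idx, key_t, key_v, left=0.0, right=0.0) * G

        # anterior-posterior channel: bell at the time-to-peak fraction so the
        # network can read the SSL timing from the foot sensor
        centre = ic_i + tau_i * n_sti
        tt = np.arange(T_imu)
        bell = 1.2 * imu_amp * np.exp(-0.5 * ((tt - centre) / (0.18 * n_sti)) ** 2)
        foot_acc[0] += bell * G
        # foot angular velocity: stance dip at tau, swing bell between steps
        foot_omega -= (2.5 + 1.0 * (imu_amp - 1.0)) * np.exp(
            -0.5 * ((tt - centre) / (0.22 * n_sti)) ** 2
        )
        swing_c = to_i + 0.5 * (stride * imu_rate - n_sti)
        foot_omega += (7.0 + 1.5 * v_n) * np.exp(
            -0.5 * ((tt - swing_c) / (0.18 * stride * imu_rate)) ** 2
        )

        steps.append(
            StepTruth(
                index=k,
                ic_grf=ic_g,  # provisional; replaced by the 50 N scan below
                to_grf=ic_g + n_st,
                ic_imu=ic_i,
                amp_rel=amp_rel,
                amps=amps,
                tau=tau,
                stance_duration=stance,
                has_next=k < n_steps - 1,
                template_start=ic_g,
                template_len=n_st,
            )
        )

    # pelvis: smooth oscillation at cadence, amplitude tied to the latents
    t_imu = np.arange(T_imu) / imu_rate
    z_mix = 1.0 + config.coupling * (
        LATENT_SCALE * 0.8 * z_subj + SPEED_SLOPE * v_n + MASS_SLOPE * (subject.mass - 75.0) / 10.0
    )
    phase = 2 * np.pi * cadence * (t_imu - t0)
    pelvis_acc[2] = 0.45 * z_mix * G * np.sin(phase)
    pelvis_acc[0] = 0.20 * z_mix * G * np.sin(phase + 0.8)
    pelvis_acc[1] = 0.08 * G * np.sin(0.5 * phase + 0.3)
    pelvis_omega[:] = (1.2 + 0.3 * (z_mix - 1.0)) * np.sin(phase + 1.9)
    foot_acc[1] += 0.25 * G * np.sin(phase + 2.4)

    # additive sensor noise
    if noise > 0:
        foot_acc += 0.03 * noise * G * rng.standard_normal(foot_acc.shape)
        pelvis_acc += 0.03 * noise * G * rng.standard_normal(pelvis_acc.shape)
        vgrf += 5.0 * noise * rng.standard_normal(T_grf)
    vgrf = np.clip(vgrf, 0.0, None)
    for s in STRUCTURES:
        ssl[s] = np.clip(ssl[s], 0.0, None)

    # orientations by integrating the scripted angular velocities
    foot_quat = _quat_from_axis_angle(np.cumsum(foot_omega) / imu_rate, axis=1)
    pelvis_quat = _quat_from_axis_angle(np.cumsum(pelvis_omega) / imu_rate, axis=2)
    if noise > 0:
        foot_quat += 0.002 * noise * rng.standard_normal(foot_quat.shape)
        pelvis_quat += 0.002 * noise * rng.standard_normal(pelvis_quat.shape)
    foot_quat /= np.linalg.norm(foot_quat, axis=0, keepdims=True)
    pelvis_quat /= np.linalg.norm(pelvis_quat, axis=0, keepdims=True)

    trial = TrialRecording(
        subject_id=subject.subject_id,
        speed=speed,
        pelvis_acc=pelvis_acc,
        pelvis_quat=pelvis_quat,
        foot_acc=foot_acc,
        foot_quat=foot_quat,
        vgrf=vgrf,
        ssl_truth=ssl,
        imu_rate=imu_rate,
        grf_rate=grf_rate,
        lag_samples=config.imu_lag_samples,
        steps=steps,
    )
    if config.corrupt_fraction > 0:
        trial = inject_artifacts(trial, config, rng=rng)
    _refresh_true_events(trial)
    if config.imu_lag_samples:
        _apply_lag(trial, config.imu_lag_samples)
    return trial


def _quat_from_axis_angle(theta: np.ndarray, axis: int) -> np.ndarray:
    """Scalar-first unit quaternions for rotations of theta about one axis."""
    q = np.zeros((4, theta.size))
    q[0] = np.cos(theta / 2.0)
    q[1 + axis] = np.sin(theta / 2.0)
    return q


def _apply_lag(trial: TrialRecording, lag: int) -> None:
    """Shift the IMU streams ``lag`` samples later relative to the vGRF clock."""
    for arr in (trial.pelvis_acc, trial.pelvis_quat, trial.foot_acc, trial.foot_quat):
        arr[:] = np.roll(arr, lag, axis=1)


def _refresh_true_events(trial: TrialRecording) -> None:
    """Recompute true IC/TO from the final vGRF via the 50 N crossing rule."""
    above = trial.vgrf >= 50.0
    d = np.diff(above.astype(int))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, len(above))
    intervals = [(s, e) for s, e in zip(starts, ends) if e - s >= 0.01 * trial.grf_rate]
    for step in trial.steps:
        # keep the interval overlapping the constructed stance
        best = None
        for s, e in intervals:
            if s < step.to_grf and e > step.ic_grf:
                if best is None or (e - s) > (best[1] - best[0]):
                    best = (s, e)
        if best is not None:
            step.ic_grf, step.to_grf = best
            step.stance_duration = (best[1] - best[0]) / trial.grf_rate
            step.ic_imu = int(round(best[0] / trial.grf_rate * trial.imu_rate))


def inject_artifacts(
    trial: TrialRecording,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> TrialRecording:
    """Corrupt a random fraction of steps, cycling through the artifact kinds.

    dropout: a >=20-sample zeroed window in the foot vertical acceleration;
    stance_inflation: the 50 N region is extended past 0.5 s; ssl_out_of_range:
    the Achilles load is rescaled to a 20 BW peak.  Truth labels are stored on
    the step records.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    if config.corrupt_fraction <= 0:
        return trial
    n_hit = 0
    for step in trial.steps:
        if rng.random() >= config.corrupt_fraction:
            continue
        kind = ARTIFACT_KINDS[n_hit % len(ARTIFACT_KINDS)]
        n_hit += 1
        step.corrupted = True
        step.artifact = kind
        if kind == "dropout":
            a = step.ic_imu + 6
            trial.foot_acc[2, a : a + 25] = 0.0
        elif kind == "stance_inflation":
            # bridge from mid-stance so the >= 50 N region stays contiguous
            # and the true stance exceeds the 0.5 s acceptance limit
            ext = int(0.30 * trial.grf_rate)
            mid = step.ic_grf + step.template_len // 2
            trial.vgrf[mid : step.to_grf + ext] = 300.0
        else:  # ssl_out_of_range
            seg = slice(step.ic_grf, step.to_grf)
            amp = step.amps["achilles"]
            scale = 20.0 / max(amp, 1e-6)
            trial.ssl_truth["achilles"][seg] *= scale
    return trial


def generate_cohort(
    config: GeneratorConfig, n_steps_per_trial: int | None = None
) -> tuple[list[SubjectProfile], list[TrialRecording]]:
    """Generate all subjects and one trial per subject x speed."""
    rng = np.random.default_rng(config.seed)
    n_male = int(round(config.sex_ratio * config.n_subjects))
    subjects = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        forced_ratio = 1.0 if i < n_male else 0.0
        subjects.append(
            generate_subject(rng, sex_ratio=forced_ratio, subject_id=sid)
        )
    trials = [
        generate_trial(sub, speed, config, n_steps=n_steps_per_trial)
        for sub in subjects
        for speed in config.speeds
    ]
    return subjects, trials


# ---------------------------------------------------------------------------
# dataset container: one directory per cohort, plain CSV + JSON manifest
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip

_IMU_COLUMNS = (
    ["pelvis_acc_x", "pelvis_acc_y", "pelvis_acc_z"]
    + ["pelvis_quat_w", "pelvis_quat_x", "pelvis_quat_y", "pelvis_quat_z"]
    + ["foot_acc_x", "foot_acc_y", "foot_acc_z"]
    + ["foot_quat_w", "foot_quat_x", "foot_quat_y", "foot_quat_z"]
)


def _trial_stem(trial: TrialRecording) -> str:
    return f"trial_{trial.subject_id}_{trial.speed:.2f}"


def write_dataset(
    trials: Sequence[TrialRecording], subjects: Sequence[SubjectProfile], path: str | Path
) -> Path:
    """Write a cohort directory: subjects.csv, per-trial CSVs, manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "mass_kg": s.mass,
                "sex": s.sex,
                "age_yr": s.age,
                "height_cm": s.height,
                "shoe_length_cm": s.shoe_length,
                "sole_thickness_cm": s.sole_thickness,
            }
            for s in subjects
        ]
    ).to_csv(path / "subjects.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {"trials": [], "version": 1}
    for trial in trials:
        stem = _trial_stem(trial)
        imu = np.vstack(
            [trial.pelvis_acc, trial.pelvis_quat, trial.foot_acc, trial.foot_quat]
        ).T
        pd.DataFrame(imu, columns=_IMU_COLUMNS).to_csv(
            path / f"{stem}_imu.csv", index=False, float_format=_FLOAT_FMT
        )
        grf = np.vstack([trial.vgrf] + [trial.ssl_truth[s] for s in STRUCTURES]).T
        pd.DataFrame(grf, columns=["vgrf"] + [f"ssl_{s}" for s in STRUCTURES]).to_csv(
            path / f"{stem}_grf.csv", index=False, float_format=_FLOAT_FMT
        )
        with open(path / f"{stem}_steps.json", "w") as fh:
            json.dump(
                [
                    {
                        "index": st.index,
                        "ic_grf": int(st.ic_grf),
                        "to_grf": int(st.to_grf),
                        "ic_imu": int(st.ic_imu),
                        "amp_rel": st.amp_rel,
                        "amps": st.amps,
                        "tau": st.tau,
                        "stance_duration": st.stance_duration,
                        "has_next": st.has_next,
                        "template_start": int(st.template_start),
                        "template_len": int(st.template_len),
                        "corrupted": st.corrupted,
                        "artifact": st.artifact,
                    }
                    for st in trial.steps
                ],
                fh,
            )
        manifest["trials"].append(
            {
                "stem": stem,
                "subject_id": trial.subject_id,
                "speed": trial.speed,
                "imu_rate": trial.imu_rate,
                "grf_rate": trial.grf_rate,
                "lag_samples": trial.lag_samples,
            }
        )
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


class DatasetError(RuntimeError):
    """Raised when a cohort directory is missing files or violates the schema."""


def read_dataset(path: str | Path) -> tuple[list[TrialRecording], list[SubjectProfile]]:
    """Load a cohort directory written by :func:`write_dataset` (lossless)."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise DatasetError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    subj_df = pd.read_csv(path / "subjects.csv", float_precision="round_trip")
    subjects = []
    for _, row in subj_df.iterrows():
        if row["mass_kg"] <= 0:
            raise DatasetError(
                f"subject {row['subject_id']}: mass must be positive, got {row['mass_kg']}"
            )
        subjects.append(
            SubjectProfile(
                subject_id=str(row["subject_id"]),
                mass=float(row["mass_kg"]),
                sex=str(row["sex"]),
                age=float(row["age_yr"]),
                height=float(row["height_cm"]),
                shoe_length=float(row["shoe_length_cm"]),
                sole_thickness=float(row["sole_thickness_cm"]),
            )
        )

    trials = []
    for entry in manifest["trials"]:
        stem = entry["stem"]
        imu_path = path / f"{stem}_imu.csv"
        grf_path = path / f"{stem}_grf.csv"
        for p in (imu_path, grf_path, path / f"{stem}_steps.json"):
            if not p.exists():
                raise DatasetError(f"manifest references missing file: {p}")
        imu = pd.read_csv(imu_path, float_precision="round_trip")[_IMU_COLUMNS].to_numpy().T
        grf = pd.read_csv(grf_path, float_precision="round_trip")
        steps = [
            StepTruth(
                index=d["index"],
                ic_grf=d["ic_grf"],
                to_grf=d["to_grf"],
                ic_imu=d["ic_imu"],
                amp_rel=d["amp_rel"],
                amps=d["amps"],
                tau=d["tau"],
                stance_duration=d["stance_duration"],
                has_next=d["has_next"],
                template_start=d["template_start"],
                template_len=d["template_len"],
                corrupted=d["corrupted"],
                artifact=d["artifact"],
            )
            for d in json.loads((path / f"{stem}_steps.json").read_text())
        ]
        trial = TrialRecording(
            subject_id=entry["subject_id"],
            speed=entry["speed"],
            pelvis_acc=imu[0:3],
            pelvis_quat=imu[3:7],
            foot_acc=imu[7:10],
            foot_quat=imu[10:14],
            vgrf=grf["vgrf"].to_numpy(),
            ssl_truth={s: grf[f"ssl_{s}"].to_numpy() for s in STRUCTURES},
            imu_rate=entry["imu_rate"],
            grf_rate=entry["grf_rate"],
            lag_samples=entry["lag_samples"],
            steps=steps,
        )
        try:
            trial.validate()
        except ValueError as exc:
            raise DatasetError(f"{stem}: {exc}") from exc
        trials.append(trial)
    return trials, subjects
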