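"""Tabular feature battery for the feedforward and hybrid models.

Six subject features (mass, sex, age, height, shoe length, sole thickness)
plus a biomechanical block computed on the native-rate stance segments:
stance and step duration, then per acceleration channel the impulse, maximum,
mean, RMS, sample entropy and skewness (6 features), and per angular-velocity
channel the maximum and mean (2 features).  Dual-IMU steps yield
2 + 6*6 + 2*6 = 50 biomechanical features; a single sensor yields
2 + 6*3 + 2*3 = 26.  Feature order is fixed and exposed through the returned
name list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .loads import StepSample
from .synth import SubjectProfile

SENSOR_SETS = ("dual", "pelvis", "foot")
ACC_CHANNEL_NAMES = ("x", "y", "z")
SUBJECT_FEATURE_NAMES = (
    "mass_kg",
    "sex_male",
    "age_yr",
    "height_cm",
    "shoe_length_cm",
    "sole_thickness_cm",
)

SAMPEN_M = 2
SAMPEN_R_FACTOR = 0.2  # r = 0.2 * SD of the segment
SAMPEN_SENTINEL = 0.0  # returned (with a flag) for degenerate segments


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list
    flagged: bool = False  # True when a degenerate statistic hit its sentinel


def subject_features(profile: SubjectProfile) -> np.ndarray:
    """[mass, sex (male=1, female=0), age, height, shoe_length, sole_thickness]."""
    return np.array(
        [
            profile.mass,
            1.0 if profile.sex == "male" else 0.0,
            profile.age,
            profile.height,
            profile.shoe_length,
            profile.sole_thickness,
        ]
    )


def acceleration_impulse(channel: np.ndarray, rate: float) -> float:
    """Rectangular time-integral of a stance acceleration channel (m/s)."""
    y = np.asarray(channel, dtype=float)
    if y.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(y) / rate)


def sample_entropy(x: np.ndarray, m: int = SAMPEN_M, r: float | None = None) -> float:
    """Sample entropy with Chebyshev distance; r defaults to 0.2 * SD.

    Vectorized over all template pairs.  Returns NaN when no template pair
    matches at length m (undefined) and raises for zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError("segment too short for sample entropy")
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("zero-variance segment: sample entropy undefined")
    if r is None:
        r = SAMPEN_R_FACTOR * sd

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # pairwise Chebyshev distances between distinct templates
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        iu = np.triu_indices(templ.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def channel_statistics(channel: np.ndarray, kind: str, rate: float) -> tuple[np.ndarray, bool]:
    """Statistics for one stance-segment channel.

    acceleration -> [impulse, max, mean, rms, sample_entropy, skewness];
    angular_velocity -> [max, mean].  Degenerate (zero-variance) segments get
    sentinel entropy/skewness values and raise the step flag.
    """
    y = np.asarray(channel, dtype=float)
    flagged = False
    if kind == "angular_velocity":
        return np.array([np.max(y), np.mean(y)]), flagged
    if kind != "acceleration":
        raise ValueError(f"unknown channel kind {kind!r}")
    rms = float(np.sqrt(np.mean(y**2)))
    if np.std(y) == 0:
        ent, skew = SAMPEN_SENTINEL, 0.0
        flagged = True
    else:
        ent = sample_entropy(y)
        if not np.isfinite(ent):
            ent, flagged = SAMPEN_SENTINEL, True
        skew = float(stats.skew(y, bias=True))
    return (
        np.array([acceleration_impulse(y, rate), np.max(y), np.mean(y), rms, ent, skew]),
        flagged,
    )


def _sensor_channel_indices(sensors: str) -> list[int]:
    if sensors == "dual":
        return [0, 1, 2, 3, 4, 5]  # pelvis xyz then foot xyz within acc/gyro blocks
    if sensors == "pelvis":
        return [0, 1, 2]
    if sensors == "foot":
        return [3, 4, 5]
    raise ValueError(f"sensors must be one of {SENSOR_SETS}, got {sensors!r}")


def assemble_features(
    step: StepSample, profile: SubjectProfile, sensors: str = "dual"
) -> FeatureVector:
    """Full tabular vector: 6 subject features + 50 (dual) / 26 (single)
    biomechanical features, in a fixed documented order.
    """
    idx = _sensor_channel_indices(sensors)
    sensor_names = (
        ["pelvis_x", "pelvis_y", "pelvis_z", "foot_x", "foot_y", "foot_z"]
        if sensors == "dual"
        else [f"{sensors}_{c}" for c in ACC_CHANNEL_NAMES]
    )
    values = list(subject_features(profile))
    names = list(SUBJECT_FEATURE_NAMES)
    values += [step.stance_duration, step.step_duration]
    names += ["stance_duration_s", "step_duration_s"]
    flagged = False
    for ci, cname in zip(idx, sensor_names):
        st, fl = channel_statistics(step.acc_filt_segments[ci], "acceleration", step.imu_rate)
        flagged |= fl
        values += list(st)
        names += [f"acc_{cname}_{s}" for s in ("impulse", "max", "mean", "rms", "sampen", "skew")]
    for ci, cname in zip(idx, sensor_names):
        st, _ = channel_statistics(step.gyro_segments[ci], "angular_velocity", step.imu_rate)
        values += list(st)
        names += [f"gyro_{cname}_{s}" for s in ("max", "mean")]
    vec = np.array(values, dtype=float)
    expected = 6 + (50 if sensors == "dual" else 26)
    if vec.size != expected:
        raise RuntimeError(f"feature assembly produced {vec.size} values, expected {expected}")
    return FeatureVector(values=vec, names=names, flagged=flagged)


def feature_matrix(
    steps: list[StepSample], profiles: dict, sensors: str = "dual"
) -> tuple[np.ndarray, list]:
    """Stack accepted steps into an (n_steps, n_features) matrix."""
    rows, names = [], None
    for st in steps:
        fv = assemble_features(st, profiles[st.subject_id], sensors)
        rows.append(fv.values)
        names = fv.names
    return np.array(rows), names or []
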