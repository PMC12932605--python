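"""Ground-truth load processing: filtering, normalization, step segmentation,
matching against IMU-detected events, exclusion rules, time normalization and
the three per-step load characteristics (peak, impulse, average loading rate).

Conventions: stance intervals are half-open ``[IC, TO)`` with 0-based sample
indices at the vGRF rate; stance duration = (TO - IC) / rate; step duration =
half the ipsilateral IC-to-IC interval (the contralateral step time under a
symmetric gait).  All load curves are expressed in body weights (BW) and
time-normalized to exactly 100 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import STRUCTURES

SSL_FILTER_ORDER = 5
SSL_FILTER_CUTOFF_HZ = 20.0
GRF_STEP_THRESHOLD_N = 50.0
CHATTER_S = 0.010  # sub-10 ms threshold crossings are discarded as chatter

N_POINTS = 100  # time-normalized curve length

STANCE_RANGE_S = (0.15, 0.5)
STEP_RANGE_S = (0.21, 0.6)
SSL_PEAK_RANGE_BW = (0.5, 15.0)  # "expected range" for load exclusion
SSL_NEGATIVE_FLOOR_BW = -0.01
DROPOUT_RUN = 20  # >= this many consecutive identical samples flags dropout
MATCH_TOLERANCE_S = 0.050

#: order in which exclusion rules are applied; the first failure is reported
EXCLUSION_ORDER = ("stance_duration", "step_duration", "corruption", "ssl_range")


@dataclass
class CharacteristicConfig:
    """Loading-rate interval definition for one structure."""

    p_lower: float
    p_upper: float
    interval_kind: str  # "ic_to_peak" | "ic_to_to"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_lower < self.p_upper <= 1.0:
            raise ValueError("need 0 <= p_lower < p_upper <= 1")
        if self.interval_kind not in ("ic_to_peak", "ic_to_to"):
            raise ValueError(f"unknown interval_kind {self.interval_kind!r}")


#: loading-rate windows: 20-80% of IC-to-peak for the tendon and ankle loads,
#: 10-40% of IC-to-TO for the knee contact force
DEFAULT_CHARACTERISTIC_CONFIGS = {
    "achilles": CharacteristicConfig(0.20, 0.80, "ic_to_peak"),
    "patellar": CharacteristicConfig(0.20, 0.80, "ic_to_peak"),
    "ankle": CharacteristicConfig(0.20, 0.80, "ic_to_peak"),
    "knee": CharacteristicConfig(0.10, 0.40, "ic_to_to"),
}


@dataclass
class StepSample:
    """One candidate right-foot stance with everything downstream needs."""

    subject_id: str
    trial_id: str
    speed: float
    stance_duration: float  # s
    step_duration: float  # s
    imu_matrix: np.ndarray  # (12, 100): pelvis acc xyz, pelvis gyro xyz, foot acc xyz, foot gyro xyz
    ssl_curves: np.ndarray  # (4, 100) BW, ordered as synth.STRUCTURES
    acc_raw_segments: np.ndarray  # (6, n) unfiltered stance acceleration, native rate
    acc_filt_segments: np.ndarray  # (6, n) filtered, native rate (m/s^2)
    gyro_segments: np.ndarray  # (6, m) angular velocity, native rate (rad/s)
    imu_rate: float
    accepted: bool = True
    exclusion_reason: str | None = None
    truth_index: int | None = None  # generator step index, when known

    @property
    def is_right(self) -> bool:
        # marker-based side detection is out of scope; synthetic steps are all
        # right-foot steps by construction
        return True


@dataclass
class SslCharacteristics:
    structure: str
    peak: float  # BW
    impulse: float  # BW*s
    loading_rate: float | None  # BW/s; None when the interval degenerates


def filter_and_normalize_ssl(ssl_n: np.ndarray, rate: float, body_weight: float) -> np.ndarray:
    """Zero-phase 5th-order 20 Hz low-pass, then divide by body weight (N).

    Small filter-induced negative excursions (> -0.01 BW) are clamped to 0.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    if rate <= 2 * SSL_FILTER_CUTOFF_HZ:
        raise ValueError(f"rate {rate} Hz too low for a {SSL_FILTER_CUTOFF_HZ} Hz cutoff")
    sos = signal.butter(SSL_FILTER_ORDER, SSL_FILTER_CUTOFF_HZ, btype="low", fs=rate, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(ssl_n, dtype=float)) / body_weight
    tiny = (out < 0) & (out > SSL_NEGATIVE_FLOOR_BW)
    out[tiny] = 0.0
    return out


def segment_steps_grf(vgrf: np.ndarray, rate: float = 1200.0) -> list[tuple[int, int]]:
    """Maximal half-open intervals where vGRF >= 50 N, chatter discarded."""
    v = np.asarray(vgrf, dtype=float)
    if v.size == 0:
        return []
    above = v >= GRF_STEP_THRESHOLD_N
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(v.size)
    min_len = CHATTER_S * rate
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def match_steps(
    grf_ic_times: np.ndarray,
    acc_ic_times: np.ndarray,
    tolerance_s: float = MATCH_TOLERANCE_S,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy one-to-one nearest-IC matching of GRF steps to IMU-detected steps.

    Returns (matches, unmatched) where matches are index pairs
    (grf_step_idx, acc_event_idx) and unmatched lists GRF step indices with no
    acceleration event within the tolerance.
    """
    grf_t = np.asarray(grf_ic_times, dtype=float)
    acc_t = np.asarray(acc_ic_times, dtype=float)
    pairs = []
    for i, t in enumerate(grf_t):
        if acc_t.size:
            offs = np.abs(acc_t - t)
            pairs.append((float(np.min(offs)), i, int(np.argmin(offs))))
    pairs.sort()
    used_grf: set[int] = set()
    used_acc: set[int] = set()
    matches = []
    for off, i, j in pairs:
        if off > tolerance_s or i in used_grf or j in used_acc:
            continue
        matches.append((i, j))
        used_grf.add(i)
        used_acc.add(j)
    matches.sort()
    unmatched = [i for i in range(grf_t.size) if i not in used_grf]
    return matches, unmatched


def _has_dropout(acc_segments: np.ndarray) -> bool:
    for ch in np.atleast_2d(acc_segments):
        if ch.size < DROPOUT_RUN:
            continue
        run = 1
        for a, b in zip(ch[:-1], ch[1:]):
            run = run + 1 if a == b else 1
            if run >= DROPOUT_RUN:
                return True
    return False


def apply_exclusions(step: StepSample) -> StepSample:
    """Flag a step against the acceptance rules; first failing rule reported.

    Order: stance duration in [0.15, 0.5] s, step duration in [0.21, 0.6] s,
    signal dropout (>= 20 consecutive identical raw acceleration samples),
    load out of expected range (peak outside (0.5, 15] BW or any value below
    -0.01 BW).  Idempotent.
    """
    reason = None
    if not STANCE_RANGE_S[0] <= step.stance_duration <= STANCE_RANGE_S[1]:
        reason = "stance_duration"
    elif not STEP_RANGE_S[0] <= step.step_duration <= STEP_RANGE_S[1]:
        reason = "step_duration"
    elif _has_dropout(step.acc_raw_segments):
        reason = "corruption"
    else:
        peaks = step.ssl_curves.max(axis=1)
        if (
            np.any(peaks <= SSL_PEAK_RANGE_BW[0])
            or np.any(peaks > SSL_PEAK_RANGE_BW[1])
            or np.any(step.ssl_curves < SSL_NEGATIVE_FLOOR_BW)
        ):
            reason = "ssl_range"
    step.accepted = reason is None
    step.exclusion_reason = reason
    return step


def time_normalize(curve: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Linear interpolation onto n_points equally spaced samples over [0, T-1]."""
    y = np.asarray(curve, dtype=float)
    if y.ndim == 1:
        if y.size < 2:
            raise ValueError("need at least 2 samples to time-normalize")
        x_new = np.linspace(0.0, y.size - 1, n_points)
        return np.interp(x_new, np.arange(y.size), y)
    return np.vstack([time_normalize(row, n_points) for row in y])


def peak(curve: np.ndarray) -> tuple[float, int]:
    """Maximum of the stance-phase load and its frame (earliest tie wins)."""
    y = np.asarray(curve, dtype=float)
    idx = int(np.argmax(y))
    return float(y[idx]), idx


def impulse(curve: np.ndarray, stance_duration: float) -> float:
    """Rectangular integral over stance in BW*s.

    The 100-frame sum (BW*frame) is divided by the effective sampling rate of
    the normalized curve, ``100 / stance_duration`` frames per second.
    """
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    y = np.asarray(curve, dtype=float)
    return float(np.sum(y) / (y.size / stance_duration))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def loading_rate(
    curve: np.ndarray, stance_duration: float, cfg: CharacteristicConfig
) -> float | None:
    """Average slope of the load-time curve over the configured interval.

    The interval spans IC to the curve's peak frame (``ic_to_peak``) or IC to
    TO (``ic_to_to``); the p% frames are rounded half-away-from-zero and the
    frame difference is converted to seconds with the effective sampling rate.
    Returns None when the rounded endpoints coincide (degenerate early peak).
    """
    y = np.asarray(curve, dtype=float)
    if stance_duration <= 0:
        raise ValueError("stance_duration must be positive")
    if cfg.interval_kind == "ic_to_peak":
        end = int(np.argmax(y))
    else:
        end = y.size - 1
    f_lower = _round_half_away(cfg.p_lower * end)
    f_upper = _round_half_away(cfg.p_upper * end)
    if f_upper == f_lower:
        return None
    eff_rate = y.size / stance_duration  # frames per second
    return float((y[f_upper] - y[f_lower]) / ((f_upper - f_lower) / eff_rate))


def characteristics(
    curve: np.ndarray,
    stance_duration: float,
    structure: str,
    cfg: CharacteristicConfig | None = None,
) -> SslCharacteristics:
    """Peak, impulse and average loading rate for one normalized curve."""
    if cfg is None:
        cfg = DEFAULT_CHARACTERISTIC_CONFIGS[structure]
    pk, _ = peak(curve)
    return SslCharacteristics(
        structure=structure,
        peak=pk,
        impulse=impulse(curve, stance_duration),
        loading_rate=loading_rate(curve, stance_duration, cfg),
    )


# ---------------------------------------------------------------------------
# trial -> step samples
# ---------------------------------------------------------------------------


def _ic_train(indices, n: int, rate: float, width_s: float = 0.02) -> np.ndarray:
    """Smoothed indicator train of event indices (for lag estimation)."""
    train = np.zeros(n)
    for i in indices:
        if 0 <= i < n:
            train[i] = 1.0
    half = max(int(round(3 * width_s * rate)), 1)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / (width_s * rate)) ** 2)
    return np.convolve(train, k, mode="same")


def build_step_samples(trial, subject, estimate_lag: bool = True) -> list[StepSample]:
    """Run a trial through the stance pipeline and emit flagged StepSamples.

    Stages: 40 Hz zero-phase acceleration filtering; angular velocity from
    quaternions; IC/TO detection on the foot's vertical acceleration (g);
    20 Hz filtering + BW normalization of the four load signals; 50 N vGRF
    step segmentation; cross-correlation lag estimation between the vGRF and
    the foot's vertical acceleration; greedy step matching; per-step slicing,
    time normalization and exclusion flagging.  The final GRF step of a trial
    has no successor IC and is dropped with reason "incomplete".
    """
    from . import imu as imu_mod

    imu_rate, grf_rate = trial.imu_rate, trial.grf_rate
    foot_filt = imu_mod.filter_acceleration(trial.foot_acc, imu_rate)
    pelvis_filt = imu_mod.filter_acceleration(trial.pelvis_acc, imu_rate)
    foot_gyro = imu_mod.angular_velocity(trial.foot_quat, 1.0 / imu_rate).omega
    pelvis_gyro = imu_mod.angular_velocity(trial.pelvis_quat, 1.0 / imu_rate).omega

    vert_g = foot_filt[2] / 9.81
    events = imu_mod.detect_gait_events(vert_g, imu_rate)

    bw = subject.body_weight
    ssl_bw = {
        s: filter_and_normalize_ssl(trial.ssl_truth[s], grf_rate, bw) for s in STRUCTURES
    }
    grf_steps = segment_steps_grf(trial.vgrf, grf_rate)

    # lag of the IMU clock relative to the vGRF clock, in IMU samples; the
    # correlation runs on smoothed initial-contact indicator trains so the
    # differing waveform shapes of the two modalities cannot bias the peak
    if estimate_lag and len(events.ic_indices) >= 2 and len(grf_steps) >= 2:
        n = foot_filt.shape[1]
        grf_ics_imu = [int(round(s / grf_rate * imu_rate)) for s, _ in grf_steps]
        ref = _ic_train(grf_ics_imu, n, imu_rate)
        tgt = _ic_train(events.ic_indices, n, imu_rate)
        lag = imu_mod.synchronize(ref, tgt, max_lag=min(int(imu_rate), n // 2 - 1))
    else:
        lag = trial.lag_samples

    grf_ic_times = np.array([s / grf_rate for s, _ in grf_steps])
    acc_ic_times = events.ic_indices / imu_rate - lag / imu_rate
    matches, _unmatched = match_steps(grf_ic_times, acc_ic_times)
    matched_grf = {i for i, _ in matches}

    truth_by_ic = {}
    for st in getattr(trial, "steps", []):
        truth_by_ic[st.ic_grf] = st

    samples = []
    trial_id = f"{trial.subject_id}_{trial.speed:.2f}"
    for i, (ic, to) in enumerate(grf_steps):
        stance = (to - ic) / grf_rate
        if i + 1 < len(grf_steps):
            step_dur = (grf_steps[i + 1][0] - ic) / (2.0 * grf_rate)
        else:
            step_dur = np.nan

        ic_i = int(round(ic / grf_rate * imu_rate)) + lag
        to_i = max(int(round(to / grf_rate * imu_rate)) + lag, ic_i + 2)
        to_i = min(to_i, foot_filt.shape[1])
        sl = slice(ic_i, to_i)
        gyro_hi = min(to_i, foot_gyro.shape[1])
        acc_raw = np.vstack([trial.pelvis_acc[:, sl], trial.foot_acc[:, sl]])
        acc_filt = np.vstack([pelvis_filt[:, sl], foot_filt[:, sl]])
        gyro = np.vstack(
            [pelvis_gyro[:, ic_i:gyro_hi], foot_gyro[:, ic_i:gyro_hi]]
        )
        imu_matrix = np.vstack(
            [
                time_normalize(pelvis_filt[0:3, sl]),
                time_normalize(pelvis_gyro[:, ic_i:gyro_hi]),
                time_normalize(foot_filt[0:3, sl]),
                time_normalize(foot_gyro[:, ic_i:gyro_hi]),
            ]
        )
        curves = np.vstack([time_normalize(ssl_bw[s][ic:to]) for s in STRUCTURES])
        truth = truth_by_ic.get(ic)
        step = StepSample(
            subject_id=trial.subject_id,
            trial_id=trial_id,
            speed=trial.speed,
            stance_duration=stance,
            step_duration=step_dur,
            imu_matrix=imu_matrix,
            ssl_curves=curves,
            acc_raw_segments=acc_raw,
            acc_filt_segments=acc_filt,
            gyro_segments=gyro,
            imu_rate=imu_rate,
            truth_index=truth.index if truth is not None else None,
        )
        if i not in matched_grf:
            step.accepted = False
            step.exclusion_reason = "unmatched"
        elif not np.isfinite(step_dur):
            step.accepted = False
            step.exclusion_reason = "incomplete"
        else:
            apply_exclusions(step)
        samples.append(step)
    return samples


def steps_table(samples: list[StepSample]) -> "pd.DataFrame":
    """One row per step x structure with durations, characteristics and flags."""
    import pandas as pd

    rows = []
    for st in samples:
        for k, s in enumerate(STRUCTURES):
            row = {
                "subject_id": st.subject_id,
                "trial_id": st.trial_id,
                "speed": st.speed,
                "structure": s,
                "stance_duration_s": st.stance_duration,
                "step_duration_s": st.step_duration,
                "accepted": st.accepted,
                "exclusion_reason": st.exclusion_reason or "",
            }
            if st.accepted:
                ch = characteristics(st.ssl_curves[k], st.stance_duration, s)
                row.update(
                    peak_bw=ch.peak,
                    impulse_bws=ch.impulse,
                    loading_rate_bws=ch.loading_rate,
                )
            rows.append(row)
    return pd.DataFrame(rows)
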