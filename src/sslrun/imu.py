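"""Deterministic IMU signal processing.

Angular velocity from quaternion streams, zero-phase acceleration filtering,
threshold-based gait-event detection on the foot's vertical acceleration, and
cross-correlation stream synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import G

IC_THRESHOLD_G = 0.18
TO_THRESHOLD_G = -0.25
TO_THRESHOLD_STEP_G = 0.05  # relaxation step toward zero
TO_THRESHOLD_CEIL_G = -0.05
# windowed "decrease before / increase after" constraints around an event:
# within PRE_WINDOW samples before the crossing the signal must have fallen by
# at least EXCURSION_G (maximum attained before the minimum), and within
# POST_WINDOW samples after an IC it must rise by at least EXCURSION_G.
PRE_WINDOW = 12  # samples (~50 ms at 240 Hz)
POST_WINDOW = 8
EXCURSION_G = 0.10
REFRACTORY_S = 0.1  # minimum spacing between accepted ICs

FILTER_ORDER = 5
FILTER_CUTOFF_HZ = 40.0


@dataclass
class AngularVelocitySeries:
    """Angular velocity in the sensor frame, forward-differenced.

    ``omega`` has length T-1 relative to the quaternion stream of length T
    and is timestamped at the left sample of each difference.
    """

    omega: np.ndarray  # (3, T-1) rad/s
    dt: float  # s


@dataclass
class GaitEventList:
    ic_indices: np.ndarray  # sample indices on the IMU clock
    to_indices: np.ndarray
    to_thresholds: np.ndarray  # threshold (g) at which each TO was found


def _quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-first quaternion arrays of shape (4, N)."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def angular_velocity(quat: np.ndarray, dt: float) -> AngularVelocitySeries:
    """Angular velocity omega(t) = (2/dt) * vec[ conj(q(t)) * q(t+dt) ].

    The increment quaternion's sign is canonicalized (scalar part >= 0) so the
    quaternion double cover (q and -q encode one orientation) cannot inject
    spurious half-turn rates.
    """
    quat = np.asarray(quat, dtype=float)
    if quat.ndim != 2 or quat.shape[0] != 4 or quat.shape[1] < 2:
        raise ValueError("quat must have shape (4, T) with T >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    norms = np.linalg.norm(quat, axis=0)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm quaternion row")
    if np.max(np.abs(norms - 1.0)) > 1e-3:
        raise ValueError("quaternion stream is not unit-norm (tolerance 1e-3)")
    quat = quat / norms

    q_t = quat[:, :-1]
    q_next = quat[:, 1:]
    conj = q_t * np.array([1.0, -1.0, -1.0, -1.0])[:, None]
    inc = _quat_multiply(conj, q_next)
    sign = np.where(inc[0] < 0, -1.0, 1.0)
    inc = inc * sign
    # exact quaternion log of the increment: angle = 2 atan2(|v|, w); the
    # first-order form (2/dt) * v underestimates the rate by O(angle^2)
    vec = inc[1:4]
    vnorm = np.linalg.norm(vec, axis=0)
    angle = 2.0 * np.arctan2(vnorm, np.clip(inc[0], -1.0, 1.0))
    scale = np.where(vnorm > 1e-12, angle / np.maximum(vnorm, 1e-300), 2.0)
    omega = (scale / dt) * vec
    return AngularVelocitySeries(omega=omega, dt=dt)


def filter_acceleration(acc: np.ndarray, rate: float) -> np.ndarray:
    """Zero-phase 5th-order low-pass Butterworth at 40 Hz, per channel."""
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    if rate <= 2 * FILTER_CUTOFF_HZ:
        raise ValueError(f"sampling rate {rate} Hz too low for a {FILTER_CUTOFF_HZ} Hz cutoff")
    sos = signal.butter(FILTER_ORDER, FILTER_CUTOFF_HZ, btype="low", fs=rate, output="sos")
    if acc.shape[1] < 3 * 2 * FILTER_ORDER:
        raise ValueError("stream shorter than the filter warm-up length")
    return signal.sosfiltfilt(sos, acc, axis=1)


def _windowed_drop(x: np.ndarray, i: int) -> bool:
    """True when the signal fell by >= EXCURSION_G shortly before sample i:
    the pre-window minimum is preceded by a value at least EXCURSION_G higher."""
    w = x[max(i - PRE_WINDOW, 0) : i]
    if w.size < 2:
        return False
    jmin = int(np.argmin(w))
    return jmin >= 1 and (np.max(w[: jmin + 1]) - w[jmin]) >= EXCURSION_G


def _windowed_rise(x: np.ndarray, i: int) -> bool:
    """True when the signal rises by >= EXCURSION_G shortly after sample i:
    the post-window maximum is preceded by a value at least EXCURSION_G lower."""
    w = x[i : i + POST_WINDOW + 1]
    if w.size < 2:
        return False
    jmax = int(np.argmax(w))
    return (w[jmax] - np.min(w[: jmax + 1])) >= EXCURSION_G


def detect_gait_events(vertical_acc_g: np.ndarray, rate: float) -> GaitEventList:
    """IC/TO detection on the vertical foot acceleration in g-units.

    IC: upward crossing of +0.18 g with a preceding windowed drop and a
    following windowed rise.  TO: first downward crossing of -0.25 g after the
    IC (before the next IC candidate) with a preceding windowed drop; when no
    crossing exists the TO threshold is relaxed in +0.05 g increments up to
    -0.05 g.  ICs without any TO are dropped.  Accepted ICs are separated by a
    0.1 s refractory interval.
    """
    x = np.asarray(vertical_acc_g, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if rate <= 0:
        raise ValueError("rate must be positive")

    up = np.where((x[:-1] < IC_THRESHOLD_G) & (x[1:] >= IC_THRESHOLD_G))[0] + 1
    refractory = int(round(REFRACTORY_S * rate))
    candidates = []
    last = -10 ** 9
    for i in up:
        if i - last < refractory:
            continue
        if _windowed_drop(x, i) and _windowed_rise(x, i):
            candidates.append(int(i))
            last = i

    ics, tos, thrs = [], [], []
    for n, ic in enumerate(candidates):
        stop = candidates[n + 1] if n + 1 < len(candidates) else x.size
        found = None
        thr = TO_THRESHOLD_G
        while found is None and thr <= TO_THRESHOLD_CEIL_G + 1e-12:
            for j in range(ic + 1, stop):
                if x[j - 1] > thr >= x[j] and _windowed_drop(x, j):
                    found = (j, thr)
                    break
            thr += TO_THRESHOLD_STEP_G
        if found is not None:
            ics.append(ic)
            tos.append(found[0])
            thrs.append(found[1])
    return GaitEventList(
        ic_indices=np.array(ics, dtype=int),
        to_indices=np.array(tos, dtype=int),
        to_thresholds=np.array(thrs, dtype=float),
    )


def synchronize(reference: np.ndarray, target: np.ndarray, max_lag: int) -> int:
    """Integer lag of ``target`` relative to ``reference`` (positive = target
    later), chosen to maximize the normalized cross-correlation; ties break
    toward the smaller absolute lag.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(target, dtype=float)
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    if max_lag >= n // 2:
        raise ValueError("max_lag must be below half the common length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("cannot synchronize constant signals")
    lags = np.arange(-max_lag, max_lag + 1)
    best_lag, best_val = 0, -np.inf
    for lag in lags:
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            continue
        val = float(np.mean((x - np.mean(x)) * (y - np.mean(y))) / (sx * sy))
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12 and abs(lag) < abs(best_lag)
        ):
            best_val, best_lag = val, int(lag)
    return best_lag


def events_to_g_units(acc_ms2: np.ndarray) -> np.ndarray:
    """Convenience: convert an acceleration channel from m/s^2 to g-units."""
    return np.asarray(acc_ms2, dtype=float) / G
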