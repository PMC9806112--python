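"""Pre-processing and forearm-orientation estimation.

Raw wrist-IMU data is cleaned (gyroscope offset correction anchored on
detected rest periods, fifth-order median filtering of the accelerometer)
and fused into an earth-referenced orientation with either the Madgwick
(gradient-descent, 6-DOF accel+gyro) or Mahony (complementary PI, 9-DOF
accel+gyro+mag) filter. Forearm yaw and pitch are read off the estimated
quaternion: pitch is the elevation of the sensor x axis (which points along
the forearm toward the hand) above the horizontal plane, yaw its heading.

Quaternions are scalar-first, sensor-to-earth: ``v_earth = q (0,v_body) q*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError

__all__ = [
    "OrientationSeries",
    "detect_rest_periods",
    "correct_gyro_offset",
    "median_filter_accel",
    "estimate_orientation",
    "gravity_subtract",
    "quat_rotate",
    "quat_from_euler",
]


@dataclass
class OrientationSeries:
    """Per-sample orientation: unit quaternions plus forearm yaw/pitch (deg)."""

    timestamps: np.ndarray
    quaternions: np.ndarray  # (N, 4) scalar-first, sensor-to-earth
    yaw: np.ndarray          # deg in (-180, 180]
    pitch: np.ndarray        # deg in [-90, 90]
    rate: float

    def __len__(self) -> int:
        return len(self.timestamps)


# ---------------------------------------------------------------------------
# Quaternion helpers

def _quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array([
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    ])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate body-frame vectors into the earth frame.

    ``q`` is (N, 4) or (4,) scalar-first sensor-to-earth; ``v`` is (N, 3)
    or (3,).
    """
    single = np.asarray(q).ndim == 1 and np.asarray(v).ndim == 1
    q = np.atleast_2d(np.asarray(q, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # rotation matrix rows applied to v
    r00 = 1 - 2 * (y * y + z * z)
    r01 = 2 * (x * y - w * z)
    r02 = 2 * (x * z + w * y)
    r10 = 2 * (x * y + w * z)
    r11 = 1 - 2 * (x * x + z * z)
    r12 = 2 * (y * z - w * x)
    r20 = 2 * (x * z - w * y)
    r21 = 2 * (y * z + w * x)
    r22 = 1 - 2 * (x * x + y * y)
    vx, vy, vz = v[:, 0], v[:, 1], v[:, 2]
    out = np.column_stack([
        r00 * vx + r01 * vy + r02 * vz,
        r10 * vx + r11 * vy + r12 * vz,
        r20 * vx + r21 * vy + r22 * vz,
    ])
    return out[0] if single else out


def quat_from_euler(yaw_deg: float, pitch_deg: float, roll_deg: float = 0.0
                    ) -> np.ndarray:
    """Quaternion for Rz(yaw) Ry(-pitch) Rx(roll).

    ``pitch`` here is the elevation of the body x axis, so the middle
    rotation is by minus the conventional Z-Y-X pitch angle.
    """
    y = np.radians(yaw_deg) / 2.0
    p = np.radians(-pitch_deg) / 2.0
    r = np.radians(roll_deg) / 2.0
    qz = np.array([np.cos(y), 0.0, 0.0, np.sin(y)])
    qy = np.array([np.cos(p), 0.0, np.sin(p), 0.0])
    qx = np.array([np.cos(r), np.sin(r), 0.0, 0.0])
    return _quat_multiply(_quat_multiply(qz, qy), qx)


def _euler_from_quat(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(yaw, pitch) in degrees from the rotated body x axis."""
    q = np.atleast_2d(q)
    x_earth = quat_rotate(q, np.tile([1.0, 0.0, 0.0], (len(q), 1)))
    pitch = np.degrees(np.arcsin(np.clip(x_earth[:, 2], -1.0, 1.0)))
    yaw = np.degrees(np.arctan2(x_earth[:, 1], x_earth[:, 0]))
    return yaw, pitch


# ---------------------------------------------------------------------------
# Rest detection and gyro offset correction

def detect_rest_periods(timestamps, gyro, min_duration: float = 10.0,
                        variance_threshold: float = 0.15,
                        block_s: float = 1.0) -> list[tuple[float, float]]:
    """Find rest intervals: stretches >= ``min_duration`` seconds where the
    per-axis gyroscope variance stays below ``variance_threshold``.

    The trace is cut into non-overlapping ``block_s``-second blocks; a block
    is quiet when every axis's sample variance within it is below the
    threshold, and maximal runs of quiet blocks at least ``min_duration``
    long are returned as ``(start, end)`` second pairs.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    n = len(timestamps)
    if n < 2:
        return []
    rate = 1.0 / np.median(np.diff(timestamps))
    block = max(1, int(round(block_s * rate)))
    n_blocks = n // block
    if n_blocks * block_s < min_duration:
        return []
    quiet = np.empty(n_blocks, dtype=bool)
    for b in range(n_blocks):
        seg = gyro[b * block:(b + 1) * block]
        quiet[b] = bool((seg.var(axis=0) < variance_threshold).all())
    intervals: list[tuple[float, float]] = []
    b = 0
    min_blocks = int(np.ceil(min_duration / block_s))
    while b < n_blocks:
        if quiet[b]:
            start = b
            while b < n_blocks and quiet[b]:
                b += 1
            if b - start >= min_blocks:
                t_start = timestamps[start * block]
                last = min(b * block, n) - 1
                intervals.append((float(t_start), float(timestamps[last])))
        else:
            b += 1
    return intervals


def correct_gyro_offset(timestamps, gyro, rest_intervals):
    """Subtract rest-period gyro bias, piecewise between rest periods.

    For each rest interval, the per-axis mean over the interval is removed
    from all samples from the interval's start until the next interval's
    start (or the end of the record). Samples before the first rest
    interval are left untouched; with no rest intervals this is the
    identity.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    out = np.array(gyro, dtype=float, copy=True)
    if not rest_intervals:
        return out
    starts = [iv[0] for iv in rest_intervals]
    for k, (t0, t1) in enumerate(rest_intervals):
        in_rest = (timestamps >= t0) & (timestamps <= t1)
        if not in_rest.any():
            continue
        offset = out[in_rest].mean(axis=0)
        seg_end = starts[k + 1] if k + 1 < len(starts) else np.inf
        seg = (timestamps >= t0) & (timestamps < seg_end)
        out[seg] -= offset
    return out


def median_filter_accel(accel, window: int = 5):
    """NaN-aware running median per axis (default fifth-order).

    Edges use a shrinking window; NaN samples are excluded from their
    windows, so isolated missing values are effectively interpolated.
    """
    accel = np.asarray(accel, dtype=float)
    one_d = accel.ndim == 1
    arr = accel[:, None] if one_d else accel
    half = window // 2
    padded = np.pad(arr, ((half, half), (0, 0)), constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, window, axis=0)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out = np.nanmedian(win, axis=-1)
    return out[:, 0] if one_d else out


# ---------------------------------------------------------------------------
# Sensor fusion

def _init_quat_from_accel(a: np.ndarray) -> np.ndarray:
    """Tilt-align the initial quaternion from one accelerometer sample."""
    norm = np.linalg.norm(a)
    if not np.isfinite(norm) or norm == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    ax, ay, az = a / norm
    # accel_body = R^T (0,0,1) = (-sin(theta), sin(phi) cos(theta), cos(phi) cos(theta))
    theta = -np.arcsin(np.clip(ax, -1.0, 1.0))
    phi = np.arctan2(ay, az)
    return quat_from_euler(0.0, -np.degrees(theta), np.degrees(phi))


def _madgwick_step(q, gyr_rad, acc, beta, dt):
    qw, qx, qy, qz = q
    gx, gy, gz = gyr_rad
    # quaternion rate from gyro
    qdot = 0.5 * np.array([
        -qx * gx - qy * gy - qz * gz,
        qw * gx + qy * gz - qz * gy,
        qw * gy - qx * gz + qz * gx,
        qw * gz + qx * gy - qy * gx,
    ])
    a_norm = np.linalg.norm(acc)
    if np.isfinite(a_norm) and a_norm > 0:
        ax, ay, az = acc / a_norm
        # gradient of || R^T(0,0,1) - a ||^2
        f1 = 2.0 * (qx * qz - qw * qy) - ax
        f2 = 2.0 * (qw * qx + qy * qz) - ay
        f3 = 2.0 * (0.5 - qx * qx - qy * qy) - az
        g = np.array([
            -2.0 * qy * f1 + 2.0 * qx * f2,
            2.0 * qz * f1 + 2.0 * qw * f2 - 4.0 * qx * f3,
            -2.0 * qw * f1 + 2.0 * qz * f2 - 4.0 * qy * f3,
            2.0 * qx * f1 + 2.0 * qy * f2,
        ])
        g_norm = np.linalg.norm(g)
        if g_norm > 0:
            qdot -= beta * g / g_norm
    q = q + qdot * dt
    return q / np.linalg.norm(q)


def _mahony_step(q, gyr_rad, acc, mag, integral, kp, ki, dt):
    qw, qx, qy, qz = q
    err = np.zeros(3)
    a_norm = np.linalg.norm(acc)
    if np.isfinite(a_norm) and a_norm > 0:
        a = acc / a_norm
        # estimated gravity direction in the body frame
        v = np.array([
            2.0 * (qx * qz - qw * qy),
            2.0 * (qw * qx + qy * qz),
            qw * qw - qx * qx - qy * qy + qz * qz,
        ])
        err += np.cross(a, v)
    if mag is not None:
        m_norm = np.linalg.norm(mag)
        if np.isfinite(m_norm) and m_norm > 0:
            m = mag / m_norm
            h = quat_rotate(q, m)
            b = np.array([np.hypot(h[0], h[1]), 0.0, h[2]])
            # reference field rotated back into the body frame
            w = quat_rotate(np.array([qw, -qx, -qy, -qz]), b)
            err += np.cross(m, w)
    if ki > 0:
        integral += ki * err * dt
        gyr_rad = gyr_rad + kp * err + integral
    else:
        gyr_rad = gyr_rad + kp * err
    gx, gy, gz = gyr_rad
    qdot = 0.5 * np.array([
        -qx * gx - qy * gy - qz * gz,
        qw * gx + qy * gz - qz * gy,
        qw * gy - qx * gz + qz * gx,
        qw * gz + qx * gy - qy * gx,
    ])
    q = q + qdot * dt
    return q / np.linalg.norm(q), integral


def estimate_orientation(timestamps, accel, gyro, mag=None,
                         algorithm: str = "madgwick", rate: float | None = None,
                         beta: float = 0.1, kp: float = 1.0, ki: float = 0.3
                         ) -> OrientationSeries:
    """Fuse IMU channels into an orientation series.

    Parameters
    ----------
    accel : (N, 3) in g; gyro : (N, 3) in deg/s; mag : optional (N, 3).
    algorithm : ``madgwick`` (6-DOF; mag ignored) or ``mahony`` (uses mag
        when provided, i.e. 9-DOF fusion).
    beta : Madgwick gradient gain. kp, ki : Mahony PI feedback gains.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    n = len(timestamps)
    if accel.shape != (n, 3) or gyro.shape != (n, 3):
        raise ValidationError("accel/gyro must both be (N, 3) matching timestamps")
    if mag is not None:
        mag = np.asarray(mag, dtype=float)
        if mag.shape != (n, 3):
            raise ValidationError("mag must be (N, 3) matching timestamps")
    if algorithm not in ("madgwick", "mahony"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if rate is None:
        rate = 1.0 / np.median(np.diff(timestamps)) if n > 1 else 50.0
    dt = 1.0 / rate
    gyr = np.radians(gyro)
    quats = np.empty((n, 4))
    q = _init_quat_from_accel(accel[0])
    integral = np.zeros(3)
    for i in range(n):
        if algorithm == "madgwick":
            q = _madgwick_step(q, gyr[i], accel[i], beta, dt)
        else:
            m = mag[i] if mag is not None else None
            q, integral = _mahony_step(q, gyr[i], accel[i], m, integral,
                                       kp, ki, dt)
        quats[i] = q
    yaw, pitch = _euler_from_quat(quats)
    return OrientationSeries(timestamps=timestamps, quaternions=quats,
                             yaw=yaw, pitch=pitch, rate=float(rate))


def gravity_subtract(accel, orientation: OrientationSeries):
    """Earth-frame linear acceleration: rotate to earth, remove (0,0,1) g."""
    accel = np.asarray(accel, dtype=float)
    if accel.shape != (len(orientation), 3):
        raise ValidationError("accel must align sample-wise with orientation")
    earth = quat_rotate(orientation.quaternions, accel)
    earth[:, 2] -= 1.0
    return earth
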