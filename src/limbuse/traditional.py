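"""Traditional (non-learning) upper-limb-use measures.

Four detectors that turn wrist-IMU data into a binary use signal:

* **Vector Magnitude (VM)** — Actigraph-style counts: gravity-corrected
  acceleration (6-DOF Madgwick) band-passed 0.25-2.5 Hz, resampled to
  10 Hz, dead-band filtered at +-0.068 g, summed per 1 s bin, 2-normed
  across axes and smoothed with a 5 s / 4 s-overlap moving average to
  1 Hz counts; use = counts > 0.
* **Activity Counts (AC)** — gravity removed with a 9-DOF Mahony filter,
  acceleration magnitude band-passed 0.25-2.5 Hz, averaged into 1 s bins
  and quantized by 0.017 g; a laterality index over both arms' counts is
  thresholded at +-0.95 to flag per-arm use.
* **Gross Movement (GM)** — 2 s windows with 75% overlap: use = 1 when
  the summed yaw+pitch angular range exceeds 30 deg while the mean
  forearm pitch stays within the +-30 deg "functional space".
* **GMAC** — hybrid of the two: use = 1 in a 1 s bin when VM counts are
  positive and the bin's mean pitch is within +-30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .data_model import ImuRecording, UseSignal, ValidationError, resample_zoh
from .orientation import OrientationSeries, estimate_orientation, gravity_subtract

__all__ = [
    "CountsSignal",
    "LateralityResult",
    "deadband",
    "quantize_counts",
    "vector_magnitude_counts",
    "vm_use",
    "activity_counts",
    "laterality_use",
    "gm_use",
    "gmac_use",
]

DEADBAND_G = 0.068          # Actigraph-style dead-band threshold
COUNT_STEP_G = 0.017        # activity-count quantization step
FUNCTIONAL_PITCH_DEG = 30.0  # half-width of the functional space
GM_ANGLE_DEG = 30.0          # yaw+pitch range threshold per 2 s window
LATERALITY_THRESHOLD = 0.95
BAND_HZ = (0.25, 2.5)


@dataclass
class CountsSignal:
    """1 Hz activity counts (reals for VM, integers for AC)."""

    timestamps: np.ndarray
    counts: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.timestamps) != len(self.counts):
            raise ValidationError("timestamps and counts lengths differ")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class LateralityResult:
    """Per-second laterality index and the per-arm use flags it implies.

    ``laterality_index`` is NaN where both arms' counts are zero (the
    index is undefined there and both arms are flagged unused).
    """

    timestamps: np.ndarray
    laterality_index: np.ndarray
    use_dominant: UseSignal
    use_nondominant: UseSignal


def deadband(x, threshold: float = DEADBAND_G):
    """Zero out samples whose magnitude is at or below ``threshold``."""
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) <= threshold, 0.0, x)


def quantize_counts(x, step: float = COUNT_STEP_G):
    """Quantize non-negative magnitudes into integer counts: floor(x/step)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("quantize_counts requires non-negative input")
    # epsilon guards against 0.034/0.017 -> 1.999... flooring to 1
    return np.floor(x / step + 1e-9).astype(int)


def _bandpass(x, rate: float, band=BAND_HZ, order: int = 4):
    """Zero-phase Butterworth band-pass along axis 0."""
    b, a = butter(order, band, btype="bandpass", fs=rate)
    return filtfilt(b, a, x, axis=0)


def _bin_edges_count(n: int, per_bin: int) -> int:
    return n // per_bin


def vector_magnitude_counts(recording: ImuRecording, *, beta: float = 0.1,
                            deadband_g: float = DEADBAND_G) -> CountsSignal:
    """Vector-magnitude counts at 1 Hz from one arm's recording.

    Pipeline: zero-order-hold resample to 30 Hz -> gravity correction via
    6-DOF Madgwick -> per-axis 4th-order Butterworth band-pass
    0.25-2.5 Hz (zero-phase) -> resample to 10 Hz -> dead-band at
    +-``deadband_g`` -> per-axis sums over non-overlapping 1 s bins ->
    2-norm across axes -> moving average (5 s window, 4 s overlap),
    stamped at window end.
    """
    if recording.duration < 6.0:
        raise ValidationError(
            "record shorter than one 5 s moving-average window plus a bin")
    t = recording.timestamps
    grid30, _ = resample_zoh(t, np.zeros(len(t)), 30.0)
    acc30 = np.column_stack([resample_zoh(t, recording.accel[:, i], 30.0)[1]
                             for i in range(3)])
    gyr30 = np.column_stack([resample_zoh(t, recording.gyro[:, i], 30.0)[1]
                             for i in range(3)])
    orient = estimate_orientation(grid30, acc30, gyr30, algorithm="madgwick",
                                  rate=30.0, beta=beta)
    linear = gravity_subtract(acc30, orient)
    filtered = _bandpass(linear, 30.0)
    t10, _ = resample_zoh(grid30, filtered[:, 0], 10.0)
    f10 = np.column_stack([resample_zoh(grid30, filtered[:, i], 10.0)[1]
                           for i in range(3)])
    f10 = np.abs(deadband(f10, deadband_g))
    n_bins = _bin_edges_count(len(t10), 10)
    sums = f10[:n_bins * 10].reshape(n_bins, 10, 3).sum(axis=1)
    norms = np.linalg.norm(sums, axis=1)
    if n_bins < 5:
        raise ValidationError("record shorter than one moving-average window")
    # moving average: window 5 bins, hop 1 bin -> 1 Hz, stamp at window end
    kernel = np.ones(5) / 5.0
    counts = np.convolve(norms, kernel, mode="valid")
    bin_end_times = t10[0] + np.arange(1, n_bins + 1) * 1.0
    ts = bin_end_times[4:]
    return CountsSignal(timestamps=ts, counts=counts, rate=1.0)


def vm_use(counts: CountsSignal) -> UseSignal:
    """Binarize VM counts with a zero threshold."""
    return UseSignal(timestamps=counts.timestamps,
                     values=(np.asarray(counts.counts) > 0).astype(int),
                     rate=counts.rate)


def activity_counts(recording: ImuRecording, *, kp: float = 1.0,
                    ki: float = 0.3, step: float = COUNT_STEP_G
                    ) -> CountsSignal:
    """Integer activity counts at 1 Hz (de Lucena-style pipeline).

    Gravity is removed with a 9-DOF Mahony filter, so the recording must
    carry magnetometer data.
    """
    if recording.mag is None:
        raise ValidationError(
            "activity counts need 9-DOF data: magnetometer channels missing")
    rate = recording.nominal_rate
    orient = estimate_orientation(recording.timestamps, recording.accel,
                                  recording.gyro, recording.mag,
                                  algorithm="mahony", rate=rate, kp=kp, ki=ki)
    linear = gravity_subtract(recording.accel, orient)
    mag = np.linalg.norm(linear, axis=1)
    filtered = _bandpass(mag, rate)
    per_bin = int(round(rate))
    n_bins = len(filtered) // per_bin
    means = np.abs(filtered[:n_bins * per_bin].reshape(n_bins, per_bin)
                   ).mean(axis=1)
    counts = quantize_counts(means, step)
    ts = recording.timestamps[0] + np.arange(1, n_bins + 1) * 1.0
    return CountsSignal(timestamps=ts, counts=counts, rate=1.0)


def laterality_use(counts_dom: CountsSignal, counts_nondom: CountsSignal,
                   threshold: float = LATERALITY_THRESHOLD
                   ) -> LateralityResult:
    """Per-arm use from the laterality index of the two arms' counts.

    LI = (c_dom - c_nondom) / (c_dom + c_nondom). LI > -threshold flags
    dominant-arm use, LI < +threshold flags non-dominant-arm use; seconds
    with zero counts on both arms are undefined (NaN) and unused.
    """
    td, tn = counts_dom.timestamps, counts_nondom.timestamps
    if len(td) != len(tn) or not np.allclose(td, tn):
        raise ValidationError("laterality requires both arms on the same 1 Hz grid")
    cd = np.asarray(counts_dom.counts, dtype=float)
    cn = np.asarray(counts_nondom.counts, dtype=float)
    total = cd + cn
    defined = total > 0
    li = np.full(len(cd), np.nan)
    np.divide(cd - cn, total, out=li, where=defined)
    use_dom = (defined & (li > -threshold)).astype(int)
    use_nondom = (defined & (li < threshold)).astype(int)
    return LateralityResult(
        timestamps=td,
        laterality_index=li,
        use_dominant=UseSignal(td, use_dom, counts_dom.rate),
        use_nondominant=UseSignal(td, use_nondom, counts_dom.rate),
    )


def gm_use(orientation: OrientationSeries, *, window_s: float = 2.0,
           hop_s: float = 0.5, angle_threshold: float = GM_ANGLE_DEG,
           pitch_band: float = FUNCTIONAL_PITCH_DEG) -> UseSignal:
    """Gross-movement score over 2 s windows with 75% overlap (2 Hz).

    A window scores 1 when the summed range of unwrapped yaw and of pitch
    exceeds ``angle_threshold`` degrees and the window's mean pitch lies
    within +-``pitch_band`` degrees.
    """
    n = len(orientation)
    rate = orientation.rate
    win = int(round(window_s * rate))
    hop = int(round(hop_s * rate))
    if n < win:
        raise ValidationError("record shorter than one GM window")
    yaw = np.unwrap(orientation.yaw, period=360.0)
    pitch = orientation.pitch
    starts = np.arange(0, n - win + 1, hop)
    values = np.empty(len(starts), dtype=int)
    for j, s in enumerate(starts):
        yw = yaw[s:s + win]
        pw = pitch[s:s + win]
        delta = (yw.max() - yw.min()) + (pw.max() - pw.min())
        values[j] = int(delta > angle_threshold
                        and abs(pw.mean()) < pitch_band)
    ts = orientation.timestamps[0] + starts / rate
    return UseSignal(timestamps=ts, values=values, rate=1.0 / hop_s)


def gmac_use(counts: CountsSignal, pitch_timestamps, pitch, *,
             pitch_band: float = FUNCTIONAL_PITCH_DEG) -> UseSignal:
    """Hybrid GM + activity-counting measure at 1 Hz.

    For each 1 s counts bin (ending at the counts timestamp), use = 1 iff
    the counts are positive and the bin's mean forearm pitch is within
    +-``pitch_band`` degrees.
    """
    pt = np.asarray(pitch_timestamps, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    if len(pt) != len(pitch):
        raise ValidationError("pitch timestamps and values lengths differ")
    ct = counts.timestamps
    if len(ct) == 0 or ct[0] - 1.0 < pt[0] - 1e-6 or ct[-1] > pt[-1] + 1.0:
        raise ValidationError("pitch series does not span the counts bins")
    values = np.empty(len(ct), dtype=int)
    for j, t in enumerate(ct):
        in_bin = (pt >= t - 1.0) & (pt < t)
        mean_pitch = pitch[in_bin].mean() if in_bin.any() else np.nan
        values[j] = int(counts.counts[j] > 0
                        and np.isfinite(mean_pitch)
                        and abs(mean_pitch) < pitch_band)
    return UseSignal(timestamps=ct, values=values, rate=counts.rate)
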