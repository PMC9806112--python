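"""End-to-end pipelines: raw two-arm dataset -> use signals -> metrics.

These functions chain the preprocessing, orientation, measure and
evaluation modules the way the CLI and the analysis scripts use them, so
the same code path serves interactive work and batch runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import ml, traditional
from .data_model import ImuRecording, SubjectDataset, UseSignal, resample_zoh
from .orientation import (OrientationSeries, correct_gyro_offset,
                          detect_rest_periods, estimate_orientation,
                          median_filter_accel)

__all__ = [
    "preprocess",
    "consensus_gt",
    "arm_use_signals",
    "evaluate_subjects",
    "window_table_for_arm",
    "window_variables",
]

MEASURES = ("vm", "ac", "gm", "gmac")


def _fit(values: np.ndarray, n: int) -> np.ndarray:
    """Pad (repeat last) or truncate a track to n samples."""
    if len(values) >= n:
        return values[:n]
    return np.concatenate([values, np.repeat(values[-1], n - len(values))])


def preprocess(recording: ImuRecording, *, beta: float = 0.1
               ) -> tuple[ImuRecording, OrientationSeries]:
    """Clean a recording and estimate its forearm orientation.

    Gyroscope bias is removed piecewise using detected rest periods, the
    accelerometer is median-filtered (5th order), and a 6-DOF Madgwick
    filter provides the earth-referenced yaw/pitch series.
    """
    rest = detect_rest_periods(recording.timestamps, recording.gyro)
    gyro = correct_gyro_offset(recording.timestamps, recording.gyro, rest)
    accel = median_filter_accel(recording.accel)
    cleaned = ImuRecording(timestamps=recording.timestamps, accel=accel,
                           gyro=gyro, mag=recording.mag,
                           nominal_rate=recording.nominal_rate,
                           arm_label=recording.arm_label)
    orient = estimate_orientation(cleaned.timestamps, cleaned.accel,
                                  cleaned.gyro, algorithm="madgwick",
                                  rate=cleaned.nominal_rate, beta=beta)
    return cleaned, orient


def consensus_gt(arm) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote ground truth on the sensor grid (50 Hz, ZOH)."""
    ann, rec = arm.annotations, arm.recording
    consensus = ann.consensus()
    return resample_zoh(ann.timestamps, consensus, rec.nominal_rate)


def arm_use_signals(subject: SubjectDataset) -> dict[str, dict[str, UseSignal]]:
    """All four traditional use signals for both arms of one subject.

    Returns ``{measure: {arm_label: UseSignal}}``. The activity-count
    measure needs both arms at once (laterality), which is why this
    operates on a subject rather than a single arm.
    """
    per_arm = {}
    for arm_label, arm in subject.arms.items():
        cleaned, orient = preprocess(arm.recording)
        vm_counts = traditional.vector_magnitude_counts(cleaned)
        per_arm[arm_label] = {
            "cleaned": cleaned,
            "orient": orient,
            "vm_counts": vm_counts,
        }
    dom_label = "right" if subject.group == "control" else "unaffected"
    nondom_label = "left" if subject.group == "control" else "affected"
    ac_dom = traditional.activity_counts(per_arm[dom_label]["cleaned"])
    ac_nondom = traditional.activity_counts(per_arm[nondom_label]["cleaned"])
    n = min(len(ac_dom), len(ac_nondom))
    ac_dom = traditional.CountsSignal(ac_dom.timestamps[:n], ac_dom.counts[:n])
    ac_nondom = traditional.CountsSignal(ac_nondom.timestamps[:n],
                                         ac_nondom.counts[:n])
    lat = traditional.laterality_use(ac_dom, ac_nondom)
    out: dict[str, dict[str, UseSignal]] = {m: {} for m in MEASURES}
    out["ac"][dom_label] = lat.use_dominant
    out["ac"][nondom_label] = lat.use_nondominant
    for arm_label, parts in per_arm.items():
        orient = parts["orient"]
        vm_counts = parts["vm_counts"]
        out["vm"][arm_label] = traditional.vm_use(vm_counts)
        out["gm"][arm_label] = traditional.gm_use(orient)
        out["gmac"][arm_label] = traditional.gmac_use(
            vm_counts, orient.timestamps, orient.pitch)
    return out


def evaluate_subjects(subjects: list[SubjectDataset]) -> pd.DataFrame:
    """Evaluate every traditional measure on every subject and arm.

    One row per (subject, arm, measure) with confusion counts,
    sensitivity, specificity and Youden index against the consensus
    annotations on the 50 Hz grid.
    """
    rows = []
    for subj in subjects:
        signals = arm_use_signals(subj)
        for arm_label, arm in subj.arms.items():
            gt_t, gt_v = consensus_gt(arm)
            for measure in MEASURES:
                use = signals[measure][arm_label]
                res = ev.evaluate_use(use, gt_t, gt_v, subject=subj.subject_id,
                                      arm=arm_label, measure=measure)
                rows.append({
                    "subject": subj.subject_id, "arm": arm_label,
                    "measure": measure, "tp": res.tp, "fp": res.fp,
                    "tn": res.tn, "fn": res.fn,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "youden": res.youden,
                })
    return pd.DataFrame(rows)


def window_table_for_arm(arm, window_s: float = 0.25, *,
                         subject: str | None = None,
                         arm_label: str | None = None,
                         include_gyro: bool = False) -> pd.DataFrame:
    """Feature-window table for one arm from its consensus annotations."""
    rec = arm.recording
    gt_t, gt_v = consensus_gt(arm)
    gt = _fit(gt_v, len(rec))
    _, task50 = resample_zoh(arm.annotations.timestamps,
                             arm.annotations.task_track, rec.nominal_rate)
    task50 = _fit(task50, len(rec))
    return ml.build_window_table(rec, gt, window_s, subject=subject,
                                 arm=arm_label, task_track=task50,
                                 include_gyro=include_gyro)


def window_variables(orient: OrientationSeries, counts, window_s: float = 0.25,
                     n_windows: int | None = None) -> pd.DataFrame:
    """Interpretable per-window quantities used by the GM/TAC measures.

    Mean forearm pitch and unwrapped-yaw range per feature window, plus
    the 1 Hz activity counts held onto the window grid (ZOH). Used to
    correlate learned features with what the traditional measures see.
    """
    rate = orient.rate
    per = window_s * rate
    total = int(np.floor(len(orient) / per + 1e-9))
    if n_windows is not None:
        total = min(total, n_windows)
    yaw = np.unwrap(orient.yaw, period=360.0)
    mean_pitch = np.empty(total)
    yaw_range = np.empty(total)
    t_centre = np.empty(total)
    for i in range(total):
        lo = int(np.floor(i * per + 1e-9))
        hi = int(np.floor((i + 1) * per + 1e-9))
        mean_pitch[i] = orient.pitch[lo:hi].mean()
        yaw_range[i] = yaw[lo:hi].max() - yaw[lo:hi].min()
        t_centre[i] = orient.timestamps[lo] + window_s / 2.0
    idx = np.searchsorted(counts.timestamps, t_centre, side="right") - 1
    idx = np.clip(idx, 0, len(counts) - 1)
    return pd.DataFrame({
        "mean_pitch": mean_pitch,
        "yaw_range": yaw_range,
        "counts": np.asarray(counts.counts, dtype=float)[idx],
    })
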