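"""Synthetic two-arm wrist-IMU generator with frame-accurate ground truth.

A scripted state machine strings together epochs of four movement
regimes — functional arm use (reaching-scale yaw excursions inside the
functional space, 0.1-0.5 g bursts), functional hand use (near-static
forearm in the functional space, millimetre-scale acceleration), gait
(arm hanging, pitch oscillating around -75 deg at ~1 Hz with pendular
acceleration) and rest (static blocks of at least 10 s) — separated by
short "unknown" transition ramps. True forearm yaw/pitch trajectories
drive an exact forward model: the accelerometer reports body-frame
specific force (gravity plus scripted earth-frame motion acceleration),
the gyroscope the body-frame angular rates plus a constant per-axis
offset, and the magnetometer a fixed earth field rotated into the body
frame, each with Gaussian noise. Four annotation tracks at 30 Hz emulate
two annotators x two passes by flipping the true use label independently
with a small probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (AnnotationSet, ArmData, ImuRecording, SubjectDataset,
                         ValidationError, resample_zoh)
from .orientation import quat_from_euler, quat_rotate

__all__ = ["SimConfig", "SimTruth", "simulate_arm", "simulate_cohort",
           "TASK_KIND"]

#: Task vocabulary -> movement regime.
TASK_KIND = {
    "drinkcup": "arm", "openbottle": "arm", "wipe": "arm", "comb": "arm",
    "eat": "arm", "fold": "arm",
    "type": "hand", "write": "hand", "button": "hand",
    "walk": "gait",
    "rest": "rest",
}

FUNCTIONAL_KINDS = ("arm", "hand")

DEFAULT_SEQUENCE = ("rest", "drinkcup", "type", "walk", "openbottle",
                    "write", "walk", "rest")

DEFAULT_DURATIONS = {"arm": 18.0, "hand": 15.0, "gait": 18.0, "rest": 12.0}

EARTH_MAG = np.array([0.6, 0.0, -0.8])  # arbitrary units, with dip

TRANSITION_S = 1.0


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated arm.

    Defaults mirror the structure of an in-clinic recording session:
    tabletop functional tasks interleaved with walking and >= 10 s rest
    blocks, ~50 Hz sampling, small sensor noise and a constant gyroscope
    bias that the offset-correction step is meant to remove.
    """

    rate: float = 50.0
    task_sequence: tuple = DEFAULT_SEQUENCE
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    functional_share: float | None = None
    accel_noise_sd: float = 0.01       # g
    gyro_noise_sd: float = 0.2         # deg/s
    gyro_offset: tuple = (0.5, -0.3, 0.2)  # deg/s per axis
    annot_flip_prob: float = 0.02
    annot_boundary_jitter_s: float = 0.3  # annotator reaction-time sd
    amplitude_scale: float = 1.0       # attenuates movement (paretic arms)
    seed: int | None = 0

    def task_duration(self, task: str) -> float:
        if task in self.durations:
            return float(self.durations[task])
        return float(self.durations[TASK_KIND[task]])


@dataclass
class SimTruth:
    """Per-sample generating state at the sensor rate."""

    timestamps: np.ndarray
    pitch: np.ndarray          # deg, elevation of the forearm axis
    yaw: np.ndarray            # deg, unwrapped heading of the forearm axis
    use: np.ndarray            # binary functional-use label
    task: np.ndarray           # task name, "unknown" during transitions
    movement_type: np.ndarray  # Arm / Hand / NonFunctional


# ---------------------------------------------------------------------------
# Epoch kinematics. Each builder returns (pitch deg, yaw deg relative to its
# own start, earth-frame motion accel in g) sampled at `rate`.

def _epoch_arm(n: int, rate: float, rng, amp: float):
    t = np.arange(n) / rate
    base_pitch = rng.uniform(-20.0, 20.0)
    pitch = base_pitch + 6.0 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    yaw = np.zeros(n)
    a_e = np.zeros((n, 3))
    i = 0
    y0 = 0.0
    moving = True
    while i < n:
        seg_s = rng.uniform(2.5, 4.0) if moving else rng.uniform(1.0, 2.0)
        m = min(n - i, max(1, int(round(seg_s * rate))))
        ts = np.arange(m) / rate
        if moving:
            amp_y = rng.uniform(15.0, 35.0) * amp
            f_y = rng.uniform(0.25, 0.5)
            yaw[i:i + m] = y0 + amp_y * np.sin(2 * np.pi * f_y * ts)
            amp_a = rng.uniform(0.1, 0.4) * amp
            f_a = rng.uniform(0.5, 2.0)
            ph = rng.uniform(0, 2 * np.pi, size=2)
            a_e[i:i + m, 0] = amp_a * np.sin(2 * np.pi * f_a * ts + ph[0])
            a_e[i:i + m, 1] = amp_a * np.sin(2 * np.pi * f_a * ts + ph[1])
        else:
            yaw[i:i + m] = y0
        y0 = yaw[i + m - 1]
        moving = not moving
        i += m
    return pitch, yaw, a_e


def _epoch_hand(n: int, rate: float, rng, amp: float):
    t = np.arange(n) / rate
    pitch = rng.uniform(-25.0, 25.0) + 1.5 * np.sin(2 * np.pi * 0.2 * t)
    yaw = 2.0 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
    a_e = np.zeros((n, 3))
    f_a = rng.uniform(1.5, 3.0)
    # wrist barely moves while writing/typing: amplitudes down at the
    # sensor noise floor, so some hand windows are genuinely ambiguous
    amp_a = rng.uniform(0.01, 0.04) * amp
    a_e[:, 0] = amp_a * np.sin(2 * np.pi * f_a * t)
    a_e[:, 2] = 0.7 * amp_a * np.sin(2 * np.pi * f_a * t + rng.uniform(0, 2 * np.pi))
    return pitch, yaw, a_e


def _epoch_gait(n: int, rate: float, rng, amp: float):
    t = np.arange(n) / rate
    base = rng.uniform(-78.0, -72.0)
    amp_p = rng.uniform(10.0, 14.0)
    ph = rng.uniform(0, 2 * np.pi)
    pitch = base + amp_p * np.sin(2 * np.pi * 1.0 * t + ph)
    yaw = 5.0 * np.sin(2 * np.pi * 1.0 * t + ph + np.pi / 3)
    a_e = np.zeros((n, 3))
    amp_a = rng.uniform(0.15, 0.3)
    a_e[:, 0] = amp_a * np.sin(2 * np.pi * 1.0 * t + ph)
    a_e[:, 2] = 0.5 * amp_a * np.sin(2 * np.pi * 2.0 * t + ph)
    return pitch, yaw, a_e


def _epoch_rest(n: int, rate: float, rng, amp: float):
    pitch = np.full(n, rng.uniform(-15.0, 15.0))
    return pitch, np.zeros(n), np.zeros((n, 3))


_EPOCH_BUILDERS = {"arm": _epoch_arm, "hand": _epoch_hand,
                   "gait": _epoch_gait, "rest": _epoch_rest}


def _adjusted_durations(config: SimConfig) -> list[float]:
    """Per-epoch durations, rescaled to hit the target functional share."""
    tasks = list(config.task_sequence)
    durs = [config.task_duration(t) for t in tasks]
    if config.functional_share is None:
        return durs
    kinds = [TASK_KIND[t] for t in tasks]
    f_tot = sum(d for d, k in zip(durs, kinds) if k in FUNCTIONAL_KINDS)
    n_tot = sum(d for d, k in zip(durs, kinds) if k not in FUNCTIONAL_KINDS)
    t_trans = TRANSITION_S * max(0, len(tasks) - 1)
    total = f_tot + n_tot + t_trans
    target = config.functional_share
    if f_tot == 0 or n_tot == 0:
        achieved = f_tot / total
        raise ValidationError(
            f"functional share {target} unreachable with this task mix "
            f"(achieved {achieved:.3f})")
    alpha = target * total / f_tot
    beta = (f_tot + n_tot - target * total) / n_tot
    out = []
    for d, k in zip(durs, kinds):
        scale = alpha if k in FUNCTIONAL_KINDS else beta
        out.append(d * scale)
    for d, k in zip(out, kinds):
        if k == "rest" and d < 10.0 - 1e-9:
            ach_f = alpha * f_tot
            achieved = ach_f / total
            raise ValidationError(
                f"functional share {target} unreachable: rest blocks would "
                f"shrink below 10 s (achieved {achieved:.3f})")
    if beta <= 0 or alpha <= 0:
        raise ValidationError(
            f"functional share {target} unreachable with this task mix")
    return out


def _jitter_boundaries(track: np.ndarray, rate: float, jitter_s: float,
                       rng) -> np.ndarray:
    """Shift each label transition by an annotator reaction time.

    Video annotators mark epoch starts/ends a fraction of a second early
    or late; each change point is displaced by N(0, jitter_s) while the
    segment values are preserved.
    """
    if jitter_s <= 0:
        return track.copy()
    track = np.asarray(track, dtype=int)
    edges = np.flatnonzero(np.diff(track)) + 1
    if len(edges) == 0:
        return track.copy()
    shifted = edges + np.round(rng.normal(0, jitter_s * rate,
                                          len(edges))).astype(int)
    shifted = np.clip(shifted, 1, len(track) - 1)
    shifted = np.sort(shifted)
    out = np.empty_like(track)
    bounds = [0, *shifted.tolist(), len(track)]
    value = track[0]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out[lo:hi] = value
        value = 1 - value
    return out


def simulate_arm(config: SimConfig, rng: np.random.Generator | None = None
                 ) -> tuple[ImuRecording, AnnotationSet, SimTruth]:
    """Generate one arm's recording, annotations and generating truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.rate
    tasks = list(config.task_sequence)
    durs = _adjusted_durations(config)
    n_trans = int(round(TRANSITION_S * rate))

    pitch_parts, yaw_parts, a_parts = [], [], []
    task_parts, move_parts, use_parts = [], [], []
    y_end, p_end = None, None
    for k, (task, dur) in enumerate(zip(tasks, durs)):
        kind = TASK_KIND[task]
        n = max(2, int(round(dur * rate)))
        pitch, yaw, a_e = _EPOCH_BUILDERS[kind](n, rate, rng,
                                                config.amplitude_scale)
        if k > 0:
            # shift epoch yaw near the previous heading, ramp through a
            # 1 s "unknown" transition
            yaw = yaw - yaw[0] + y_end + rng.uniform(-20.0, 20.0)
            w = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_trans) / n_trans)
            pitch_parts.append(p_end + w * (pitch[0] - p_end))
            yaw_parts.append(y_end + w * (yaw[0] - y_end))
            a_parts.append(np.zeros((n_trans, 3)))
            task_parts.append(np.repeat("unknown", n_trans))
            move_parts.append(np.repeat("NonFunctional", n_trans))
            use_parts.append(np.zeros(n_trans, dtype=int))
        pitch_parts.append(pitch)
        yaw_parts.append(yaw)
        a_parts.append(a_e)
        task_parts.append(np.repeat(task, n))
        move = {"arm": "Arm", "hand": "Hand"}.get(kind, "NonFunctional")
        move_parts.append(np.repeat(move, n))
        use_parts.append(np.full(n, int(kind in FUNCTIONAL_KINDS)))
        y_end, p_end = yaw[-1], pitch[-1]

    pitch = np.concatenate(pitch_parts)
    yaw = np.concatenate(yaw_parts)
    a_earth = np.vstack(a_parts)
    task_track = np.concatenate(task_parts)
    move_track = np.concatenate(move_parts)
    use = np.concatenate(use_parts)
    n_total = len(pitch)
    t = np.arange(n_total) / rate

    # body angular rates consistent with the scripted angles (roll = 0):
    # w_x = yaw_rate * sin(pitch), w_y = -pitch_rate, w_z = yaw_rate * cos(pitch)
    pitch_rate = np.gradient(pitch, t)
    yaw_rate = np.gradient(yaw, t)
    p_rad = np.radians(pitch)
    omega = np.column_stack([yaw_rate * np.sin(p_rad),
                             -pitch_rate,
                             yaw_rate * np.cos(p_rad)])

    quats = np.array([quat_from_euler(y_, p_) for y_, p_ in zip(yaw, pitch)])
    conj = quats * np.array([1.0, -1.0, -1.0, -1.0])
    specific_force = a_earth + np.array([0.0, 0.0, 1.0])
    accel_body = quat_rotate(conj, specific_force)
    mag_body = quat_rotate(conj, np.tile(EARTH_MAG, (n_total, 1)))

    accel = accel_body + rng.normal(0.0, config.accel_noise_sd, (n_total, 3))
    gyro = (omega + np.asarray(config.gyro_offset)
            + rng.normal(0.0, config.gyro_noise_sd, (n_total, 3)))
    mag = mag_body + rng.normal(0.0, 0.01, (n_total, 3))

    rec = ImuRecording(timestamps=t, accel=accel, gyro=gyro, mag=mag,
                       nominal_rate=rate, arm_label="right")
    truth = SimTruth(timestamps=t, pitch=pitch, yaw=yaw, use=use,
                     task=task_track, movement_type=move_track)

    t30, use30 = resample_zoh(t, use, 30.0)
    _, task30 = resample_zoh(t, task_track, 30.0)
    _, move30 = resample_zoh(t, move_track, 30.0)
    tracks = np.empty((len(t30), 4), dtype=int)
    for j in range(4):
        marked = _jitter_boundaries(use30, 30.0,
                                    config.annot_boundary_jitter_s, rng)
        flips = rng.random(len(t30)) < config.annot_flip_prob
        tracks[:, j] = np.where(flips, 1 - marked, marked)
    ann = AnnotationSet(timestamps=t30, use_tracks=tracks, task_track=task30,
                        movement_type_track=move30, rate=30.0)
    return rec, ann, truth


def simulate_cohort(n_subjects: int = 15, seed: int = 0,
                    overrides: dict | None = None,
                    base_config: SimConfig | None = None,
                    patient_fraction: float = 1.0 / 3.0,
                    ) -> tuple[list[SubjectDataset], dict]:
    """Generate a cohort of two-arm subjects.

    Roughly one third of the cohort are "patients": their affected arm is
    generated with a reduced functional share and attenuated movement
    amplitude. Returns ``(subjects, truths)`` where ``truths`` maps
    ``(subject_id, arm_label)`` to the arm's :class:`SimTruth`.

    ``overrides`` maps subject id -> dict of SimConfig field overrides
    applied to both arms of that subject.
    """
    if n_subjects < 1:
        raise ValidationError("need at least one subject")
    base = base_config if base_config is not None else SimConfig()
    n_patients = int(round(n_subjects * patient_fraction))
    subjects, truths = [], {}
    for i in range(n_subjects):
        sid = f"s{i + 1:02d}"
        is_patient = i >= n_subjects - n_patients
        group = "patient" if is_patient else "control"
        arm_labels = (("affected", "unaffected") if is_patient
                      else ("left", "right"))
        arms = {}
        for a, arm_label in enumerate(arm_labels):
            cfg = replace(base)
            if is_patient and arm_label == "affected":
                cfg = replace(cfg, amplitude_scale=0.5 * base.amplitude_scale,
                              functional_share=0.3)
            if overrides and sid in overrides:
                cfg = replace(cfg, **overrides[sid])
            rng = np.random.default_rng(np.random.SeedSequence((seed, i, a)))
            # shuffle task order per arm for variety
            order = list(cfg.task_sequence)
            rng.shuffle(order)
            cfg = replace(cfg, task_sequence=tuple(order))
            rec, ann, truth = simulate_arm(cfg, rng)
            rec.arm_label = arm_label
            arms[arm_label] = ArmData(rec, ann)
            truths[(sid, arm_label)] = truth
        subjects.append(SubjectDataset(sid, group, arms))
    return subjects, truths
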