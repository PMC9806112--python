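"""The four non-learning use measures: VM, AC, GM and GMAC."""

import numpy as np
import pytest

from conftest import static_recording
from limbuse.data_model import ValidationError
from limbuse.orientation import OrientationSeries, estimate_orientation
from limbuse.simulate import SimConfig, simulate_arm
from limbuse.traditional import (CountsSignal, activity_counts, deadband,
                                 gm_use, gmac_use, laterality_use,
                                 quantize_counts, vector_magnitude_counts,
                                 vm_use)

RATE = 50.0


def _orientation_window(yaw, pitch, rate=RATE):
    n = len(yaw)
    t = np.arange(n) / rate
    q = np.tile([1.0, 0, 0, 0], (n, 1))  # quaternions unused by gm_use
    return OrientationSeries(t, q, np.asarray(yaw, float),
                             np.asarray(pitch, float), rate)


class TestElementaryOps:
    @pytest.mark.parametrize("x, expected", [
        (0.05, 0.0), (0.10, 0.10), (0.0, 0.0), (-0.05, 0.0), (-0.2, -0.2),
    ])
    def test_deadband(self, x, expected):
        assert deadband(np.array([x]))[0] == expected

    @pytest.mark.parametrize("x, expected", [
        (0.034, 2), (0.0169, 0), (0.0, 0), (0.017, 1), (0.1, 5),
    ])
    def test_quantize(self, x, expected):
        assert quantize_counts(np.array([x]))[0] == expected

    def test_quantize_rejects_negative(self):
        with pytest.raises(ValidationError):
            quantize_counts(np.array([-0.1]))


class TestVectorMagnitude:
    def test_static_recording_counts_near_zero(self):
        rec = static_recording(pose=(0.2, 0.1, 0.97), seed=3)
        counts = vector_magnitude_counts(rec)
        assert counts.counts.max() < 0.01

    def test_inband_shake_gives_positive_counts(self, sim_arm_default):
        rec, _, truth = sim_arm_default
        counts = vector_magnitude_counts(rec)
        # counts over the moving (arm-task) stretches must be positive
        arm_windows = [i for i, t in enumerate(counts.timestamps)
                       if truth.task[int(min(t, truth.timestamps[-1]) * RATE)]
                       in ("drinkcup", "openbottle")]
        active = counts.counts[arm_windows]
        assert (active > 0).mean() > 0.8

    def test_output_rate_is_one_hz(self):
        rec = static_recording(n=3000)
        counts = vector_magnitude_counts(rec)
        np.testing.assert_allclose(np.diff(counts.timestamps), 1.0)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValidationError):
            vector_magnitude_counts(static_recording(n=100))


class TestVmUse:
    def test_zero_threshold_rule(self):
        c = CountsSignal(np.arange(3.0), np.array([0.0, 0.3, 5.0]))
        np.testing.assert_array_equal(vm_use(c).values, [0, 1, 1])

    def test_all_zero_counts(self):
        c = CountsSignal(np.arange(4.0), np.zeros(4))
        assert vm_use(c).values.sum() == 0


class TestActivityCounts:
    def test_static_recording_counts_all_zero(self):
        rec = static_recording(pose=(0.1, -0.2, 0.97), seed=7)
        counts = activity_counts(rec)
        assert counts.counts.max() == 0

    def test_counts_are_nonnegative_integers(self, sim_arm_default):
        rec, _, _ = sim_arm_default
        counts = activity_counts(rec)
        assert np.issubdtype(counts.counts.dtype, np.integer)
        assert counts.counts.min() >= 0
        assert counts.counts.max() >= 1  # movement present in the default mix

    def test_missing_magnetometer_names_9dof(self):
        rec = static_recording(with_mag=False)
        with pytest.raises(ValidationError, match="9-DOF"):
            activity_counts(rec)


class TestLaterality:
    def _counts(self, values):
        return CountsSignal(np.arange(len(values), dtype=float),
                            np.asarray(values, float))

    def test_exclusive_dominant_movement(self):
        res = laterality_use(self._counts([10.0]), self._counts([0.0]))
        assert res.laterality_index[0] == 1.0
        assert res.use_dominant.values[0] == 1
        assert res.use_nondominant.values[0] == 0

    def test_bimanual_movement_flags_both(self):
        res = laterality_use(self._counts([5.0]), self._counts([5.0]))
        assert res.laterality_index[0] == 0.0
        assert res.use_dominant.values[0] == 1
        assert res.use_nondominant.values[0] == 1

    def test_no_movement_flags_neither(self):
        res = laterality_use(self._counts([0.0]), self._counts([0.0]))
        assert np.isnan(res.laterality_index[0])
        assert res.use_dominant.values[0] == 0
        assert res.use_nondominant.values[0] == 0

    def test_grid_mismatch_rejected(self):
        a = self._counts([1.0, 2.0])
        b = CountsSignal(np.array([0.5, 1.5]), np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            laterality_use(a, b)


class TestGrossMovement:
    def test_moving_window_in_functional_space_scores_one(self):
        t = np.arange(100) / RATE
        yaw = 12.5 * np.sin(2 * np.pi * 0.5 * t)       # range 25 deg
        pitch = 5.0 + 7.5 * np.sin(2 * np.pi * 0.5 * t)  # range 15, mean 5
        use = gm_use(_orientation_window(yaw, pitch))
        assert use.values[0] == 1

    def test_same_motion_out_of_functional_space_scores_zero(self):
        t = np.arange(100) / RATE
        yaw = 20.0 * np.sin(2 * np.pi * 0.5 * t)
        pitch = 60.0 + 10.0 * np.sin(2 * np.pi * 0.5 * t)
        use = gm_use(_orientation_window(yaw, pitch))
        assert use.values[0] == 0

    def test_still_window_scores_zero(self):
        use = gm_use(_orientation_window(np.zeros(100), np.full(100, 5.0)))
        assert use.values[0] == 0

    def test_two_hz_output(self):
        n = int(60 * RATE)
        t = np.arange(n) / RATE
        yaw = 40.0 * np.sin(2 * np.pi * 0.3 * t)
        use = gm_use(_orientation_window(yaw, np.zeros(n)))
        np.testing.assert_allclose(np.diff(use.timestamps), 0.5)
        assert use.rate == 2.0

    def test_yaw_wraparound_not_a_spurious_movement(self):
        # heading sitting at the +-180 deg seam, barely moving
        yaw = np.where(np.arange(100) % 2 == 0, 179.0, -179.0)
        use = gm_use(_orientation_window(yaw, np.zeros(100)))
        assert use.values[0] == 0

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            gm_use(_orientation_window(np.zeros(50), np.zeros(50)))


class TestGmac:
    def _counts(self, values, t0=1.0):
        return CountsSignal(t0 + np.arange(len(values), dtype=float),
                            np.asarray(values, float))

    def _pitch(self, deg, seconds=4):
        n = int(seconds * RATE)
        return np.arange(n) / RATE, np.full(n, float(deg))

    def test_counts_and_pitch_in_band_scores_one(self):
        pt, pv = self._pitch(5.0)
        use = gmac_use(self._counts([3.0]), pt, pv)
        assert use.values[0] == 1

    def test_pitch_out_of_band_scores_zero(self):
        pt, pv = self._pitch(-60.0)
        use = gmac_use(self._counts([3.0]), pt, pv)
        assert use.values[0] == 0

    def test_zero_counts_scores_zero(self):
        pt, pv = self._pitch(0.0)
        use = gmac_use(self._counts([0.0]), pt, pv)
        assert use.values[0] == 0

    def test_span_mismatch_rejected(self):
        pt, pv = self._pitch(0.0, seconds=1)
        with pytest.raises(ValidationError):
            gmac_use(self._counts([1.0, 1.0, 1.0], t0=5.0), pt, pv)


class TestCrossMeasureProperties:
    def test_gmac_never_exceeds_vm_use(self, sim_arm_default):
        rec, _, _ = sim_arm_default
        counts = vector_magnitude_counts(rec)
        orient = estimate_orientation(rec.timestamps, rec.accel, rec.gyro,
                                      rate=RATE)
        vm = vm_use(counts)
        gmac = gmac_use(counts, orient.timestamps, orient.pitch)
        assert np.all(gmac.values <= vm.values)

    def test_gait_only_segment_vm_fires_gm_and_gmac_silent(self):
        cfg = SimConfig(task_sequence=("walk",), durations={"gait": 40.0},
                        seed=2)
        rec, _, _ = simulate_arm(cfg)
        counts = vector_magnitude_counts(rec)
        orient = estimate_orientation(rec.timestamps, rec.accel, rec.gyro,
                                      rate=RATE)
        assert gm_use(orient).values.sum() == 0
        assert gmac_use(counts, orient.timestamps, orient.pitch).values.sum() == 0
        assert vm_use(counts).values.mean() > 0.5
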