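import numpy as np
import pytest

from armreach import arm_model as am
from armreach import measurement as me
from armreach.exceptions import InvalidArgumentError, OnsetDetectionError
from armreach.synthetic import SynthConfig, make_task, synth_measurement


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        series = np.full((500, 2), 1.234)
        out = me.lowpass_filter(series, fs=200.0)
        np.testing.assert_allclose(out, series, atol=1e-9)

    def test_passband_tone_preserved(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = me.lowpass_filter(x, fs=200.0)
        core = slice(400, -400)  # ignore transients
        attenuation = 1.0 - np.max(np.abs(y[core])) / np.max(np.abs(x[core]))
        assert abs(attenuation) < 0.01

    def test_stopband_tone_crushed(self):
        t = np.arange(4000) / 200.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = me.lowpass_filter(x, fs=200.0)
        assert np.max(np.abs(y[400:-400])) < 0.01

    def test_zero_phase_keeps_pulse_centred(self):
        x = np.zeros(1001)
        x[480:521] = np.hanning(41)
        y = me.lowpass_filter(x, fs=200.0)
        com_in = np.sum(np.arange(x.size) * x) / np.sum(x)
        com_out = np.sum(np.arange(y.size) * np.abs(y)) / np.sum(np.abs(y))
        assert abs(com_out - com_in) < 1.0  # less than one sample

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            me.lowpass_filter(np.zeros(10), fs=200.0)

    def test_sampling_rate_must_exceed_twice_cutoff(self):
        with pytest.raises(InvalidArgumentError):
            me.lowpass_filter(np.zeros(100), fs=15.0, cutoff=10.0)


class TestDetectOnsetOffset:
    def test_noiseless_detection_is_sample_accurate(self, arm):
        task = make_task("T41")
        cfg = SynthConfig(task=task, noise_sigma=0.0, seed=0)
        rec, truth = synth_measurement(cfg, arm)
        onset, offset = me.detect_onset_offset(rec.fingertip, rec.fs)
        # at rest the speed vanishes, so curvature is degenerate (treated as
        # resting) and detection lands within a couple of samples of truth
        assert abs(onset - truth.onset_index) <= 2
        assert abs(offset - truth.offset_index) <= 2

    def test_no_interior_false_trigger_on_straight_path(self, arm):
        # a straight constant-direction path has zero curvature at speed, so
        # the detected interval must contain the whole high-speed phase
        task = make_task("T31")
        rec, truth = synth_measurement(
            SynthConfig(task=task, noise_sigma=0.0003, seed=5), arm)
        filtered = me.lowpass_filter(rec.fingertip, rec.fs)
        onset, offset = me.detect_onset_offset(filtered, rec.fs)
        v = np.gradient(filtered, 1 / rec.fs, axis=0, edge_order=2)
        speed = np.hypot(v[:, 0], v[:, 1])
        fast = np.flatnonzero(speed > 0.5 * speed.max())
        assert onset < fast[0] and offset > fast[-1]

    def test_infinite_threshold_fails_loudly(self, arm):
        task = make_task("T41")
        rec, _ = synth_measurement(SynthConfig(task=task, noise_sigma=0.0, seed=0), arm)
        with pytest.raises(OnsetDetectionError) as exc:
            me.detect_onset_offset(rec.fingertip, rec.fs, threshold=np.inf)
        assert exc.value.side == "onset"

    def test_onset_precedes_offset(self, arm):
        task = make_task("T24")
        rec, _ = synth_measurement(
            SynthConfig(task=task, noise_sigma=0.0005, seed=3), arm)
        filtered = me.lowpass_filter(rec.fingertip, rec.fs)
        onset, offset = me.detect_onset_offset(filtered, rec.fs)
        assert onset < offset


class TestMarkersToAngles:
    def test_collinear_markers_give_zero_angles(self):
        markers = np.zeros((5, 4, 2))
        markers[:, 1, 0] = 0.28
        markers[:, 2, 0] = 0.52
        markers[:, 3, 0] = 0.71
        rec = me.MarkerRecording(fs=200.0, markers=markers)
        np.testing.assert_allclose(me.markers_to_angles(rec), 0.0, atol=1e-15)

    def test_fk_roundtrip(self, arm, rng):
        theta = rng.uniform([-1.0, 0.2, -1.0], [1.5, 2.5, 1.0], size=(40, 3))
        elbow, wrist, tip = am.forward_kinematics(theta, arm)
        markers = np.stack([np.zeros((40, 2)), elbow, wrist, tip], axis=1)
        rec = me.MarkerRecording(fs=200.0, markers=markers)
        np.testing.assert_allclose(me.markers_to_angles(rec), theta, atol=1e-10)

    def test_global_rotation_shifts_shoulder_angle_only(self, arm):
        theta = np.array([[0.4, 1.2, 0.3]])
        elbow, wrist, tip = am.forward_kinematics(theta, arm)
        markers = np.stack([np.zeros((1, 2)), elbow, wrist, tip], axis=1)
        phi = 0.6
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = markers @ R.T
        base = me.markers_to_angles(me.MarkerRecording(fs=200.0, markers=markers))
        rot = me.markers_to_angles(me.MarkerRecording(fs=200.0, markers=rotated))
        np.testing.assert_allclose(rot[0, 0] - base[0, 0], phi, atol=1e-12)
        np.testing.assert_allclose(rot[0, 1:], base[0, 1:], atol=1e-12)

    def test_coincident_markers_rejected(self):
        markers = np.zeros((3, 4, 2))
        markers[:, 2:, 0] = 0.5  # elbow == shoulder
        with pytest.raises(InvalidArgumentError, match="degenerate"):
            me.markers_to_angles(me.MarkerRecording(fs=200.0, markers=markers))


class TestRmsErrors:
    def _movement(self, t, xy, theta):
        return t, xy, theta

    def test_identical_inputs_zero(self):
        t = np.linspace(0, 1, 101)
        xy = np.stack([t, t ** 2], axis=1)
        theta = np.stack([t, 2 * t, 3 * t], axis=1)
        f, j = me.rms_errors(t, xy, theta, t, xy, theta)
        assert f == 0.0 and j == 0.0

    def test_constant_fingertip_offset(self):
        t = np.linspace(0, 1, 101)
        xy = np.stack([t, np.zeros_like(t)], axis=1)
        theta = np.zeros((101, 3))
        f, _ = me.rms_errors(t, xy, theta, t, xy + [0.01, 0.0], theta)
        assert f == pytest.approx(0.01, rel=1e-9)

    def test_invariant_to_sampling_rate(self):
        t = np.linspace(0, 1, 401)
        xy = np.stack([np.sin(t), np.cos(t)], axis=1)
        theta = np.stack([t, t ** 2, np.sin(t)], axis=1)
        f1, j1 = me.rms_errors(t, xy, theta, t[::4], xy[::4], theta[::4])
        assert f1 < 1e-4 and j1 < 1e-4

    def test_symmetric_in_arguments(self, rng):
        t1 = np.linspace(0, 1, 101)
        t2 = np.linspace(0, 0.8, 81)
        xy1 = rng.normal(0, 1, (101, 2)).cumsum(axis=0) * 0.01
        xy2 = rng.normal(0, 1, (81, 2)).cumsum(axis=0) * 0.01
        th1 = rng.normal(0, 1, (101, 3)).cumsum(axis=0) * 0.01
        th2 = rng.normal(0, 1, (81, 3)).cumsum(axis=0) * 0.01
        a = me.rms_errors(t1, xy1, th1, t2, xy2, th2)
        b = me.rms_errors(t2, xy2, th2, t1, xy1, th1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_per_joint_reporting(self):
        t = np.linspace(0, 1, 101)
        xy = np.zeros((101, 2))
        theta = np.zeros((101, 3))
        shifted = theta + [0.1, 0.0, 0.0]
        _, per_joint = me.rms_errors(t, xy, theta, t, xy, shifted, per_joint=True)
        np.testing.assert_allclose(per_joint, [0.1, 0.0, 0.0], atol=1e-12)


class TestProcessRecording:
    def test_end_to_end_crop(self, arm):
        task = make_task("T41")
        rec, truth = synth_measurement(
            SynthConfig(task=task, noise_sigma=0.0003, seed=1,
                        wrist_delta=np.deg2rad(15)), arm)
        mv = me.process_recording(rec, task)
        assert mv.onset_index < mv.offset_index
        assert mv.movement_time > 0
        assert mv.traj.theta.shape[0] == mv.offset_index - mv.onset_index + 1
        # detected interval sits inside the recording and near the truth
        assert abs(mv.onset_index - truth.onset_index) < 0.05 * rec.fs
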