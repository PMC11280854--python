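import numpy as np
import pytest

from armsign import synth
from armsign.kinematics import EulerAngles, Quaternion, euler_to_quaternion
from armsign.segmentation import (
    Segment,
    SegmenterConfig,
    emg_motion,
    imu_motion,
    min_duration_filter,
    quiet_frames_to_close,
    segment_stream,
    segments_to_tsv,
)
from armsign.synth import ArmbandStream, EmgFrame, ImuFrame


def make_stream(device, emg_rows, n_imu=None, quats=None):
    """EMG-driven stream with quiet IMU unless quaternions are supplied."""
    emg = np.asarray(emg_rows, dtype=np.int16)
    n_emg = len(emg)
    if n_imu is None:
        n_imu = max(2, n_emg // 4)
    if quats is None:
        quats = np.tile([1.0, 0.0, 0.0, 0.0], (n_imu, 1))
    return ArmbandStream(
        device_id=device,
        emg_t=np.arange(n_emg) / 200.0,
        emg=emg,
        imu_t=np.arange(n_imu) / 50.0,
        accel=np.tile([0.0, 0.0, 1.0], (n_imu, 1)),
        gyro=np.zeros((n_imu, 3)),
        quat=np.asarray(quats, dtype=float),
    )


def quiet_pair(n_frames=100):
    zeros = np.zeros((n_frames, 8))
    return make_stream("left", zeros), make_stream("right", zeros)


class TestEmgMotion:
    def test_threshold_reached_on_one_channel(self):
        prev = np.zeros(8)
        curr = np.zeros(8)
        curr[3] = 40
        assert emg_motion(prev, curr, 40) is True

    def test_identical_frames_quiet(self):
        frame = np.array([5, -3, 0, 0, 7, 1, 2, 9])
        assert emg_motion(frame, frame, 1) is False

    def test_frame_objects_accepted(self):
        a = EmgFrame(0.0, np.zeros(8, dtype=int))
        b = EmgFrame(0.005, np.array([0, 0, 0, 0, 0, 0, 0, 50]))
        assert emg_motion(a, b, 40) is True

    def test_brute_force_oracle_1000_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            prev = rng.integers(-127, 129, 8)
            curr = rng.integers(-127, 129, 8)
            threshold = int(rng.integers(0, 257))
            expected = any(abs(int(curr[c]) - int(prev[c])) >= threshold for c in range(8))
            assert emg_motion(prev, curr, threshold) == expected

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError):
            emg_motion(np.zeros(8), np.zeros(4), 40)


def imu_frame(t, roll=0.0, pitch=0.0, yaw=0.0):
    return ImuFrame(t, np.zeros(3), np.zeros(3), euler_to_quaternion(EulerAngles(roll, pitch, yaw)))


class TestImuMotion:
    def test_no_change_is_quiet(self):
        f = imu_frame(0.0, 10, 5, -20)
        assert imu_motion(f, imu_frame(0.02, 10, 5, -20), 20) is False

    def test_pure_yaw_90_mean_30(self):
        assert imu_motion(imu_frame(0.0), imu_frame(0.02, yaw=90), 20) is True
        assert imu_motion(imu_frame(0.0), imu_frame(0.02, yaw=90), 30) is False  # strict >

    def test_opposite_changes_cancel_in_literal_mean(self):
        prev = imu_frame(0.0)
        curr = imu_frame(0.02, roll=30, pitch=-30)
        assert imu_motion(prev, curr, 20) is False
        assert imu_motion(prev, curr, 20, mean_of_abs=True) is False  # mean |d| = 20, strict >
        assert imu_motion(prev, curr, 19, mean_of_abs=True) is True

    def test_degenerate_quaternion_rejected(self):
        bad = ImuFrame(0.0, np.zeros(3), np.zeros(3), Quaternion(0, 0, 0, 0))
        with pytest.raises(ValueError):
            imu_motion(bad, imu_frame(0.02), 20)


class TestQuietRunArithmetic:
    def test_pause_60ms_at_200hz_is_12_frames(self):
        assert quiet_frames_to_close(SegmenterConfig(pause_ms=60)) == 12

    def burst_then_quiet(self, n_quiet):
        rows = [[0] * 8]
        for i in range(100):  # 0.5 s alternating burst, every delta = 100
            rows.append([100 * ((i + 1) % 2)] * 8)
        last = rows[-1]
        rows.extend([last] * n_quiet)
        left = make_stream("left", rows)
        right = make_stream("right", np.zeros((len(rows), 8)))
        return left, right

    def test_exactly_12_quiet_frames_close_the_sign(self):
        cfg = SegmenterConfig(pause_ms=60)
        segs = segment_stream(self.burst_then_quiet(12), cfg)
        assert len(segs) == 1
        assert segs[0].closed_by_pause is True

    def test_11_quiet_frames_do_not(self):
        cfg = SegmenterConfig(pause_ms=60)
        segs = segment_stream(self.burst_then_quiet(11), cfg)
        assert len(segs) == 1
        assert segs[0].closed_by_pause is False  # only end-of-stream closed it


class TestSegmentStream:
    def test_all_constant_session_has_no_segments(self):
        assert segment_stream(quiet_pair(), SegmenterConfig()) == []

    def test_empty_stream_is_empty_result(self):
        empty = np.zeros((0, 8))
        left = make_stream("left", empty, n_imu=2)
        right = make_stream("right", empty, n_imu=2)
        assert segment_stream((left, right), SegmenterConfig()) == []

    def test_misordered_timestamps_rejected(self):
        left, right = quiet_pair()
        left.emg_t = left.emg_t[::-1].copy()
        with pytest.raises(ValueError):
            segment_stream((left, right), SegmenterConfig())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_session_annotations_within_one_imu_frame(self, seed):
        templates = synth.make_sign_templates(3, seed=seed)
        session = synth.synthesize_session(templates, reps=2, rest_ms=400, seed=seed, noise_level=0.25)
        segs = segment_stream(session, SegmenterConfig())
        assert len(segs) == len(session.annotations)
        for ann, seg in zip(session.annotations, segs):
            assert abs(seg.start_t - ann.start_t) <= 0.02 + 1e-9
            assert abs(seg.end_t - ann.end_t) <= 0.02 + 1e-9

    def test_segments_disjoint_and_ordered(self):
        templates = synth.make_sign_templates(4, seed=9)
        session = synth.synthesize_session(templates, reps=2, rest_ms=300, seed=9)
        segs = segment_stream(session, SegmenterConfig())
        for a, b in zip(segs, segs[1:]):
            assert a.end_t <= b.start_t

    def test_invariant_under_appended_quiet_frames(self):
        templates = synth.make_sign_templates(2, seed=5)
        session = synth.synthesize_session(templates, reps=1, rest_ms=400, seed=5)
        base = segment_stream(session, SegmenterConfig())

        def extend(arm):
            n_extra_imu = 50
            n_extra_emg = 4 * n_extra_imu
            return ArmbandStream(
                device_id=arm.device_id,
                emg_t=np.arange(arm.n_emg + n_extra_emg) / 200.0,
                emg=np.vstack([arm.emg, np.tile(arm.emg[-1], (n_extra_emg, 1))]),
                imu_t=np.arange(arm.n_imu + n_extra_imu) / 50.0,
                accel=np.vstack([arm.accel, np.tile(arm.accel[-1], (n_extra_imu, 1))]),
                gyro=np.vstack([arm.gyro, np.tile(arm.gyro[-1], (n_extra_imu, 1))]),
                quat=np.vstack([arm.quat, np.tile(arm.quat[-1], (n_extra_imu, 1))]),
            )

        extended = segment_stream((extend(session.left), extend(session.right)), SegmenterConfig())
        assert [(s.start_t, s.end_t) for s in extended] == [(s.start_t, s.end_t) for s in base]

    def test_slices_cover_half_open_window(self):
        templates = synth.make_sign_templates(1, seed=6)
        session = synth.synthesize_session(templates, reps=1, rest_ms=300, seed=6)
        seg = segment_stream(session, SegmenterConfig())[0]
        fs, x = seg.channels[("left", "emg0")]
        t = session.left.emg_t
        expected = session.left.emg[(t >= seg.start_t - 1e-12) & (t < seg.end_t - 1e-12), 0]
        assert np.array_equal(x, expected.astype(float))
        fs_q, q = seg.channels[("right", "quat_w")]
        ti = session.right.imu_t
        n_expected = int(np.count_nonzero((ti >= seg.start_t - 1e-12) & (ti < seg.end_t - 1e-12)))
        assert len(q) == n_expected

    def test_brute_force_rescan_oracle(self):
        """Frame-by-frame scalar re-scan reproduces boundaries exactly."""
        templates = synth.make_sign_templates(2, seed=11)
        session = synth.synthesize_session(templates, reps=2, rest_ms=300, seed=11, noise_level=0.3)
        cfg = SegmenterConfig()

        events = []
        for arm in (session.left, session.right):
            prev = None
            for frame in arm.emg_frames():
                if prev is not None:
                    events.append((frame.t, emg_motion(prev, frame, cfg.emg_threshold), "emg"))
                prev = frame
            prev = None
            for frame in arm.imu_frames():
                if prev is not None:
                    events.append((frame.t, imu_motion(prev, frame, cfg.imu_threshold), "imu"))
                prev = frame
        events.sort(key=lambda e: (e[0], not e[1]))
        pause = cfg.pause_ms / 1000.0
        expected = []
        start = last = None
        for t, motion, src in events:
            if motion:
                if start is None:
                    start = t - (0.005 if src == "emg" else 0.02)
                last = t
            elif start is not None and t - last >= pause - 1e-12:
                expected.append((start, last + 0.005))
                start = None
        if start is not None:
            expected.append((start, last + 0.005))
        expected = [(s, e) for s, e in expected if e - s >= cfg.min_record_s - 1e-12]

        got = [(s.start_t, s.end_t) for s in segment_stream(session, cfg)]
        assert got == pytest.approx(expected)


class TestMinDurationFilter:
    def _seg(self, start, end):
        return Segment(start, end, "emg", {})

    def test_paper_default(self):
        segs = [self._seg(0.0, 0.3), self._seg(1.0, 1.5)]
        kept = min_duration_filter(segs, 0.4)
        assert [s.duration for s in kept] == pytest.approx([0.5])

    def test_zero_min_is_identity(self):
        segs = [self._seg(0, 0.1), self._seg(1, 1.2)]
        assert min_duration_filter(segs, 0.0) == segs

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        segs = [self._seg(0, float(d)) for d in rng.uniform(0, 1, 200)]
        kept = min_duration_filter(segs, 0.4)
        assert len(kept) == sum(1 for s in segs if s.duration >= 0.4 - 1e-12)

    def test_discard_logs_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="armsign.segmentation"):
            min_duration_filter([self._seg(0, 0.1)], 0.4)
        assert any("discarding" in r.message for r in caplog.records)


class TestConfigAndSerialization:
    def test_defaults(self):
        cfg = SegmenterConfig()
        assert (cfg.emg_threshold, cfg.imu_threshold, cfg.pause_ms, cfg.min_record_s) == (40, 20.0, 60.0, 0.4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"emg_threshold": -1},
            {"emg_threshold": 300},
            {"imu_threshold": 400},
            {"pause_ms": 10},
            {"pause_ms": 2000},
            {"min_record_s": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmenterConfig(**kwargs)

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError):
            SegmenterConfig.from_mapping({"emg_thresh": 40})

    def test_tsv_dump(self):
        seg = Segment(0.5, 1.25, "emg", {}, label="hello")
        text = segments_to_tsv([seg])
        assert text.splitlines()[0] == "start_s\tend_s\ttrigger_source\tlabel"
        assert "0.500000\t1.250000\temg\thello" in text
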