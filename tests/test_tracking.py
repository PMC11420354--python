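"""Chloroplast detection/linking and pose/velocity estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glidekymo as gk
from glidekymo.tracking import moving_average

from conftest import make_small_scenario, run_pipeline


def _centers_by_frame(detections):
    out = {}
    for d in detections:
        out.setdefault(d.frame, []).append(np.array(d.center))
    return out


class TestDetection:
    def test_noise_free_blobs_within_quarter_pixel(self):
        sc = make_small_scenario()
        stack, truth = gk.generate_gliding_movie(sc)
        dets = gk.detect_chloroplasts(stack, 6.0)
        by_frame = _centers_by_frame(dets)
        px = sc.pixel_size
        for i in range(stack.n_frames):
            c = truth.center_um[i] / px
            a = np.array([np.cos(np.radians(truth.angle_deg[i])),
                          -np.sin(np.radians(truth.angle_deg[i]))])
            expected = [c + off / px * a for off in sc.chloroplast_offsets]
            found = by_frame[i]
            assert len(found) == 2
            for e in expected:
                err = min(np.linalg.norm(f - e) for f in found)
                assert err < 0.25

    @pytest.mark.parametrize("diameter", [4.5, 6.0])
    def test_paper_diameter_range_accepted(self, diameter):
        sc = make_small_scenario(duration=0.2)
        stack, _ = gk.generate_gliding_movie(sc)
        assert len(gk.detect_chloroplasts(stack, diameter)) > 0

    def test_out_of_range_diameter_rejected(self):
        sc = make_small_scenario(duration=0.2)
        stack, _ = gk.generate_gliding_movie(sc)
        with pytest.raises(ValueError):
            gk.detect_chloroplasts(stack, 3.0)

    def test_blank_frame_becomes_gap_not_error(self):
        sc = make_small_scenario(duration=1.0)
        stack, _ = gk.generate_gliding_movie(sc)
        stack.data[4] = 0.0  # blank out one frame
        dets = gk.detect_chloroplasts(stack, 6.0)
        frames = {d.frame for d in dets}
        assert 4 not in frames
        ta, tb = gk.link_tracks(dets, stack.n_frames)
        assert ta.gap[4] and tb.gap[4]

    def test_all_blank_stack_raises(self):
        blank = gk.CalibratedStack(
            np.zeros((3, 2, 64, 64), dtype=np.float32), 0.13, 0.1, ("gfp", "chloroplast")
        )
        with pytest.raises(ValueError, match="no chloroplast"):
            gk.detect_chloroplasts(blank, 6.0)


class TestLinking:
    def test_rigid_motion_keeps_constant_separation(self):
        sc = make_small_scenario()
        stack, _ = gk.generate_gliding_movie(sc)
        ta, tb = gk.link_tracks(gk.detect_chloroplasts(stack, 6.0), stack.n_frames)
        sep = np.linalg.norm(ta.centers - tb.centers, axis=1)
        assert np.ptp(sep) < 0.5

    def test_single_frame_input(self):
        dets = [
            gk.SpotDetection(0, (10.0, 20.0), 40.0, 100.0),
            gk.SpotDetection(0, (60.0, 20.0), 40.0, 90.0),
        ]
        ta, tb = gk.link_tracks(dets, 1)
        assert len(ta.centers) == 1 and len(tb.centers) == 1
        # deterministic fallback order: ascending x
        assert ta.centers[0, 0] < tb.centers[0, 0]

    def test_gap_closed_by_interpolation_and_flagged(self):
        dets = []
        for t in range(10):
            if t in (4, 5, 6):
                continue
            dets.append(gk.SpotDetection(t, (10.0 + t, 10.0), 10.0, 100.0))
            dets.append(gk.SpotDetection(t, (10.0 + t, 40.0), 10.0, 100.0))
        ta, tb = gk.link_tracks(dets, 10, max_gap=5)
        for tr in (ta, tb):
            assert list(np.where(tr.gap)[0]) == [4, 5, 6]
            np.testing.assert_allclose(tr.centers[:, 0], 10.0 + np.arange(10), atol=1e-9)

    def test_gap_longer_than_budget_raises(self):
        dets = []
        for t in (0, 9):
            dets.append(gk.SpotDetection(t, (10.0 + t, 10.0), 10.0, 100.0))
            dets.append(gk.SpotDetection(t, (10.0 + t, 40.0), 10.0, 100.0))
        with pytest.raises(ValueError, match="max_gap"):
            gk.link_tracks(dets, 10, max_gap=5)


class TestCellPose:
    def test_horizontal_pair(self):
        ta = gk.ChloroplastTrack("a", np.array([[10.0, 10.0]]), np.array([False]))
        tb = gk.ChloroplastTrack("b", np.array([[30.0, 10.0]]), np.array([False]))
        pose = gk.compute_cell_pose(ta, tb)
        np.testing.assert_allclose(pose.center[0], [20.0, 10.0])
        assert pose.angle_deg[0] == pytest.approx(0.0)

    def test_diagonal_pair_uses_math_convention(self):
        # y grows downward, so (0,0)->(10,10) points down-right: -45 deg CCW
        ta = gk.ChloroplastTrack("a", np.array([[0.0, 0.0]]), np.array([False]))
        tb = gk.ChloroplastTrack("b", np.array([[10.0, 10.0]]), np.array([False]))
        pose = gk.compute_cell_pose(ta, tb)
        np.testing.assert_allclose(pose.center[0], [5.0, 5.0])
        assert pose.angle_deg[0] == pytest.approx(-45.0)

    def test_angle_wraps_to_half_open_interval(self):
        ta = gk.ChloroplastTrack("a", np.array([[0.0, 0.0]]), np.array([False]))
        tb = gk.ChloroplastTrack("b", np.array([[-10.0, 0.0]]), np.array([False]))
        pose = gk.compute_cell_pose(ta, tb)
        assert pose.angle_deg[0] == pytest.approx(0.0)  # 180 wraps to 0

    def test_gap_frames_marked_invalid(self):
        ta = gk.ChloroplastTrack("a", np.zeros((3, 2)), np.array([False, True, False]))
        tb = gk.ChloroplastTrack("b", np.ones((3, 2)), np.array([False, False, False]))
        pose = gk.compute_cell_pose(ta, tb)
        assert list(pose.valid) == [True, False, True]

    def test_full_movie_pose_recovery(self):
        sc = make_small_scenario(trajectory=[(0.0, 4.0, 2.0, 10.0)], fov=(160, 320))
        run = run_pipeline(sc)
        truth = run["truth"]
        err_px = np.linalg.norm(
            run["pose"].center * sc.pixel_size - truth.center_um, axis=1
        ) / sc.pixel_size
        assert err_px.max() < 0.5
        ang_err = np.abs(run["pose"].angle_deg - truth.angle_deg)
        assert ang_err.max() < 1.0

    def test_rotation_equivariance(self):
        sc = make_small_scenario(duration=1.0, trajectory=[(0.0, 1.0, 2.0, 20.0)], fov=(200, 200))
        stack, _ = gk.generate_gliding_movie(sc)
        pose = gk.compute_cell_pose(
            *gk.link_tracks(gk.detect_chloroplasts(stack, 6.0), stack.n_frames)
        )
        rotated = gk.CalibratedStack(
            np.rot90(stack.data, axes=(2, 3)).copy(),
            stack.pixel_size, stack.frame_interval, stack.channels,
        )
        pose_r = gk.compute_cell_pose(
            *gk.link_tracks(gk.detect_chloroplasts(rotated, 6.0), rotated.n_frames)
        )
        delta = (pose_r.angle_deg - pose.angle_deg - 90.0) % 180.0
        delta = np.minimum(delta, 180.0 - delta)
        assert np.abs(delta).max() < 1.0


class TestVelocityTrace:
    def test_constant_motion(self):
        centers = np.stack([np.arange(41) * 0.2 / 0.13, np.full(41, 10.0)], axis=1)
        pose = gk.CellPose(centers, np.zeros(41), np.ones(41, bool))
        trace = gk.compute_velocity_trace(pose, 0.13, 0.1, window=20)
        np.testing.assert_allclose(trace.speed, 2.0, rtol=1e-9)
        np.testing.assert_allclose(trace.smoothed, 2.0, rtol=1e-9)

    def test_smoother_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([np.zeros(30), np.full(40, 2.0)]) + rng.normal(0, 0.1, 70)
        got = moving_average(x, 20)
        # oracle: mean over mirror-padded window, effective odd width 19
        w, h = 19, 9
        padded = np.pad(x, h, mode="symmetric")
        expected = np.array([padded[i : i + w].mean() for i in range(len(x))])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=5, max_size=60),
        st.integers(min_value=1, max_value=5),
    )
    def test_smoothing_conserves_mean(self, values, half_window):
        x = np.asarray(values)
        window = 2 * half_window + 1
        if window > len(x):
            window = len(x) if len(x) % 2 == 1 else len(x) - 1
        sm = moving_average(x, window)
        assert sm.mean() == pytest.approx(x.mean(), rel=1e-9, abs=1e-9)

    def test_stationary_velocity_monotone_in_noise(self):
        means = []
        for sd in (0.0, 10.0, 40.0):
            sc = make_small_scenario(
                duration=2.0, trajectory=[(0.0, 2.0, 0.0, 0.0)], noise_sd=sd, rng_seed=3
            )
            run = run_pipeline(sc)
            means.append(run["trace"].speed.mean())
        assert means[0] < 1e-6
        assert means[0] <= means[1] <= means[2]

    def test_window_longer_than_trace_raises(self):
        pose = gk.CellPose(np.zeros((5, 2)), np.zeros(5), np.ones(5, bool))
        with pytest.raises(ValueError):
            gk.compute_velocity_trace(pose, 0.13, 0.1, window=10)
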