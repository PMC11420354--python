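"""Reference-frame selection and rigid cell-frame registration."""

import numpy as np
import pytest

import glidekymo as gk
from glidekymo.registration import pose_score

from conftest import make_small_scenario, run_pipeline


def _retrack_centers(registered_chl: gk.CalibratedStack):
    dets = gk.detect_chloroplasts(registered_chl, 6.0, channel="chloroplast")
    ta, tb = gk.link_tracks(dets, registered_chl.n_frames)
    return gk.compute_cell_pose(ta, tb)


class TestReferenceSelection:
    def test_horizontal_centered_frame_wins(self):
        centers = np.array([[10.0, 10.0], [50.0, 50.0], [90.0, 90.0]])
        angles = np.array([30.0, 0.0, 10.0])
        pose = gk.CellPose(centers, angles, np.ones(3, bool))
        ref = gk.select_reference_frame(pose, (101, 101))
        assert ref.index == 1
        assert ref.angle_deg == 0.0

    def test_tie_breaks_to_earliest_frame(self):
        pose = gk.CellPose(np.full((5, 2), 20.0), np.full(5, 5.0), np.ones(5, bool))
        assert gk.select_reference_frame(pose, (64, 64)).index == 0

    def test_matches_exhaustive_score_minimization(self):
        rng = np.random.default_rng(0)
        n = 200
        pose = gk.CellPose(
            rng.uniform(0, 100, (n, 2)),
            rng.uniform(-90, 90, n),
            rng.random(n) > 0.1,
        )
        fov = (120, 100)
        ref = gk.select_reference_frame(pose, fov)
        # brute-force oracle over all valid frames
        best, best_score = None, np.inf
        fov_c = np.array([(fov[1] - 1) / 2, (fov[0] - 1) / 2])
        diag = np.hypot(*fov) / 2
        for i in range(n):
            if not pose.valid[i]:
                continue
            s = abs(pose.angle_deg[i]) / 90 + np.linalg.norm(pose.center[i] - fov_c) / diag
            if s < best_score - 1e-15:
                best, best_score = i, s
        assert ref.index == best
        np.testing.assert_allclose(
            pose_score(pose, fov)[ref.index], best_score, rtol=1e-12
        )

    def test_no_valid_frames_raises(self):
        pose = gk.CellPose(np.zeros((3, 2)), np.zeros(3), np.zeros(3, bool))
        with pytest.raises(ValueError):
            gk.select_reference_frame(pose, (64, 64))


class TestRegistration:
    def test_stationary_horizontal_cell_is_identity(self):
        sc = make_small_scenario(trajectory=[(0.0, 4.0, 0.0, 0.0)])
        stack, _ = gk.generate_gliding_movie(sc)
        run = run_pipeline(sc)
        reg = gk.register_stack(stack, run["pose"], run["ref"], channel="gfp")
        orig = stack.channel("gfp")
        dyn = orig.max() - orig.min()
        assert np.abs(reg.channel("gfp") - orig).mean() / dyn < 1e-6

    def test_translation_cancelled_to_quarter_pixel(self, standard_run):
        # re-track the registered chloroplast channel: centres must collapse
        reg_all = gk.register_stack(
            standard_run["stack"], standard_run["pose"], standard_run["ref"]
        )
        chl_only = gk.CalibratedStack(
            reg_all.channel("chloroplast")[:, None],
            reg_all.pixel_size, reg_all.frame_interval, ("chloroplast",),
        )
        pose2 = _retrack_centers(chl_only)
        ref_c = np.array(standard_run["ref"].center)
        err = np.linalg.norm(pose2.center - ref_c, axis=1)
        assert err.max() < 0.5
        assert np.median(err) < 0.25

    def test_rotated_cell_restored_to_reference_angle(self):
        sc = make_small_scenario(
            duration=2.0, fov=(220, 220), cell_length=16.0,
            chloroplast_offsets=(-6.0, 6.0),
            trajectory=[(0.0, 2.0, 0.0, 0.0)],
        )
        stack, _ = gk.generate_gliding_movie(sc)
        # same cell rendered at 30 deg; registered against the 0-deg frame it
        # must come back horizontal
        sc30 = make_small_scenario(
            duration=2.0, fov=(220, 220), cell_length=16.0,
            chloroplast_offsets=(-6.0, 6.0),
            trajectory=[(0.0, 2.0, 0.0, 30.0)],
        )
        stack30, _ = gk.generate_gliding_movie(sc30)
        frames = np.concatenate([stack.data, stack30.data], axis=0)
        both = gk.CalibratedStack(frames, sc.pixel_size, sc.frame_interval, stack.channels)
        dets = gk.detect_chloroplasts(both, 6.0)
        pose = gk.compute_cell_pose(*gk.link_tracks(dets, both.n_frames))
        ref = gk.ReferenceFrame(0, tuple(pose.center[0]), float(pose.angle_deg[0]))
        reg = gk.register_stack(both, pose, ref)
        chl = gk.CalibratedStack(
            reg.channel("chloroplast")[:, None], reg.pixel_size, reg.frame_interval,
            ("chloroplast",),
        )
        pose2 = _retrack_centers(chl)
        assert np.abs(pose2.angle_deg - ref.angle_deg).max() < 1.0

    def test_invalid_pose_frames_emitted_blank_and_flagged(self):
        sc = make_small_scenario(duration=2.0)
        stack, _ = gk.generate_gliding_movie(sc)
        run = run_pipeline(sc)
        pose = run["pose"]
        pose.valid[3] = False
        reg = gk.register_stack(stack, pose, run["ref"], channel="gfp")
        assert not reg.frame_valid[3]
        assert np.all(reg.channel("gfp")[3] == 0.0)

    def test_idempotent_within_interpolation_error(self, standard_run):
        reg1 = gk.register_stack(
            standard_run["stack"], standard_run["pose"], standard_run["ref"]
        )
        chl = gk.CalibratedStack(
            reg1.channel("chloroplast")[:, None], reg1.pixel_size, reg1.frame_interval,
            ("chloroplast",),
        )
        pose2 = _retrack_centers(chl)
        ref2 = gk.select_reference_frame(pose2, (reg1.data.shape[2], reg1.data.shape[3]))
        reg2 = gk.register_stack(reg1, pose2, ref2)
        first_pass = np.abs(reg1.data - standard_run["stack"].data).mean()
        second_pass = np.abs(reg2.data - reg1.data).mean()
        assert second_pass < 0.1 * first_pass
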