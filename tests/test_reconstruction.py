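import numpy as np
import pytest
from scipy.optimize import minimize

from circumtrack import calibration as calib
from circumtrack import synthetic as syn
from circumtrack.camera import CameraModel, project
from circumtrack.exceptions import (
    EmptyReconstruction,
    IllConditionedTriangulation,
)
from circumtrack.reconstruction import (
    DetectionCounts,
    VideoReprojectionSummary,
    reconstruct_trajectory,
    report_rows,
    reprojection_error,
    summarize_tables,
    triangulate,
)
from circumtrack.tracking import SyncResult, TipObservation
from tests.conftest import sample_world_points


class TestTriangulate:
    def test_inverts_noiseless_projection(self, true_rig):
        rng = np.random.default_rng(0)
        for pw in sample_world_points(rng, 25):
            p_top = project(true_rig.top, pw)
            p_side = project(true_rig.side, pw)
            assert np.linalg.norm(triangulate(true_rig, p_top, p_side)
                                  - pw) < 1e-6

    def test_matches_bruteforce_lattice_search(self, true_rig):
        """DLT+refinement equals an exhaustive coarse-lattice search with
        local polish of the reprojection cost."""
        rng = np.random.default_rng(1)
        for pw in sample_world_points(rng, 3):
            p_top = project(true_rig.top, pw) + rng.normal(0, 1.0, 2)
            p_side = project(true_rig.side, pw) + rng.normal(0, 1.0, 2)

            def cost(x):
                rt, rs, _ = reprojection_error(true_rig, x, p_top, p_side)
                return rt * rt + rs * rs

            # coarse lattice around the volume, then local refinement
            grid = np.stack(np.meshgrid(
                np.linspace(pw[0] - 5, pw[0] + 5, 11),
                np.linspace(pw[1] - 5, pw[1] + 5, 11),
                np.linspace(pw[2] - 5, pw[2] + 5, 11),
            ), axis=-1).reshape(-1, 3)
            costs = [cost(g) for g in grid]
            x0 = grid[int(np.argmin(costs))]
            brute = minimize(cost, x0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-14,
                                      "maxiter": 5000}).x
            ours = triangulate(true_rig, p_top, p_side)
            # one refinement step promises the same optimum to first order
            assert cost(ours) <= cost(brute) * (1 + 1e-6) + 1e-12
            assert np.linalg.norm(ours - brute) < 1e-2

    def test_monte_carlo_error_at_booth_center(self, true_rig):
        """1 px pixel noise at the booth centre localises the tip to well
        under a centimetre (median over trials)."""
        rng = np.random.default_rng(2)
        pw = np.array([0.0, 0.0, 50.0])
        p_top = project(true_rig.top, pw)
        p_side = project(true_rig.side, pw)
        errs = []
        for _ in range(300):
            est = triangulate(true_rig, p_top + rng.normal(0, 1, 2),
                              p_side + rng.normal(0, 1, 2))
            errs.append(np.linalg.norm(est - pw))
        assert np.median(errs) < 1.0

    def test_error_decreases_with_noise(self, true_rig):
        rng = np.random.default_rng(3)
        pw = np.array([5.0, -3.0, 55.0])
        p_top = project(true_rig.top, pw)
        p_side = project(true_rig.side, pw)
        medians = []
        for sigma in (2.0, 1.0, 0.5, 0.0):
            errs = []
            for _ in range(300):
                est = triangulate(true_rig,
                                  p_top + rng.normal(0, sigma, 2),
                                  p_side + rng.normal(0, sigma, 2))
                errs.append(np.linalg.norm(est - pw))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2] > medians[3]

    def test_near_parallel_rays_rejected(self, true_rig):
        """A rig with an almost-zero baseline yields near-parallel rays."""
        cam_t = true_rig.top
        # side camera displaced by 1 mm from the top camera
        pose_s = calib.Pose(cam_t.pose.R, cam_t.pose.t + [0.0, 0.0, 0.1])
        R, t = calib.relative_pose(cam_t.pose, pose_s)
        E = calib.essential_matrix(R, t)
        F = calib.fundamental_matrix(E, cam_t.intrinsics, cam_t.intrinsics)
        rig = calib.StereoRig(
            top=cam_t,
            side=CameraModel(cam_t.intrinsics, cam_t.distortion, pose_s),
            R_rel=R, t_rel=t, E=E, F=F)
        pw = np.array([0.0, 0.0, 50.0])
        with pytest.raises(IllConditionedTriangulation):
            triangulate(rig, project(rig.top, pw), project(rig.side, pw))


class TestReprojectionError:
    def test_zero_for_noiseless_triangulation(self, true_rig):
        pw = np.array([3.0, 2.0, 60.0])
        p_top = project(true_rig.top, pw)
        p_side = project(true_rig.side, pw)
        xyz = triangulate(true_rig, p_top, p_side)
        rt, rs, rm = reprojection_error(true_rig, xyz, p_top, p_side)
        assert max(rt, rs, rm) < 1e-6

    def test_shifted_observation_measures_the_shift(self, true_rig):
        pw = np.array([3.0, 2.0, 60.0])
        p_top = project(true_rig.top, pw)
        p_side = project(true_rig.side, pw)
        rt, rs, rm = reprojection_error(true_rig, pw, p_top + [12.0, 0.0],
                                        p_side)
        assert np.isclose(rt, 12.0, atol=1e-9)
        assert np.isclose(rs, 0.0, atol=1e-9)
        assert np.isclose(rm, 6.0, atol=1e-9)
        assert rm < 10.0  # mean below the flag threshold despite one view

    def test_matches_hand_distance_formula(self, true_rig):
        rng = np.random.default_rng(4)
        pw = sample_world_points(rng, 1)[0]
        p_top = project(true_rig.top, pw) + rng.normal(0, 3, 2)
        p_side = project(true_rig.side, pw) + rng.normal(0, 3, 2)
        rt, rs, rm = reprojection_error(true_rig, pw, p_top, p_side)
        assert np.isclose(rt, np.hypot(*(project(true_rig.top, pw) - p_top)))
        assert np.isclose(rs, np.hypot(*(project(true_rig.side, pw)
                                         - p_side)))
        assert np.isclose(rm, (rt + rs) / 2)


def make_tracks(rig, xyz, offset, noise, rng):
    track_top, track_side = [], []
    for k, pw in enumerate(xyz):
        pt = project(rig.top, pw) + rng.normal(0, noise, 2)
        ps = project(rig.side, pw) + rng.normal(0, noise, 2)
        track_top.append(TipObservation(k, "top", *pt, "automatic"))
        track_side.append(TipObservation(k + offset, "side", *ps,
                                         "automatic"))
    return track_top, track_side


class TestReconstructTrajectory:
    def test_recovers_synthetic_trajectory(self, scene_cfg, true_rig):
        rng = np.random.default_rng(5)
        xyz = syn.make_trajectory(scene_cfg, 200, syn.NutationParams())
        tt, ts = make_tracks(true_rig, xyz, 4, 0.5, rng)
        sync = SyncResult(4, [], [])
        points, report = reconstruct_trajectory(true_rig, tt, ts, sync)
        assert report.total_points == 200
        err = np.linalg.norm(
            np.array([p.xyz for p in points]) - xyz, axis=1)
        assert np.sqrt((err ** 2).mean()) < 1.0
        assert report.n_flagged / report.total_points < 0.05

    def test_report_aggregates_match_bruteforce(self, true_rig):
        rng = np.random.default_rng(6)
        xyz = sample_world_points(rng, 40)
        tt, ts = make_tracks(true_rig, xyz, 0, 2.0, rng)
        sync = SyncResult(0, [], [])
        points, report = reconstruct_trajectory(true_rig, tt, ts, sync,
                                                flag_threshold=2.0)
        res_t = [p.re_top for p in points]
        res_s = [p.re_side for p in points]
        assert np.isclose(report.mean_re_top, np.mean(res_t))
        assert np.isclose(report.stdev_re_side, np.std(res_s))
        assert report.n_flagged == sum(p.re_mean > 2.0 for p in points)
        assert report.n_flagged <= report.total_points

    def test_empty_overlap_rejected(self, true_rig):
        tt = [TipObservation(0, "top", 640, 360, "automatic")]
        ts = [TipObservation(0, "side", 640, 360, "automatic")]
        with pytest.raises(EmptyReconstruction):
            reconstruct_trajectory(true_rig, tt, ts, SyncResult(50, [], []))

    def test_zero_length_range_rejected(self, true_rig):
        rng = np.random.default_rng(7)
        xyz = sample_world_points(rng, 5)
        tt, ts = make_tracks(true_rig, xyz, 0, 0.0, rng)
        with pytest.raises(EmptyReconstruction):
            reconstruct_trajectory(true_rig, tt, ts, SyncResult(0, [], []),
                                   frame_range=(90, 80))

    def test_csv_export_columns(self, true_rig, tmp_path):
        import pandas as pd

        from circumtrack.reconstruction import trajectory_to_csv

        rng = np.random.default_rng(8)
        xyz = sample_world_points(rng, 10)
        tt, ts = make_tracks(true_rig, xyz, 2, 0.5, rng)
        sync = SyncResult(2, [], [])
        points, _ = reconstruct_trajectory(true_rig, tt, ts, sync)
        path = tmp_path / "traj.csv"
        trajectory_to_csv(points, tt, ts, sync, path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "frame_id", "X_cm", "Y_cm", "Z_cm", "u_top", "v_top", "u_side",
            "v_side", "label_top", "label_side", "re_top_px", "re_side_px",
            "flagged"]
        assert len(df) == 10


class TestCoverageExtrapolation:
    def test_errors_largest_outside_calibrated_image_region(self, scene_cfg,
                                                            board):
        """Calibration coverage lesson: a camera calibrated from boards
        confined to one half of the image mis-projects targets in the
        uncovered half (the fitted distortion/intrinsics extrapolate
        badly), reproducing — as a ranking, not absolute values — why the
        largest tracking errors appear where no calibration points were
        collected."""
        rng = np.random.default_rng(9)
        views = syn.render_calibration_set(scene_cfg, board, 40, "top",
                                           np.random.default_rng(100))
        confined = [v for v in views
                    if v.corners_px[:, 0].max() < 640][:10]
        assert len(confined) >= 5
        obs = syn.observations_from_views(confined, board, 0.3, rng)
        intr, dist, _, _ = calib.calibrate_camera(
            obs, (scene_cfg.image_width, scene_cfg.image_height))

        inside, outside = [], []
        for v in views:
            truth_obs = calib.BoardObservation(v.corners_px,
                                               board.object_points())
            pose = calib.estimate_board_pose(intr, dist, truth_obs)
            pred = project(CameraModel(intr, dist, pose),
                           board.object_points())
            err = np.linalg.norm(pred - v.corners_px, axis=1)
            for e, c in zip(err, v.corners_px):
                (inside if c[0] < 640 else outside).append(e)
        assert np.mean(outside) > 1.5 * np.mean(inside)


class TestStudySummaries:
    def test_single_report_passthrough(self):
        row = VideoReprojectionSummary("v", "top", 2.5, 1.0, 100, 3)
        det = DetectionCounts("v", "top", 0, 99, 90, 5, 3, 2)
        s = summarize_tables([row], [det])
        assert s.overall_mean_re == 2.5
        assert np.isclose(s.flagged_pct, 3.0)
        assert np.isclose(s.manual_pct, 5.0)

    def test_report_rows_split_views(self, true_rig):
        rng = np.random.default_rng(10)
        xyz = sample_world_points(rng, 30)
        tt, ts = make_tracks(true_rig, xyz, 0, 1.0, rng)
        _, report = reconstruct_trajectory(true_rig, tt, ts,
                                           SyncResult(0, [], []))
        rows = report_rows("vid", report)
        assert [r.view for r in rows] == ["top", "side"]
        assert all(r.total_points == 30 for r in rows)
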