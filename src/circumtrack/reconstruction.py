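"""Two-view triangulation, reprojection-error audit and study summaries.

Triangulation undistorts both pixel observations to normalised image
coordinates, solves the two-ray DLT system in the rig's world frame, and
applies one Gauss-Newton refinement step on the summed squared pixel
reprojection error (with the full distortion model in the loop). Per-frame
reprojection errors are the package's accuracy currency: points whose mean
error exceeds the flag threshold (default 10 px) are flagged for review.

``summarize_tables`` aggregates per-video, per-view statistics into the
study-level figures: the overall mean reprojection error is the unweighted
mean of the per-video per-view means (not point-weighted), the flagged
percentage is total flagged points over total points, and the manual
percentage is total manual detections over total frames.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import StereoRig
from .camera import pixel_to_normalized, project
from .exceptions import (
    EmptyReconstruction,
    IllConditionedTriangulation,
)
from .tracking import SyncResult


@dataclass
class TrajectoryPoint:
    frame_id: int
    xyz: np.ndarray
    re_top: float
    re_side: float
    re_mean: float
    flagged: bool


@dataclass
class TrajectoryReport:
    mean_re_top: float
    stdev_re_top: float
    mean_re_side: float
    stdev_re_side: float
    total_points: int
    n_flagged: int
    per_frame_re_top: np.ndarray
    per_frame_re_side: np.ndarray


def _ray_angle_deg(rig: StereoRig, x_top, x_side) -> float:
    d_top = rig.top.pose.R.T @ np.array([x_top[0], x_top[1], 1.0])
    d_side = rig.side.pose.R.T @ np.array([x_side[0], x_side[1], 1.0])
    cosang = np.dot(d_top, d_side) / (np.linalg.norm(d_top)
                                      * np.linalg.norm(d_side))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def triangulate(rig: StereoRig, p_top, p_side,
                min_ray_angle_deg: float = 0.5) -> np.ndarray:
    """3D world point (cm) from one pixel observation per view."""
    x_top = pixel_to_normalized(rig.top, np.asarray(p_top, float))
    x_side = pixel_to_normalized(rig.side, np.asarray(p_side, float))
    if _ray_angle_deg(rig, x_top, x_side) < min_ray_angle_deg:
        raise IllConditionedTriangulation("viewing rays are near-parallel")

    P1 = rig.top.pose.matrix
    P2 = rig.side.pose.matrix
    A = np.vstack([
        x_top[0] * P1[2] - P1[0],
        x_top[1] * P1[2] - P1[1],
        x_side[0] * P2[2] - P2[0],
        x_side[1] * P2[2] - P2[1],
    ])
    _, _, vt = np.linalg.svd(A)
    Xh = vt[-1]
    X = Xh[:3] / Xh[3]

    # one Gauss-Newton step on pixel reprojection error
    obs = np.concatenate([np.asarray(p_top, float), np.asarray(p_side, float)])

    def residual(pt):
        return np.concatenate([
            project(rig.top, pt) - obs[:2],
            project(rig.side, pt) - obs[2:],
        ])

    r0 = residual(X)
    eps = 1e-4
    J = np.empty((4, 3))
    for i in range(3):
        dX = np.zeros(3)
        dX[i] = eps
        J[:, i] = (residual(X + dX) - r0) / eps
    JtJ = J.T @ J
    try:
        step = np.linalg.solve(JtJ, -J.T @ r0)
        X_new = X + step
        if np.sum(residual(X_new) ** 2) <= np.sum(r0 ** 2):
            X = X_new
    except np.linalg.LinAlgError:
        pass
    return X


def reprojection_error(rig: StereoRig, xyz, p_top, p_side):
    """(re_top, re_side, re_mean) pixel distances for one 3D estimate."""
    xyz = np.asarray(xyz, float)
    re_top = float(np.linalg.norm(project(rig.top, xyz)
                                  - np.asarray(p_top, float)))
    re_side = float(np.linalg.norm(project(rig.side, xyz)
                                   - np.asarray(p_side, float)))
    return re_top, re_side, 0.5 * (re_top + re_side)


def reconstruct_trajectory(rig: StereoRig, track_top: list, track_side: list,
                           sync: SyncResult, flag_threshold: float = 10.0,
                           frame_range=None):
    """Triangulate aligned frame pairs and audit their reprojection errors.

    Top frame ``k`` pairs with side frame ``k + offset``. Frames without a
    partner at the sequence edges are dropped. Returns
    ``(list[TrajectoryPoint], TrajectoryReport)``.
    """
    top_by_frame = {o.frame_id: o for o in track_top}
    side_by_frame = {o.frame_id: o for o in track_side}
    offset = sync.offset_frames
    frames = sorted(k for k in top_by_frame if (k + offset) in side_by_frame)
    if frame_range is not None:
        lo, hi = frame_range
        frames = [k for k in frames if lo <= k <= hi]
    if not frames:
        raise EmptyReconstruction("no aligned frame pairs")

    points, res_t, res_s = [], [], []
    for k in frames:
        ot, os_ = top_by_frame[k], side_by_frame[k + offset]
        xyz = triangulate(rig, (ot.u, ot.v), (os_.u, os_.v))
        re_t, re_s, re_m = reprojection_error(rig, xyz, (ot.u, ot.v),
                                              (os_.u, os_.v))
        points.append(TrajectoryPoint(frame_id=k, xyz=xyz, re_top=re_t,
                                      re_side=re_s, re_mean=re_m,
                                      flagged=re_m > flag_threshold))
        res_t.append(re_t)
        res_s.append(re_s)
    res_t = np.array(res_t)
    res_s = np.array(res_s)
    report = TrajectoryReport(
        mean_re_top=float(res_t.mean()), stdev_re_top=float(res_t.std()),
        mean_re_side=float(res_s.mean()), stdev_re_side=float(res_s.std()),
        total_points=len(points),
        n_flagged=int(sum(p.flagged for p in points)),
        per_frame_re_top=res_t, per_frame_re_side=res_s,
    )
    return points, report


def trajectory_to_csv(points: list, track_top: list, track_side: list,
                      sync: SyncResult, path) -> None:
    top_by_frame = {o.frame_id: o for o in track_top}
    side_by_frame = {o.frame_id: o for o in track_side}
    rows = []
    for p in points:
        ot = top_by_frame[p.frame_id]
        os_ = side_by_frame[p.frame_id + sync.offset_frames]
        rows.append({
            "frame_id": p.frame_id,
            "X_cm": p.xyz[0], "Y_cm": p.xyz[1], "Z_cm": p.xyz[2],
            "u_top": ot.u, "v_top": ot.v, "u_side": os_.u, "v_side": os_.v,
            "label_top": ot.label, "label_side": os_.label,
            "re_top_px": p.re_top, "re_side_px": p.re_side,
            "flagged": p.flagged,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VideoReprojectionSummary:
    """Per-video per-view reprojection statistics (one table row)."""

    video: str
    view: str
    mean_re: float
    stdev_re: float
    total_points: int
    n_over_threshold: int


@dataclass(frozen=True)
class DetectionCounts:
    """Per-video per-view detection-type counts over a frame range."""

    video: str
    view: str
    frame_start: int
    frame_end: int
    automatic: int
    manual: int
    estimated: int
    interpolated: int

    @property
    def total(self) -> int:
        return self.automatic + self.manual + self.estimated \
            + self.interpolated

    @property
    def range_length(self) -> int:
        return self.frame_end - self.frame_start + 1


@dataclass
class StudySummary:
    overall_mean_re: float      # unweighted mean of per-row mean REs
    flagged_pct: float          # flagged points / total points * 100
    manual_pct: float           # manual detections / total frames * 100
    total_points: int
    total_flagged: int
    total_frames: int
    total_manual: int


def summarize_tables(reproj_rows, detection_rows) -> StudySummary:
    """Aggregate per-video tables into study-level statistics."""
    if not reproj_rows:
        raise ValueError("need at least one reprojection summary row")
    overall_mean = float(np.mean([r.mean_re for r in reproj_rows]))
    total_points = int(sum(r.total_points for r in reproj_rows))
    total_flagged = int(sum(r.n_over_threshold for r in reproj_rows))
    total_frames = int(sum(d.total for d in detection_rows))
    total_manual = int(sum(d.manual for d in detection_rows))
    return StudySummary(
        overall_mean_re=overall_mean,
        flagged_pct=100.0 * total_flagged / total_points,
        manual_pct=(100.0 * total_manual / total_frames
                    if total_frames else 0.0),
        total_points=total_points, total_flagged=total_flagged,
        total_frames=total_frames, total_manual=total_manual,
    )


def report_rows(video: str, report: TrajectoryReport,
                flag_threshold: float = 10.0):
    """TrajectoryReport -> two VideoReprojectionSummary rows (per view)."""
    return [
        VideoReprojectionSummary(video, "top", report.mean_re_top,
                                 report.stdev_re_top, report.total_points,
                                 int(np.sum(report.per_frame_re_top
                                            > flag_threshold))),
        VideoReprojectionSummary(video, "side", report.mean_re_side,
                                 report.stdev_re_side, report.total_points,
                                 int(np.sum(report.per_frame_re_side
                                            > flag_threshold))),
    ]
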