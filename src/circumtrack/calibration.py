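"""Camera and stereo-rig calibration from chessboard observations.

Single-camera calibration follows the classic planar-target recipe: a
homography is estimated per board view, closed-form intrinsics are recovered
from the homography constraints, per-view poses are extracted, and all
parameters (intrinsics, distortion, poses) are refined jointly by
Levenberg-Marquardt on the total squared reprojection error.

Stereo calibration combines per-pair relative poses (board seen by both
cameras simultaneously) into a single rig: rotations are averaged as
quaternions, translations arithmetically. The world frame of the resulting
rig is anchored at the first stereo board's coordinate frame.

Conventions
-----------
* ``relative_pose(pose_top, pose_side)`` returns ``(R, t)`` such that
  ``R_side = R @ R_top`` and ``t_side = R @ t_top + t`` — i.e. the pose of
  the side camera relative to the top camera.
* ``E = [t]x R`` relates *normalised* coordinates: ``x_side^T E x_top = 0``.
* ``F = K_side^-T E K_top^-1`` relates *pixels*: for a pixel ``p_top`` in
  the top view, ``F @ p_top`` (homogeneous) is the epipolar line in the
  side view. Note the side intrinsics enter on the left and the top
  intrinsics on the right; a single shared camera matrix is only correct
  when both cameras are identical.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .camera import (
    CameraModel,
    Distortion,
    Intrinsics,
    Pose,
    apply_distortion,
    remove_distortion,
)
from .exceptions import (
    DegenerateRig,
    UnderConstrainedCalibration,
    UnstableStereoCalibration,
)


@dataclass(frozen=True)
class BoardSpec:
    """Chessboard described by its *inner* corner grid and square size (cm)."""

    inner_cols: int
    inner_rows: int
    square_size: float

    def __post_init__(self):
        if self.inner_cols < 2 or self.inner_rows < 2:
            raise ValueError("board needs at least a 2x2 inner corner grid")
        if not self.square_size > 0:
            raise ValueError("square size must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_cols * self.inner_rows

    def object_points(self) -> np.ndarray:
        """Inner corners in the board frame, row-major (rows outer), Z = 0."""
        jj, ii = np.meshgrid(
            np.arange(self.inner_rows), np.arange(self.inner_cols), indexing="ij"
        )
        pts = np.zeros((self.n_corners, 3))
        pts[:, 0] = ii.ravel() * self.square_size
        pts[:, 1] = jj.ravel() * self.square_size
        return pts


@dataclass(frozen=True, eq=False)
class BoardObservation:
    """Matched 2D corner pixels and 3D board-frame points for one view."""

    image_points: np.ndarray  # (N, 2)
    object_points: np.ndarray  # (N, 3), Z = 0
    frame_id: str = ""

    def __post_init__(self):
        ip = np.asarray(self.image_points, dtype=float)
        op = np.asarray(self.object_points, dtype=float)
        if ip.shape[0] != op.shape[0]:
            raise ValueError("image/object point lists differ in length")
        object.__setattr__(self, "image_points", ip)
        object.__setattr__(self, "object_points", op)


@dataclass
class CalibrationReport:
    mean_re: float
    stdev_re: float
    per_view_re: list
    n_points: int


@dataclass(frozen=True, eq=False)
class StereoRig:
    """Two calibrated cameras plus their relative epipolar geometry."""

    top: CameraModel
    side: CameraModel
    R_rel: np.ndarray
    t_rel: np.ndarray
    E: np.ndarray
    F: np.ndarray


# ---------------------------------------------------------------------------
# homography / closed-form initialisation
# ---------------------------------------------------------------------------

def _normalise_points(pts: np.ndarray):
    mean = pts.mean(axis=0)
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - mean, axis=1)), 1e-12)
    T = np.array([[scale, 0, -scale * mean[0]],
                  [0, scale, -scale * mean[1]],
                  [0, 0, 1.0]])
    homog = np.column_stack([pts, np.ones(len(pts))]) @ T.T
    return homog, T


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography mapping src (N,2) to dst (N,2), Hartley-normalised."""
    src_h, Ts = _normalise_points(np.asarray(src, float))
    dst_h, Td = _normalise_points(np.asarray(dst, float))
    n = len(src_h)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = src_h
    A[0::2, 6:9] = -dst_h[:, 0:1] * src_h
    A[1::2, 3:6] = src_h
    A[1::2, 6:9] = -dst_h[:, 1:2] * src_h
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    h_i, h_j = H[:, i], H[:, j]
    return np.array([
        h_i[0] * h_j[0],
        h_i[0] * h_j[1] + h_i[1] * h_j[0],
        h_i[1] * h_j[1],
        h_i[2] * h_j[0] + h_i[0] * h_j[2],
        h_i[2] * h_j[1] + h_i[1] * h_j[2],
        h_i[2] * h_j[2],
    ])


def intrinsics_from_homographies(Hs, image_size) -> Intrinsics:
    """Closed-form intrinsics from >= 3 board homographies (Zhang's method)."""
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.array(V)
    _, s, vt = np.linalg.svd(V)
    if s[-2] < 1e-12 * s[0]:
        raise UnderConstrainedCalibration("board poses are degenerate")
    b1, b2, b3, b4, b5, b6 = vt[-1]
    denom = b1 * b3 - b2 * b2
    v0 = (b2 * b4 - b1 * b5) / denom
    lam = b6 - (b4 * b4 + v0 * (b2 * b4 - b1 * b5)) / b1
    if lam / b1 <= 0 or lam * b1 / denom <= 0:
        raise UnderConstrainedCalibration("invalid closed-form intrinsics")
    fx = np.sqrt(lam / b1)
    fy = np.sqrt(lam * b1 / denom)
    skew = -b2 * fx * fx * fy / lam
    u0 = skew * v0 / fy - b4 * fx * fx / lam
    w, h = image_size
    return Intrinsics(fx=fx, fy=fy, cx=float(np.clip(u0, 0, w - 1)),
                      cy=float(np.clip(v0, 0, h - 1)), width=w, height=h)


def pose_from_homography(K: np.ndarray, H: np.ndarray) -> Pose:
    """Board->camera pose from a pixel homography and known intrinsics."""
    B = np.linalg.solve(K, H)
    lam = 2.0 / (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1]))
    if B[2, 2] * lam < 0:  # enforce board in front of the camera
        lam = -lam
    r1, r2 = lam * B[:, 0], lam * B[:, 1]
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(R_approx)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return Pose(R, lam * B[:, 2])


# ---------------------------------------------------------------------------
# bundle refinement
# ---------------------------------------------------------------------------

def _project_params(obj: np.ndarray, intr_v: np.ndarray, dist_v: np.ndarray,
                    rvec: np.ndarray, tvec: np.ndarray) -> np.ndarray:
    R = Rotation.from_rotvec(rvec).as_matrix()
    pc = obj @ R.T + tvec
    xy = pc[:, :2] / pc[:, 2:3]
    d = Distortion(k1=dist_v[0], k2=dist_v[1], k3=dist_v[4],
                   p1=dist_v[2], p2=dist_v[3])
    xyd = apply_distortion(d, xy)
    fx, fy, cx, cy = intr_v
    return np.column_stack([fx * xyd[:, 0] + cx, fy * xyd[:, 1] + cy])


def _per_point_errors(intr: Intrinsics, dist: Distortion, poses, observations):
    errs, per_view = [], []
    intr_v = np.array([intr.fx, intr.fy, intr.cx, intr.cy])
    dist_v = np.array([dist.k1, dist.k2, dist.p1, dist.p2, dist.k3])
    for pose, obs in zip(poses, observations):
        proj = _project_params(obs.object_points, intr_v, dist_v,
                               Rotation.from_matrix(pose.R).as_rotvec(), pose.t)
        e = np.linalg.norm(proj - obs.image_points, axis=1)
        errs.append(e)
        per_view.append(float(e.mean()))
    all_e = np.concatenate(errs)
    return all_e, per_view


def make_report(intr, dist, poses, observations) -> CalibrationReport:
    all_e, per_view = _per_point_errors(intr, dist, poses, observations)
    return CalibrationReport(
        mean_re=float(all_e.mean()),
        stdev_re=float(all_e.std()),
        per_view_re=per_view,
        n_points=int(all_e.size),
    )


def calibrate_camera(observations, image_size, fix_k3: bool | None = None):
    """Full intrinsic + distortion + per-view-pose calibration.

    Parameters
    ----------
    observations : list of BoardObservation
        At least three views with distinct board orientations.
    image_size : (width, height)
    fix_k3 : bool, optional
        Keep k3 at zero. Default: fixed unless >= 15 views are provided
        (estimating the sixth-order term from few boards is unstable).

    Returns
    -------
    (Intrinsics, Distortion, list[Pose], CalibrationReport)
    """
    if len(observations) < 3:
        raise UnderConstrainedCalibration(
            f"need >= 3 board views, got {len(observations)}"
        )
    if fix_k3 is None:
        fix_k3 = len(observations) < 15
    Hs = [
        homography_dlt(obs.object_points[:, :2], obs.image_points)
        for obs in observations
    ]
    intr0 = intrinsics_from_homographies(Hs, image_size)
    poses0 = [pose_from_homography(intr0.K, H) for H in Hs]

    n_views = len(observations)
    n_dist = 4 if fix_k3 else 5
    x0 = np.zeros(4 + n_dist + 6 * n_views)
    x0[0:4] = [intr0.fx, intr0.fy, intr0.cx, intr0.cy]
    for i, p in enumerate(poses0):
        base = 4 + n_dist + 6 * i
        x0[base:base + 3] = Rotation.from_matrix(p.R).as_rotvec()
        x0[base + 3:base + 6] = p.t

    obj_list = [obs.object_points for obs in observations]
    img_list = [obs.image_points for obs in observations]

    def residuals(x):
        intr_v = x[0:4]
        dist_v = np.zeros(5)
        dist_v[:n_dist] = x[4:4 + n_dist]
        out = []
        for i in range(n_views):
            base = 4 + n_dist + 6 * i
            proj = _project_params(obj_list[i], intr_v, dist_v,
                                   x[base:base + 3], x[base + 3:base + 6])
            out.append((proj - img_list[i]).ravel())
        return np.concatenate(out)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    x = sol.x
    w, h = image_size
    intr = Intrinsics(fx=x[0], fy=x[1], cx=float(np.clip(x[2], 0, w - 1)),
                      cy=float(np.clip(x[3], 0, h - 1)), width=w, height=h)
    dist_v = np.zeros(5)
    dist_v[:n_dist] = x[4:4 + n_dist]
    dist = Distortion(k1=dist_v[0], k2=dist_v[1], p1=dist_v[2], p2=dist_v[3],
                      k3=dist_v[4])
    poses = []
    for i in range(n_views):
        base = 4 + n_dist + 6 * i
        poses.append(Pose(Rotation.from_rotvec(x[base:base + 3]).as_matrix(),
                          x[base + 3:base + 6]))
    report = make_report(intr, dist, poses, observations)
    return intr, dist, poses, report


def estimate_board_pose(intr: Intrinsics, dist: Distortion,
                        obs: BoardObservation) -> Pose:
    """Planar PnP: board->camera pose with known intrinsics/distortion."""
    xd = (obs.image_points[:, 0] - intr.cx) / intr.fx
    yd = (obs.image_points[:, 1] - intr.cy) / intr.fy
    xy = remove_distortion(dist, np.stack([xd, yd], axis=-1))
    H = homography_dlt(obs.object_points[:, :2], xy)
    pose0 = pose_from_homography(np.eye(3), H)

    intr_v = np.array([intr.fx, intr.fy, intr.cx, intr.cy])
    dist_v = np.array([dist.k1, dist.k2, dist.p1, dist.p2, dist.k3])

    def residuals(x):
        proj = _project_params(obs.object_points, intr_v, dist_v, x[:3], x[3:])
        return (proj - obs.image_points).ravel()

    x0 = np.concatenate([Rotation.from_matrix(pose0.R).as_rotvec(), pose0.t])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    return Pose(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


# ---------------------------------------------------------------------------
# stereo geometry
# ---------------------------------------------------------------------------

def relative_pose(pose1: Pose, pose2: Pose):
    """(R, t) with R = R2 R1^T and t = t2 - R t1 (pose of 2 relative to 1)."""
    R = pose2.R @ pose1.R.T
    t = pose2.t - R @ pose1.t
    return R, t


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix [v]x such that [v]x w = v x w."""
    v = np.asarray(v, float).reshape(3)
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def essential_matrix(R_rel: np.ndarray, t_rel: np.ndarray) -> np.ndarray:
    if np.linalg.norm(t_rel) == 0:
        raise DegenerateRig("zero baseline")
    return skew(t_rel) @ np.asarray(R_rel, float)


def fundamental_matrix(E: np.ndarray, A_top: Intrinsics,
                       A_side: Intrinsics) -> np.ndarray:
    """F = K_side^-T E K_top^-1, mapping top pixels to side epipolar lines."""
    return np.linalg.inv(A_side.K).T @ E @ np.linalg.inv(A_top.K)


def calibrate_stereo(obs_pairs, cam_top: CameraModel, cam_side: CameraModel,
                     max_rotation_spread_deg: float = 5.0):
    """Combine simultaneous board-pair observations into one StereoRig.

    ``obs_pairs`` is a list of ``(BoardObservation_top, BoardObservation_side)``
    of the *same physical board placement*. Per-pair relative poses are fused
    by quaternion averaging (rotation) and arithmetic mean (translation);
    a rotation spread above ``max_rotation_spread_deg`` raises
    :class:`UnstableStereoCalibration`.

    The returned rig's world frame is the first pair's board frame. The
    report pools per-point reprojection errors over both views of all pairs
    (using the fused rig to predict the side view from the top-view pose).
    """
    if len(obs_pairs) < 1:
        raise UnderConstrainedCalibration("need at least one stereo pair")
    poses_top, poses_side, rels = [], [], []
    for obs_t, obs_s in obs_pairs:
        pt = estimate_board_pose(cam_top.intrinsics, cam_top.distortion, obs_t)
        ps = estimate_board_pose(cam_side.intrinsics, cam_side.distortion, obs_s)
        poses_top.append(pt)
        poses_side.append(ps)
        rels.append(relative_pose(pt, ps))

    rots = Rotation.from_matrix(np.array([R for R, _ in rels]))
    R_mean = rots.mean().as_matrix()
    spreads = [
        np.degrees(np.linalg.norm((Rotation.from_matrix(R_mean).inv() * r).as_rotvec()))
        for r in rots
    ]
    if max(spreads) > max_rotation_spread_deg:
        raise UnstableStereoCalibration(
            f"relative-rotation spread {max(spreads):.2f} deg exceeds "
            f"{max_rotation_spread_deg} deg"
        )
    t_mean = np.mean([t for _, t in rels], axis=0)

    top = CameraModel(cam_top.intrinsics, cam_top.distortion, poses_top[0])
    side_pose = Pose(R_mean @ poses_top[0].R, R_mean @ poses_top[0].t + t_mean)
    side = CameraModel(cam_side.intrinsics, cam_side.distortion, side_pose)
    E = essential_matrix(R_mean, t_mean)
    F = fundamental_matrix(E, cam_top.intrinsics, cam_side.intrinsics)
    rig = StereoRig(top=top, side=side, R_rel=R_mean, t_rel=t_mean, E=E, F=F)

    errs, per_view = [], []
    for (obs_t, obs_s), pt in zip(obs_pairs, poses_top):
        cam_t_i = CameraModel(cam_top.intrinsics, cam_top.distortion, pt)
        ps_pred = Pose(R_mean @ pt.R, R_mean @ pt.t + t_mean)
        cam_s_i = CameraModel(cam_side.intrinsics, cam_side.distortion, ps_pred)
        from .camera import project  # local import to avoid cycle at top
        e_t = np.linalg.norm(project(cam_t_i, obs_t.object_points)
                             - obs_t.image_points, axis=1)
        e_s = np.linalg.norm(project(cam_s_i, obs_s.object_points)
                             - obs_s.image_points, axis=1)
        errs.extend([e_t, e_s])
        per_view.extend([float(e_t.mean()), float(e_s.mean())])
    all_e = np.concatenate(errs)
    report = CalibrationReport(mean_re=float(all_e.mean()),
                               stdev_re=float(all_e.std()),
                               per_view_re=per_view,
                               n_points=int(all_e.size))
    return rig, report


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def rig_to_dict(rig: StereoRig) -> dict:
    from .camera import camera_to_dict

    return {
        "top": camera_to_dict(rig.top),
        "side": camera_to_dict(rig.side),
        "R_rel": [float(v) for v in np.asarray(rig.R_rel).ravel()],
        "t_rel": [float(v) for v in np.asarray(rig.t_rel).ravel()],
        "E": [float(v) for v in np.asarray(rig.E).ravel()],
        "F": [float(v) for v in np.asarray(rig.F).ravel()],
    }


def rig_from_dict(doc: dict) -> StereoRig:
    from .camera import camera_from_dict

    return StereoRig(
        top=camera_from_dict(doc["top"]),
        side=camera_from_dict(doc["side"]),
        R_rel=np.array(doc["R_rel"]).reshape(3, 3),
        t_rel=np.array(doc["t_rel"]),
        E=np.array(doc["E"]).reshape(3, 3),
        F=np.array(doc["F"]).reshape(3, 3),
    )


def save_rig(rig: StereoRig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(rig_to_dict(rig), fh, sort_keys=True)


def load_rig(path) -> StereoRig:
    with open(path) as fh:
        return rig_from_dict(yaml.safe_load(fh))


def write_calibration_report(path, top: CalibrationReport,
                             side: CalibrationReport,
                             stereo: CalibrationReport) -> None:
    """Six-column calibration summary (mean/stdev RE per camera and rig)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "mean_re_top", "stdev_re_top", "mean_re_side", "stdev_re_side",
            "mean_re_stereo", "stdev_re_stereo",
        ])
        writer.writerow([
            top.mean_re, top.stdev_re, side.mean_re, side.stdev_re,
            stereo.mean_re, stereo.stdev_re,
        ])
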