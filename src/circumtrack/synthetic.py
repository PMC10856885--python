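"""Ground-truthed synthetic stereo scenes of a nutating plant tip.

The generator emulates the recording booth used for climbing-bean
experiments: a cylindrical cabin (100 cm tall, 93 cm radius) with a zenithal
camera 130 cm above the pot looking straight down and a lateral camera at
55 cm height on the booth wall, the two optical axes 90 degrees apart. Both
cameras are 1280 x 720 with a 112 degree horizontal field of view and mild
radial-tangential distortion. Illumination follows a light:dark photoperiod
(scaled from L16:D8 to a configurable number of frames per phase) with a dim
safelight level during the dark phase; the lower part of the lateral view is
a dark band, matching the contrast cover used in the real booth.

The plant is rendered as a bending stem polyline from the pot base to the
current tip position plus a circular tip blob; the stem shape
``P(s) = (x_tip s^2, y_tip s^2, z_tip s)`` keeps the base nearly static
while the distal portion sweeps with the tip, which is the behaviour the
background-subtraction stage relies on. The tip follows a growing helix
(circumnutation): a circle in (x, y) with linearly increasing height.

Every random draw flows through one seeded generator, so identical configs
produce bit-identical outputs. All "truth" quantities (3D tip path, exact
projections, true cameras, lighting-change frames, injected stereo offset)
are returned alongside the rendered frames.
"""
from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .calibration import BoardObservation, BoardSpec
from .camera import (
    CameraModel,
    Distortion,
    Intrinsics,
    Pose,
    camera_to_dict,
    project,
    remove_distortion,
)
from .exceptions import OutOfFrame


@dataclass(frozen=True)
class NutationParams:
    """Helical tip path: circle radius (cm), period (frames), growth (cm/frame)."""

    radius_cm: float = 15.0
    period_frames: float = 120.0
    growth_cm_per_frame: float = 0.07
    start_height_cm: float = 35.0
    phase: float = 0.0
    # the stem below the tip keeps swaying with amplitude decaying over
    # this many frames of tissue age (0 disables the sway)
    sway_tau_frames: float = 30.0

    def __post_init__(self):
        if not self.period_frames > 0:
            raise ValueError("period must be positive")


@dataclass(frozen=True)
class PoleSpec:
    height_cm: float = 90.0
    diameter_cm: float = 1.8
    distance_cm: float = 30.0


@dataclass(frozen=True)
class SceneConfig:
    booth_height_cm: float = 100.0
    booth_radius_cm: float = 93.0
    side_cam_height_cm: float = 55.0
    top_cam_height_cm: float = 130.0
    image_width: int = 1280
    image_height: int = 720
    fov_deg: float = 112.0
    frame_interval_min: float = 1.0
    light_frames: int = 40
    dark_frames: int = 20
    dark_illumination: float = 0.1
    pole: PoleSpec | None = None
    noise_px: float = 0.0         # jitter applied to synthetic point observations
    intensity_noise: float = 1.0  # additive image noise, grey levels
    stem_radius_px: float = 1.8
    tip_radius_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("booth_height_cm", "booth_radius_cm", "side_cam_height_cm",
                     "top_cam_height_cm", "fov_deg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    tip_xyz: np.ndarray          # (n, 3), world cm, indexed by top-frame time
    proj_top: np.ndarray         # (n, 2), exact tip projection, top view
    proj_side: np.ndarray        # (n, 2), exact tip projection, side view
    cam_top: CameraModel
    cam_side: CameraModel
    lighting_change_frames: list  # top-timeline frames where illumination steps
    offset_frames: int
    illumination: np.ndarray     # (n,), top timeline
    base_px_top: np.ndarray      # projection of the pot base, top view
    base_px_side: np.ndarray


_TRUE_DIST = Distortion(k1=-0.08, k2=0.01, p1=4e-4, p2=-3e-4)

# grey levels of the scene elements (before the illumination multiplier)
_TOP_BG = 70.0
_TOP_PLANT = 170.0
_SIDE_BG_UPPER = 200.0
_SIDE_BG_LOWER = 60.0
_SIDE_PLANT = 30.0
_SIDE_POLE = 110.0
_SIDE_DARK_BAND_FRAC = 0.35
_BOARD_DARK = 45.0
_BOARD_LIGHT = 235.0


def true_intrinsics(cfg: SceneConfig) -> Intrinsics:
    f = (cfg.image_width / 2.0) / np.tan(np.radians(cfg.fov_deg / 2.0))
    return Intrinsics(fx=f, fy=f, cx=(cfg.image_width - 1) / 2.0,
                      cy=(cfg.image_height - 1) / 2.0,
                      width=cfg.image_width, height=cfg.image_height)


def true_cameras(cfg: SceneConfig) -> tuple[CameraModel, CameraModel]:
    """Ground-truth top and side cameras in the booth world frame.

    World frame: origin at the pot base, z up; the side camera sits on the
    +x wall. The optical axes meet at 90 degrees.
    """
    intr = true_intrinsics(cfg)
    # top: at (0, 0, h) looking straight down
    R_top = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
    c_top = np.array([0.0, 0.0, cfg.top_cam_height_cm])
    cam_top = CameraModel(intr, _TRUE_DIST, Pose(R_top, -R_top @ c_top))
    # side: on the wall at (r, 0, h_side) looking toward the plant axis
    R_side = np.array([[0.0, 1.0, 0], [0, 0, -1.0], [-1.0, 0, 0]])
    c_side = np.array([cfg.booth_radius_cm, 0.0, cfg.side_cam_height_cm])
    cam_side = CameraModel(intr, _TRUE_DIST, Pose(R_side, -R_side @ c_side))
    return cam_top, cam_side


def make_trajectory(cfg: SceneConfig, n_frames: int,
                    nutation: NutationParams,
                    t_start: int = 0) -> np.ndarray:
    """Helical circumnutation path, (n_frames, 3) in world cm.

    ``t_start`` shifts the time origin; negative values extrapolate the
    helix backwards (used to render the lead-in of an offset camera).
    """
    t = np.arange(t_start, t_start + n_frames, dtype=float)
    ang = 2.0 * np.pi * t / nutation.period_frames + nutation.phase
    xyz = np.column_stack([
        nutation.radius_cm * np.cos(ang),
        nutation.radius_cm * np.sin(ang),
        nutation.start_height_cm + nutation.growth_cm_per_frame * t,
    ])
    return xyz


def illumination_series(cfg: SceneConfig, n_frames: int) -> np.ndarray:
    """Photoperiod multiplier per frame: 1.0 in light, dim in dark."""
    t = np.arange(n_frames)
    period = cfg.light_frames + cfg.dark_frames
    light = (t % period) < cfg.light_frames
    return np.where(light, 1.0, cfg.dark_illumination)


def _transitions(series: np.ndarray) -> list:
    d = np.flatnonzero(np.diff(series) != 0) + 1
    return [int(i) for i in d]


def _stamp_disks(canvas: np.ndarray, centers: np.ndarray, radius: float):
    """Max-combine anti-aliased disk coverage into ``canvas`` (float, 0..1)."""
    h, w = canvas.shape
    r_ext = int(np.ceil(radius + 1.5))
    for u, v in centers:
        c0, r0 = int(round(u)), int(round(v))
        if c0 < -r_ext or c0 >= w + r_ext or r0 < -r_ext or r0 >= h + r_ext:
            continue
        rr = np.arange(max(r0 - r_ext, 0), min(r0 + r_ext + 1, h))
        cc = np.arange(max(c0 - r_ext, 0), min(c0 + r_ext + 1, w))
        if len(rr) == 0 or len(cc) == 0:
            continue
        dd = np.hypot(rr[:, None] - v, cc[None, :] - u)
        cov = np.clip(radius + 0.5 - dd, 0.0, 1.0)
        region = canvas[rr[0]:rr[-1] + 1, cc[0]:cc[-1] + 1]
        np.maximum(region, cov, out=region)


def stem_points(tip_xyz: np.ndarray, n: int = 80) -> np.ndarray:
    """Default bending stem: quadratic arc from the base to the tip.

    The ``s^2`` lateral profile keeps the base nearly static while the
    distal portion sweeps with the tip, which is what the background
    subtraction relies on. :func:`growth_path` offers the alternative
    past-trajectory (twining helix) stem model.
    """
    s = np.linspace(0.0, 1.0, n)
    return np.column_stack([
        tip_xyz[0] * s ** 2, tip_xyz[1] * s ** 2, tip_xyz[2] * s,
    ])


def growth_path(cfg: SceneConfig, nutation: NutationParams,
                t_now: float, n: int | None = None) -> np.ndarray:
    """Stem as the helical path the tip traced while growing to ``t_now``.

    The path is extrapolated back to ground level (z = 0) and closed with a
    short straight run to the pot base, so the rendered plant is anchored
    at the origin. Because z grows monotonically, the tip is always the
    highest plant point and never occludes its own stem in either view.
    """
    t0 = (0.0 - nutation.start_height_cm) / max(nutation.growth_cm_per_frame,
                                                1e-9)
    if n is None:
        # sample the path at ~0.4 cm arc spacing so the rendered stem is a
        # continuous line
        speed = np.hypot(2.0 * np.pi * nutation.radius_cm
                         / nutation.period_frames,
                         nutation.growth_cm_per_frame)
        n = max(80, int(speed * (t_now - t0) / 0.4))
    ts = np.linspace(t0, t_now, n)
    ang = 2.0 * np.pi * ts / nutation.period_frames + nutation.phase
    helix = np.column_stack([
        nutation.radius_cm * np.cos(ang),
        nutation.radius_cm * np.sin(ang),
        nutation.start_height_cm + nutation.growth_cm_per_frame * ts,
    ])
    # anchor: fade the radius to zero over the lowest 15 cm of the climb
    # (a fixed height, so the lower stem is identical in every frame)
    frac = np.clip(helix[:, 2] / 15.0, 0.0, 1.0)
    helix[:, 0] *= frac
    helix[:, 1] *= frac
    if nutation.sway_tau_frames > 0:
        # young tissue keeps circumnutating: each stem point is pulled
        # toward the tip's current lateral offset with an age-decaying
        # weight, so the upper stem sways while the old stem stands still
        age = t_now - ts
        w = np.exp(-np.maximum(age, 0.0) / nutation.sway_tau_frames)
        helix[:, 0] += w * (helix[-1, 0] - helix[:, 0])
        helix[:, 1] += w * (helix[-1, 1] - helix[:, 1])
    return helix


def _project_safe(cam: CameraModel, pts: np.ndarray) -> np.ndarray:
    """Project, silently dropping points at or behind the camera."""
    from .camera import world_to_camera, apply_distortion

    pc = world_to_camera(cam.pose, np.asarray(pts, float))
    keep = pc[..., 2] > 1.0
    pc = pc[keep]
    xy = pc[:, :2] / pc[:, 2:3]
    xyd = apply_distortion(cam.distortion, xy)
    intr = cam.intrinsics
    return np.column_stack([intr.fx * xyd[:, 0] + intr.cx,
                            intr.fy * xyd[:, 1] + intr.cy])


def _background(cfg: SceneConfig, view: str) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    if view == "top":
        return np.full((h, w), _TOP_BG, dtype=float)
    bg = np.full((h, w), _SIDE_BG_UPPER, dtype=float)
    band_start = int(h * (1.0 - _SIDE_DARK_BAND_FRAC))
    bg[band_start:, :] = _SIDE_BG_LOWER
    return bg


def render_view(cfg: SceneConfig, cam: CameraModel, tip_xyz: np.ndarray,
                illumination: float, view: str, rng: np.random.Generator,
                draw_stem: bool = True,
                stem_xyz: np.ndarray | None = None) -> np.ndarray:
    base = _background(cfg, view)
    plant_val = _TOP_PLANT if view == "top" else _SIDE_PLANT
    cov = np.zeros_like(base)
    if cfg.pole is not None and view == "side":
        pole = cfg.pole
        zs = np.linspace(0.0, pole.height_cm, 120)
        pole_pts = np.column_stack([np.zeros_like(zs),
                                    np.full_like(zs, pole.distance_cm), zs])
        pole_uv = _project_safe(cam, pole_pts)
        pole_cov = np.zeros_like(base)
        # pole width in px from its diameter at the plant-axis depth
        depth = cfg.booth_radius_cm
        r_px = max(0.9, cam.intrinsics.fx * pole.diameter_cm / (2 * depth))
        _stamp_disks(pole_cov, pole_uv, r_px)
        base = base * (1 - pole_cov) + _SIDE_POLE * pole_cov
    if draw_stem:
        pts = stem_xyz if stem_xyz is not None else stem_points(tip_xyz)
        uv = _project_safe(cam, pts)
        _stamp_disks(cov, uv, cfg.stem_radius_px)
    tip_uv = _project_safe(cam, tip_xyz[None, :])
    tip_cov = np.zeros_like(base)
    if len(tip_uv):
        _stamp_disks(tip_cov, tip_uv, cfg.tip_radius_px)
    cov = np.maximum(cov, tip_cov)
    img = base * (1 - cov) + plant_val * cov
    img = img * illumination
    if cfg.intensity_noise > 0:
        img = img + rng.normal(0.0, cfg.intensity_noise, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_frame(cfg: SceneConfig, tip_xyz: np.ndarray, illumination: float,
                 rng: np.random.Generator | None = None,
                 draw_stem: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render the (top, side) image pair for one tip position.

    Raises :class:`OutOfFrame` if the tip is visible in neither view.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cam_top, cam_side = true_cameras(cfg)
    visible = 0
    for cam in (cam_top, cam_side):
        uv = _project_safe(cam, np.asarray(tip_xyz, float)[None, :])
        if len(uv) and (0 <= uv[0, 0] < cfg.image_width) and \
                (0 <= uv[0, 1] < cfg.image_height):
            visible += 1
    if visible == 0:
        raise OutOfFrame("tip projects outside both views")
    top = render_view(cfg, cam_top, np.asarray(tip_xyz, float), illumination,
                      "top", rng, draw_stem)
    side = render_view(cfg, cam_side, np.asarray(tip_xyz, float), illumination,
                       "side", rng, draw_stem)
    return top, side


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def generate_sequence_pair(cfg: SceneConfig, n_frames: int,
                           offset_frames: int = 0,
                           nutation: NutationParams = NutationParams(),
                           outdir=None):
    """Render synchronised-but-offset top/side sequences with ground truth.

    The side camera's clock lags the top camera by ``offset_frames``: side
    frame ``j`` shows the scene at top-timeline time ``j - offset_frames``
    (clamped at the sequence start), so an illumination step at top frame k
    appears at side frame ``k + offset_frames``.

    Returns ``(frames_top, frames_side, truth)`` with frames as uint8 arrays;
    if ``outdir`` is given, also writes PNG frames, a truth manifest CSV and
    a camera-truth YAML there.
    """
    if abs(offset_frames) >= n_frames:
        raise ValueError("offset must be smaller than the sequence length")
    rng = np.random.default_rng(cfg.seed)
    cam_top, cam_side = true_cameras(cfg)
    # extend the timeline so the offset camera's lead-in/tail shows the
    # plant in motion rather than a frozen scene
    pre = max(offset_frames, 0)
    post = max(-offset_frames, 0)
    xyz_ext = make_trajectory(cfg, n_frames + pre + post, nutation,
                              t_start=-pre)
    xyz = xyz_ext[pre:pre + n_frames]
    illum = illumination_series(cfg, n_frames)
    proj_top = project(cam_top, xyz)
    proj_side = project(cam_side, xyz)
    base_top = project(cam_top, np.zeros(3))
    base_side = project(cam_side, np.zeros(3))

    frames_top, frames_side = [], []
    for k in range(n_frames):
        frames_top.append(render_view(cfg, cam_top, xyz[k], illum[k], "top",
                                      rng))
    for j in range(n_frames):
        k = j - offset_frames  # scene time of side frame j
        il = illum[int(np.clip(k, 0, n_frames - 1))]
        frames_side.append(render_view(cfg, cam_side, xyz_ext[k + pre], il,
                                       "side", rng))

    truth = GroundTruth(
        tip_xyz=xyz, proj_top=proj_top, proj_side=proj_side,
        cam_top=cam_top, cam_side=cam_side,
        lighting_change_frames=_transitions(illum),
        offset_frames=offset_frames, illumination=illum,
        base_px_top=base_top, base_px_side=base_side,
    )
    if outdir is not None:
        _write_sequence(outdir, frames_top, frames_side, truth)
    return frames_top, frames_side, truth


def _write_sequence(outdir, frames_top, frames_side, truth: GroundTruth):
    from pathlib import Path

    outdir = Path(outdir)
    for sub, frames in (("top", frames_top), ("side", frames_side)):
        d = outdir / sub
        d.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(frames):
            iio.imwrite(d / f"frame_{i:06d}.png", fr)
    n = len(frames_top)
    manifest = pd.DataFrame({
        "frame_id": np.arange(n),
        "X": truth.tip_xyz[:, 0], "Y": truth.tip_xyz[:, 1],
        "Z": truth.tip_xyz[:, 2],
        "u_top": truth.proj_top[:, 0], "v_top": truth.proj_top[:, 1],
        "u_side": truth.proj_side[:, 0], "v_side": truth.proj_side[:, 1],
        "illumination": truth.illumination,
    })
    manifest.to_csv(outdir / "truth_manifest.csv", index=False)
    doc = {
        "top": camera_to_dict(truth.cam_top),
        "side": camera_to_dict(truth.cam_side),
        "offset_frames": int(truth.offset_frames),
        "lighting_change_frames": [int(i) for i in
                                   truth.lighting_change_frames],
        "base_px_top": [float(v) for v in truth.base_px_top],
        "base_px_side": [float(v) for v in truth.base_px_side],
    }
    with open(outdir / "camera_truth.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------

@dataclass
class CalibView:
    """One rendered board view with its exact corner projections."""

    corners_px: np.ndarray          # (N, 2) exact projections
    pose_board_to_cam: Pose
    image: np.ndarray | None = None


@dataclass
class StereoCalibView:
    corners_top: np.ndarray
    corners_side: np.ndarray
    pose_board_to_top: Pose
    pose_board_to_side: Pose
    pose_board_to_world: Pose
    image_top: np.ndarray | None = None
    image_side: np.ndarray | None = None


def _board_center_offset(board: BoardSpec) -> np.ndarray:
    return np.array([(board.inner_cols - 1) / 2.0 * board.square_size,
                     (board.inner_rows - 1) / 2.0 * board.square_size, 0.0])


def _pattern_values(X: np.ndarray, Y: np.ndarray, board: BoardSpec,
                    bg: np.ndarray) -> np.ndarray:
    """Board colour at board coords (X, Y); ``bg`` where outside the board."""
    s = board.square_size
    # squares index a in [-1, inner_cols-1], b in [-1, inner_rows-1]
    a = np.floor(X / s)
    b = np.floor(Y / s)
    in_pattern = (a >= -1) & (a <= board.inner_cols - 1) & \
                 (b >= -1) & (b <= board.inner_rows - 1)
    margin = 0.7 * s
    in_board = (X >= -s - margin) & (X <= board.inner_cols * s + margin) & \
               (Y >= -s - margin) & (Y <= board.inner_rows * s + margin)
    dark = ((a + b) % 2) == 0
    vals = np.where(in_pattern,
                    np.where(dark, _BOARD_DARK, _BOARD_LIGHT),
                    _BOARD_LIGHT)
    return np.where(in_board, vals, bg)


def render_board_image(cam: CameraModel, board: BoardSpec,
                       pose_board_to_cam: Pose, background: np.ndarray,
                       supersample: int = 5) -> np.ndarray:
    """Render the board over ``background`` by inverse homography mapping."""
    intr = cam.intrinsics
    s = board.square_size
    margin = 0.7 * s
    outline = np.array([
        [-s - margin, -s - margin, 0],
        [board.inner_cols * s + margin, -s - margin, 0],
        [board.inner_cols * s + margin, board.inner_rows * s + margin, 0],
        [-s - margin, board.inner_rows * s + margin, 0],
    ])
    cam_board = CameraModel(intr, cam.distortion, pose_board_to_cam)
    corners_px = project(cam_board, outline)
    u0 = int(np.clip(np.floor(corners_px[:, 0].min()) - 2, 0, intr.width - 1))
    u1 = int(np.clip(np.ceil(corners_px[:, 0].max()) + 2, 0, intr.width - 1))
    v0 = int(np.clip(np.floor(corners_px[:, 1].min()) - 2, 0, intr.height - 1))
    v1 = int(np.clip(np.ceil(corners_px[:, 1].max()) + 2, 0, intr.height - 1))
    if u1 <= u0 or v1 <= v0:
        return background.copy()

    ss = supersample
    us = (np.arange(u0 * ss, (u1 + 1) * ss) + 0.5) / ss - 0.5
    vs = (np.arange(v0 * ss, (v1 + 1) * ss) + 0.5) / ss - 0.5
    # undistort on a pixel-resolution grid and interpolate: the distortion
    # field is smooth, so bilinear interpolation is far below render accuracy
    from scipy.ndimage import map_coordinates

    ug = np.arange(u0 - 1, u1 + 3, dtype=float)
    vg = np.arange(v0 - 1, v1 + 3, dtype=float)
    uug, vvg = np.meshgrid(ug, vg)
    xdg = (uug - intr.cx) / intr.fx
    ydg = (vvg - intr.cy) / intr.fy
    xyg = remove_distortion(cam.distortion,
                            np.stack([xdg, ydg], axis=-1), tol=1e-9)
    uu, vv = np.meshgrid(us, vs)
    ci = (vv - (v0 - 1), uu - (u0 - 1))
    xy = np.stack([
        map_coordinates(xyg[..., 0], ci, order=1, mode="nearest"),
        map_coordinates(xyg[..., 1], ci, order=1, mode="nearest"),
    ], axis=-1)
    R, t = pose_board_to_cam.R, pose_board_to_cam.t
    H = np.column_stack([R[:, 0], R[:, 1], t])
    Hinv = np.linalg.inv(H)
    ph = np.stack([xy[..., 0], xy[..., 1], np.ones_like(xy[..., 0])], axis=-1)
    bc = ph @ Hinv.T
    X = bc[..., 0] / bc[..., 2]
    Y = bc[..., 1] / bc[..., 2]
    bg_patch = np.repeat(np.repeat(background[v0:v1 + 1, u0:u1 + 1], ss, 0),
                         ss, 1)
    vals = _pattern_values(X, Y, board, bg_patch)
    h_lo, w_lo = v1 - v0 + 1, u1 - u0 + 1
    vals = vals.reshape(h_lo, ss, w_lo, ss).mean(axis=(1, 3))
    out = background.copy()
    out[v0:v1 + 1, u0:u1 + 1] = vals
    return out


def _corners_world(board: BoardSpec, pose_bw: Pose) -> np.ndarray:
    obj = board.object_points()
    return obj @ pose_bw.R.T + pose_bw.t


def _visible(cam: CameraModel, pts_w: np.ndarray, margin: float = 8.0) -> bool:
    try:
        uv = project(cam, pts_w)
    except Exception:
        return False
    intr = cam.intrinsics
    return bool(np.all((uv[:, 0] >= margin) & (uv[:, 0] < intr.width - margin)
                       & (uv[:, 1] >= margin)
                       & (uv[:, 1] < intr.height - margin)))


def render_calibration_set(cfg: SceneConfig, board: BoardSpec, n_views: int,
                           which: str, rng: np.random.Generator | None = None,
                           render_images: bool = False):
    """Board placements with exact corner projections (optionally rendered).

    ``which`` is ``"top"``, ``"side"`` (single-camera sets: boards placed in
    front of that camera at varied offsets and tilts so corner coverage spans
    the image) or ``"stereo"`` (boards visible in both views at once).
    Returns a list of :class:`CalibView` or :class:`StereoCalibView`.
    """
    if which not in ("top", "side", "stereo"):
        raise ValueError("which must be top, side or stereo")
    if which == "stereo":
        if n_views < 1:
            raise ValueError("stereo set needs >= 1 view")
    elif n_views < 3:
        raise ValueError("single-camera set needs >= 3 views")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cam_top, cam_side = true_cameras(cfg)
    center_off = _board_center_offset(board)

    if which in ("top", "side"):
        cam = cam_top if which == "top" else cam_side
        views = []
        # lateral offsets cycle through a 3x3 image-coverage pattern
        pattern = [(-0.45, -0.45), (0.45, -0.45), (-0.45, 0.45), (0.45, 0.45),
                   (0.0, 0.0), (-0.45, 0.0), (0.45, 0.0), (0.0, -0.45),
                   (0.0, 0.45)]
        attempts = 0
        while len(views) < n_views and attempts < 50 * n_views:
            attempts += 1
            i = len(views)
            dist = rng.uniform(70.0, 110.0)
            fu, fv = pattern[i % len(pattern)]
            half_w = dist * np.tan(np.radians(cfg.fov_deg / 2.0))
            cx_off = fu * half_w * 0.75 + rng.uniform(-3, 3)
            cy_off = fv * half_w * 0.45 + rng.uniform(-3, 3)
            tilt = rng.uniform(-25, 25, size=2)
            roll = rng.uniform(-40, 40)
            R = Rotation.from_euler("xyz", [tilt[0], tilt[1], roll],
                                    degrees=True).as_matrix()
            c_cam = np.array([cx_off, cy_off, dist])
            pose_bc = Pose(R, c_cam - R @ center_off)
            obj = board.object_points()
            pts_cam = obj @ pose_bc.R.T + pose_bc.t
            cam_at_board = CameraModel(cam.intrinsics, cam.distortion, pose_bc)
            if not _visible(cam_at_board, obj):
                continue
            if np.any(pts_cam[:, 2] < 25.0):
                continue
            corners = project(cam_at_board, obj)
            img = None
            if render_images:
                img = render_board_image(cam, board, pose_bc,
                                         _background(cfg, which))
                if cfg.intensity_noise > 0:
                    img = np.clip(
                        img + rng.normal(0, cfg.intensity_noise, img.shape),
                        0, 255)
            views.append(CalibView(corners_px=corners,
                                   pose_board_to_cam=pose_bc, image=img))
        if len(views) < n_views:
            raise RuntimeError("could not place enough visible boards")
        return views

    # stereo: boards in the shared working volume, front facing both cameras
    views = []
    bisector = -(np.array([0, 0, 1.0]) + np.array([1.0, 0, 0]))
    bisector /= np.linalg.norm(bisector)
    attempts = 0
    while len(views) < n_views and attempts < 200 * n_views:
        attempts += 1
        center = np.array([rng.uniform(5, 30), rng.uniform(-15, 15),
                           rng.uniform(40, 70)])
        z_axis = bisector + rng.normal(0, 0.12, 3)
        z_axis /= np.linalg.norm(z_axis)
        x_axis = np.cross([0.0, 0, 1.0], z_axis)
        x_axis /= np.linalg.norm(x_axis)
        y_axis = np.cross(z_axis, x_axis)
        R_bw = np.column_stack([x_axis, y_axis, z_axis])
        pose_bw = Pose(R_bw, center - R_bw @ center_off)
        pts_w = _corners_world(board, pose_bw)
        cam_t_b = Pose(cam_top.pose.R @ pose_bw.R,
                       cam_top.pose.R @ pose_bw.t + cam_top.pose.t)
        cam_s_b = Pose(cam_side.pose.R @ pose_bw.R,
                       cam_side.pose.R @ pose_bw.t + cam_side.pose.t)
        if not (_visible(cam_top, pts_w) and _visible(cam_side, pts_w)):
            continue
        corners_t = project(cam_top, pts_w)
        corners_s = project(cam_side, pts_w)
        img_t = img_s = None
        if render_images:
            img_t = render_board_image(cam_top, board, cam_t_b,
                                       _background(cfg, "top"))
            img_s = render_board_image(cam_side, board, cam_s_b,
                                       _background(cfg, "side"))
        views.append(StereoCalibView(
            corners_top=corners_t, corners_side=corners_s,
            pose_board_to_top=cam_t_b, pose_board_to_side=cam_s_b,
            pose_board_to_world=pose_bw, image_top=img_t, image_side=img_s))
    if len(views) < n_views:
        raise RuntimeError("could not place enough stereo-visible boards")
    return views


def observations_from_views(views, board: BoardSpec, noise_px: float,
                            rng: np.random.Generator):
    """BoardObservations from exact corner projections plus Gaussian jitter."""
    obj = board.object_points()
    out = []
    for i, v in enumerate(views):
        pts = v.corners_px + rng.normal(0, noise_px, v.corners_px.shape) \
            if noise_px > 0 else v.corners_px.copy()
        out.append(BoardObservation(image_points=pts, object_points=obj,
                                    frame_id=f"synt_{i:03d}"))
    return out


def stereo_observations_from_views(views, board: BoardSpec, noise_px: float,
                                   rng: np.random.Generator):
    obj = board.object_points()
    pairs = []
    for i, v in enumerate(views):
        pt = v.corners_top + rng.normal(0, noise_px, v.corners_top.shape) \
            if noise_px > 0 else v.corners_top.copy()
        ps = v.corners_side + rng.normal(0, noise_px, v.corners_side.shape) \
            if noise_px > 0 else v.corners_side.copy()
        pairs.append((
            BoardObservation(pt, obj, frame_id=f"stereo_top_{i:03d}"),
            BoardObservation(ps, obj, frame_id=f"stereo_side_{i:03d}"),
        ))
    return pairs
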