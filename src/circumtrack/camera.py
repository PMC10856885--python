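"""Pinhole camera geometry with radial-tangential lens distortion.

World coordinates are expressed in centimetres. Pixel coordinates follow the
top-left-origin convention: ``u`` grows rightward, ``v`` downward, and pixel
centres sit on integer coordinates.

A camera is the triple (intrinsics, distortion, pose). Projection of a world
point ``Pw`` proceeds as

    Pc = R @ Pw + t                      (world -> camera)
    (x, y) = (Xc / Zc, Yc / Zc)          (normalised image plane)
    (x', y') = distort(x, y)             (radial + tangential model)
    (u, v) = (fx * x' + cx, fy * y' + cy)

The distortion model is the standard Brown-Conrady polynomial:

    x' = x (1 + k1 r^2 + k2 r^4 + k3 r^6) + p2 (r^2 + 2 x^2) + 2 p1 x y
    y' = y (1 + k1 r^2 + k2 r^4 + k3 r^6) + p1 (r^2 + 2 y^2) + 2 p2 x y

with ``r^2 = x^2 + y^2`` in normalised coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import DistortionDivergence, PointBehindCamera

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Intrinsics:
    """Focal lengths and principal point, all in pixel units."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class Distortion:
    """Radial (k1..k3) and tangential (p1, p2) coefficients.

    All coefficients are dimensionless and act on normalised coordinates;
    the all-zero default is an ideal pinhole.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        vals = (self.k1, self.k2, self.k3, self.p1, self.p2)
        if not np.all(np.isfinite(vals)):
            raise ValueError("distortion coefficients must be finite")

    @property
    def is_zero(self) -> bool:
        return all(c == 0.0 for c in (self.k1, self.k2, self.k3, self.p1, self.p2))


@dataclass(frozen=True, eq=False)
class Pose:
    """Rigid world->camera transform: ``Pc = R @ Pw + t`` (t in cm)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("R must be a proper rotation (det +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        """3x4 matrix [R | t]."""
        return np.hstack([self.R, self.t[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates, -R^T t."""
        return -self.R.T @ self.t

    def compose_after(self, other: "Pose") -> "Pose":
        """Pose mapping ``other``'s source frame through self: self o other."""
        return Pose(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "Pose":
        return Pose(self.R.T, -self.R.T @ self.t)


@dataclass(frozen=True, eq=False)
class CameraModel:
    intrinsics: Intrinsics
    distortion: Distortion = field(default_factory=Distortion)
    pose: Pose = field(default_factory=Pose.identity)


def world_to_camera(pose: Pose, pw: np.ndarray) -> np.ndarray:
    """Map world points (..., 3) into the camera frame."""
    pw = np.asarray(pw, dtype=float)
    return pw @ pose.R.T + pose.t


def apply_distortion(d: Distortion, xy: np.ndarray) -> np.ndarray:
    """Apply the Brown-Conrady model to normalised coordinates (..., 2)."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (d.k1 + r2 * (d.k2 + r2 * d.k3))
    xd = x * radial + d.p2 * (r2 + 2.0 * x * x) + 2.0 * d.p1 * x * y
    yd = y * radial + d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def remove_distortion(
    d: Distortion,
    xy_dist: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Invert :func:`apply_distortion` by fixed-point iteration.

    Valid for moderate distortion (|correction| well below 0.5 in normalised
    units); raises :class:`DistortionDivergence` if the residual does not
    fall below ``tol`` within ``max_iter`` iterations.
    """
    xy_dist = np.asarray(xy_dist, dtype=float)
    if d.is_zero:
        return xy_dist.copy()
    xy = xy_dist.copy()
    residual = np.inf
    for _ in range(max_iter):
        delta = apply_distortion(d, xy) - xy
        xy_new = xy_dist - delta
        residual = float(np.max(np.abs(apply_distortion(d, xy_new) - xy_dist)))
        xy = xy_new
        if residual < tol:
            return xy
    raise DistortionDivergence(residual)


def project(cam: CameraModel, pw: np.ndarray) -> np.ndarray:
    """Project world points (..., 3) to pixels (..., 2).

    Raises :class:`PointBehindCamera` if any point has depth Zc <= 0.
    """
    pc = world_to_camera(cam.pose, pw)
    z = pc[..., 2]
    if np.any(z <= 0):
        raise PointBehindCamera("point has non-positive depth")
    xy = pc[..., :2] / pc[..., 2:3]
    xyd = apply_distortion(cam.distortion, xy)
    intr = cam.intrinsics
    uv = np.empty_like(xyd)
    uv[..., 0] = intr.fx * xyd[..., 0] + intr.cx
    uv[..., 1] = intr.fy * xyd[..., 1] + intr.cy
    return uv


def pixel_to_normalized(cam: CameraModel, uv: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Back-map pixels (..., 2) to undistorted normalised coordinates."""
    uv = np.asarray(uv, dtype=float)
    intr = cam.intrinsics
    xd = (uv[..., 0] - intr.cx) / intr.fx
    yd = (uv[..., 1] - intr.cy) / intr.fy
    return remove_distortion(cam.distortion, np.stack([xd, yd], axis=-1), tol=tol)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def camera_to_dict(cam: CameraModel) -> dict:
    intr, d, pose = cam.intrinsics, cam.distortion, cam.pose
    return {
        "fx": float(intr.fx),
        "fy": float(intr.fy),
        "cx": float(intr.cx),
        "cy": float(intr.cy),
        "width": int(intr.width),
        "height": int(intr.height),
        "k1": float(d.k1),
        "k2": float(d.k2),
        "k3": float(d.k3),
        "p1": float(d.p1),
        "p2": float(d.p2),
        "R": [float(v) for v in pose.R.ravel()],
        "t": [float(v) for v in pose.t],
    }


def camera_from_dict(doc: dict) -> CameraModel:
    intr = Intrinsics(
        fx=doc["fx"], fy=doc["fy"], cx=doc["cx"], cy=doc["cy"],
        width=doc["width"], height=doc["height"],
    )
    dist = Distortion(k1=doc["k1"], k2=doc["k2"], k3=doc["k3"],
                      p1=doc["p1"], p2=doc["p2"])
    pose = Pose(np.array(doc["R"]).reshape(3, 3), np.array(doc["t"]))
    return CameraModel(intr, dist, pose)


def save_camera(cam: CameraModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(camera_to_dict(cam), fh, sort_keys=True)


def load_camera(path) -> CameraModel:
    with open(path) as fh:
        return camera_from_dict(yaml.safe_load(fh))
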