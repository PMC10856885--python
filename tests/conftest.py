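import numpy as np
import pytest
from hypothesis import settings

from circumtrack import calibration as calib
from circumtrack import synthetic as syn
from circumtrack.camera import CameraModel

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scene_cfg():
    return syn.SceneConfig(seed=5)


@pytest.fixture(scope="session")
def true_rig(scene_cfg):
    """Stereo rig built directly from the ground-truth cameras."""
    cam_t, cam_s = syn.true_cameras(scene_cfg)
    R, t = calib.relative_pose(cam_t.pose, cam_s.pose)
    E = calib.essential_matrix(R, t)
    F = calib.fundamental_matrix(E, cam_t.intrinsics, cam_s.intrinsics)
    return calib.StereoRig(top=cam_t, side=cam_s, R_rel=R, t_rel=t, E=E, F=F)


@pytest.fixture(scope="session")
def zero_dist_rig(scene_cfg):
    """Same geometry with ideal (distortion-free) optics."""
    cam_t, cam_s = syn.true_cameras(scene_cfg)
    cam_t = CameraModel(cam_t.intrinsics, pose=cam_t.pose)
    cam_s = CameraModel(cam_s.intrinsics, pose=cam_s.pose)
    R, t = calib.relative_pose(cam_t.pose, cam_s.pose)
    E = calib.essential_matrix(R, t)
    F = calib.fundamental_matrix(E, cam_t.intrinsics, cam_s.intrinsics)
    return calib.StereoRig(top=cam_t, side=cam_s, R_rel=R, t_rel=t, E=E, F=F)


@pytest.fixture(scope="session")
def board():
    return calib.BoardSpec(10, 7, 7.5)


@pytest.fixture(scope="session")
def stereo_board():
    return calib.BoardSpec(10, 7, 5.3)


@pytest.fixture(scope="session")
def calib_views_top(scene_cfg, board):
    rng = np.random.default_rng(42)
    return syn.render_calibration_set(scene_cfg, board, 10, "top", rng)


@pytest.fixture(scope="session")
def calib_views_side(scene_cfg, board):
    rng = np.random.default_rng(43)
    return syn.render_calibration_set(scene_cfg, board, 10, "side", rng)


@pytest.fixture(scope="session")
def calib_views_stereo(scene_cfg, stereo_board):
    rng = np.random.default_rng(44)
    return syn.render_calibration_set(scene_cfg, stereo_board, 8, "stereo",
                                      rng)


@pytest.fixture(scope="session")
def rendered_boards(scene_cfg, board):
    """Three rendered (noiseless) board images with exact corner truth."""
    cfg = syn.SceneConfig(seed=9, intensity_noise=0.0)
    rng = np.random.default_rng(9)
    return syn.render_calibration_set(cfg, board, 3, "top", rng,
                                      render_images=True)


def sample_world_points(rng, n):
    """Random 3D points inside the tracked booth volume (cm)."""
    return np.column_stack([
        rng.uniform(-20, 20, n),
        rng.uniform(-20, 20, n),
        rng.uniform(35, 75, n),
    ])
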