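"""Run configuration: one YAML document binding paths and parameters."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pipeline import TrackingSettings


@dataclass
class RunConfig:
    frames_top: str = ""
    frames_side: str = ""
    calib_top: str = ""
    calib_side: str = ""
    calib_stereo: str = ""
    corrections: str = ""
    output: str = "out"
    rig: str = ""
    board_inner_cols: int = 10
    board_inner_rows: int = 7
    board_square_cm: float = 7.5
    # the stereo target is a smaller print of the same pattern
    stereo_board_square_cm: float = 5.3
    base_top: tuple = (639.5, 359.5)
    base_side: tuple = (639.5, 614.0)
    flag_threshold_px: float = 10.0
    frame_start: int | None = None
    frame_end: int | None = None
    offset_frames: int | None = None
    seed: int = 0
    tracking: TrackingSettings = field(default_factory=TrackingSettings)

    def __post_init__(self):
        if (self.frame_start is not None and self.frame_end is not None
                and self.frame_start > self.frame_end):
            raise ValueError("frame_start must be <= frame_end")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    tracking = doc.pop("tracking", None)
    cfg = RunConfig(**doc)
    if tracking:
        mog = tracking.pop("mog", None)
        settings = TrackingSettings(**tracking)
        if mog:
            settings.mog.update(mog)
        cfg.tracking = settings
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items() if k != "tracking"
    }
    t = cfg.tracking
    doc["tracking"] = {
        "lighting_change_area_frac": t.lighting_change_area_frac,
        "lighting_change_est_time": t.lighting_change_est_time,
        "min_contour_area": t.min_contour_area,
        "max_candidates": t.max_candidates,
        "epipolar_threshold_px": t.epipolar_threshold_px,
        "mog": dict(t.mog),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
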