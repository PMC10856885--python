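"""End-to-end orchestration: segment -> detect -> select -> interpolate.

This module strings the per-frame stages together for whole sequences and
is what both the command-line interface and the validation suite drive.
The top view is processed first; the side view then uses the synchronised
top-view track to build the epipolar line that disambiguates contour
fragments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .segmentation import (
    LightingConfig,
    MixtureBackgroundModel,
    check_lighting_change,
    find_contours,
    polarity_filter,
    reset_model,
)
from .tip_detection import (
    BaseAnchor,
    extract_candidates_side,
    extract_candidates_top,
    epipolar_line,
)
from .tracking import (
    SyncResult,
    estimate_offset,
    interpolate_gaps,
    select_tip,
)

logger = logging.getLogger(__name__)


@dataclass
class TrackingSettings:
    """Per-run analysis parameters (see methods note for defaults)."""

    lighting_change_area_frac: float = 0.25   # fraction of image area
    lighting_change_est_time: int = 30
    min_contour_area: float = 50.0
    max_candidates: int = 5
    epipolar_threshold_px: float = 20.0
    # learning rate used while the model re-stabilises after a reset; the
    # reset exists to shorten stabilisation, so adaptation is fastest there
    post_reset_learning_rate: float | None = None
    # plant contrast polarity per view ('bright', 'dark' or 'any'): the
    # booth is built so the plant is bright against the dark floor cover
    # from above and dark against the white wall from the side
    polarity: dict = field(default_factory=lambda: {
        "top": "bright", "side": "dark"})
    mog: dict = field(default_factory=lambda: {
        "max_components": 5,
        "learning_rate": 0.01,
        "background_threshold": 0.9,
        "var_threshold": 16.0,
    })


def luminance_series(frames) -> np.ndarray:
    """Mean grey level per frame."""
    return np.array([float(np.mean(f)) for f in frames])


def sync_sequences(frames_top, frames_side) -> SyncResult:
    return estimate_offset(luminance_series(frames_top),
                           luminance_series(frames_side))


def track_sequence(frames, view: str, base: BaseAnchor,
                   settings: TrackingSettings,
                   F: np.ndarray | None = None,
                   top_track: list | None = None,
                   offset: int = 0):
    """Track the tip through one view's frame sequence.

    For the side view, pass the rig's fundamental matrix ``F``, the
    gap-free top-view track and the stereo ``offset`` so each side frame
    ``j`` can use the epipolar line of the top tip at frame ``j - offset``.

    Returns ``(track, lighting_change_frames)`` where ``track`` is gap-free
    over the full sequence.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("empty sequence")
    h, w = frames[0].shape
    lighting_cfg = LightingConfig(
        lighting_change_area=settings.lighting_change_area_frac * h * w,
        lighting_change_est_time=settings.lighting_change_est_time,
    )
    top_by_frame = ({o.frame_id: o for o in top_track}
                    if top_track is not None else {})

    model = MixtureBackgroundModel.from_frame(frames[0], **settings.mog)
    base_lr = model.learning_rate
    boost_lr = settings.post_reset_learning_rate
    # the first frames are a stabilisation window too (the model was just
    # seeded), so the burn-in learning rate applies from the start; the
    # lighting-change check itself is live immediately
    frames_since_change = lighting_cfg.lighting_change_est_time
    if boost_lr is not None:
        model.learning_rate = boost_lr
        frames_since_change = 0
    observations = {}
    previous = None
    lighting_changes = []
    pol = settings.polarity.get(view, "any")
    for i in range(n):
        raw_mask = model.update_and_classify(frames[i])
        mask = polarity_filter(model, frames[i], raw_mask, pol)
        # the lighting-change check watches the unfiltered foreground: a
        # global illumination step flips intensities in one direction, which
        # the polarity filter could otherwise hide from one of the views
        raw_contours = find_contours(raw_mask, settings.min_contour_area)
        contours = find_contours(mask, settings.min_contour_area)
        if check_lighting_change(raw_contours, lighting_cfg,
                                 frames_since_change):
            logger.debug("%s frame %d: lighting change, model reset", view, i)
            model = reset_model(model, frames[i])
            lighting_changes.append(i)
            frames_since_change = 0
            if boost_lr is not None:
                model.learning_rate = boost_lr
            continue  # no candidates on the reset frame
        frames_since_change += 1
        if (boost_lr is not None
                and frames_since_change >= lighting_cfg.lighting_change_est_time):
            model.learning_rate = base_lr
        if view == "top":
            cands = extract_candidates_top(contours, base,
                                           settings.max_candidates,
                                           frame_id=i)
        else:
            line = None
            if F is not None:
                top_obs = top_by_frame.get(i - offset)
                if top_obs is not None:
                    line = epipolar_line(F, (top_obs.u, top_obs.v))
            cands = extract_candidates_side(
                contours, base, line=line,
                dist_threshold=settings.epipolar_threshold_px,
                max_candidates=settings.max_candidates, frame_id=i)
        obs = select_tip(cands, previous)
        if obs is not None:
            observations[i] = obs
            previous = obs
    track = interpolate_gaps(observations, (0, n - 1), view)
    return track, lighting_changes


def track_pair(frames_top, frames_side, base_top: BaseAnchor,
               base_side: BaseAnchor, settings: TrackingSettings,
               F: np.ndarray | None = None,
               sync: SyncResult | None = None):
    """Track both views; returns (track_top, track_side, sync)."""
    if sync is None:
        sync = sync_sequences(frames_top, frames_side)
    logger.info("stereo offset: %d frames", sync.offset_frames)
    track_top, _ = track_sequence(frames_top, "top", base_top, settings)
    track_side, _ = track_sequence(frames_side, "side", base_side, settings,
                                   F=F, top_track=track_top,
                                   offset=sync.offset_frames)
    return track_top, track_side, sync
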