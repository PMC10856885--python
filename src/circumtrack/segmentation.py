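"""Per-pixel Gaussian-mixture background subtraction with lighting logic.

Each pixel is modelled by up to ``max_components`` Gaussians over grey-level
intensity, updated online with an exponential learning rate. A pixel is
classified as background when it matches (squared Mahalanobis distance below
``var_threshold``) one of the highest-weight components whose cumulative
weight reaches ``background_threshold``; otherwise it is foreground and, on
no match at all, the weakest component is replaced by a fresh one centred on
the observed value.

Time-lapse recordings under a light:dark photoperiod show abrupt global
illumination steps that would otherwise flood the foreground for many
frames. The pipeline therefore watches the total foreground contour area:
when it exceeds ``lighting_change_area`` the event is declared a lighting
change, the model is reset (reseeded from the current frame, which restores
a clean background within a frame instead of waiting for the mixture to
re-stabilise) and re-detection is suppressed for
``lighting_change_est_time`` frames.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .exceptions import IncompatibleFrame


@dataclass(frozen=True)
class LightingConfig:
    lighting_change_area: float   # px^2 threshold on total foreground area
    lighting_change_est_time: int  # frames of cooldown after a reset

    def __post_init__(self):
        if not (self.lighting_change_area > 0
                and self.lighting_change_est_time > 0):
            raise ValueError("lighting parameters must be positive")


@dataclass(frozen=True)
class Contour:
    """One 8-connected foreground region."""

    id: int
    area: float
    coords: np.ndarray  # (N, 2) as (row, col)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    contours: list
    lighting_change: bool
    model_reset: bool


class MixtureBackgroundModel:
    """Vectorised per-pixel mixture of Gaussians over a grey-level image."""

    def __init__(self, shape, max_components: int = 5,
                 learning_rate: float = 0.01,
                 background_threshold: float = 0.9,
                 var_threshold: float = 16.0,
                 var_floor: float = 1.0,
                 var_init: float = 25.0,
                 var_seed: float = 4.0):
        self.shape = tuple(shape)
        self.max_components = max_components
        self.learning_rate = learning_rate
        self.background_threshold = background_threshold
        self.var_threshold = var_threshold
        self.var_floor = var_floor
        self.var_init = var_init
        self.var_seed = var_seed
        k = max_components
        self.weights = np.zeros((k,) + self.shape, dtype=np.float32)
        self.means = np.zeros((k,) + self.shape, dtype=np.float32)
        self.variances = np.full((k,) + self.shape, var_init, dtype=np.float32)

    def dominant_mean(self) -> np.ndarray:
        """Per-pixel mean of the highest-weight component."""
        k = np.argmax(self.weights.reshape(self.max_components, -1), axis=0)
        mu = self.means.reshape(self.max_components, -1)
        return mu[k, np.arange(mu.shape[1])].reshape(self.shape)

    @classmethod
    def from_frame(cls, frame: np.ndarray, **kwargs) -> "MixtureBackgroundModel":
        model = cls(frame.shape, **kwargs)
        model.reset(frame)
        return model

    def reset(self, frame: np.ndarray) -> None:
        """Re-seed as a single full-weight component centred on ``frame``."""
        if frame.shape != self.shape:
            raise IncompatibleFrame(
                f"frame {frame.shape} vs model {self.shape}")
        self.weights[:] = 0.0
        self.weights[0] = 1.0
        self.means[:] = 0.0
        self.means[0] = frame.astype(np.float32)
        self.variances[:] = self.var_init
        # seeded tighter than var_init so low-contrast objects (e.g. the
        # plant under the night safelight) are still separable, but wide
        # enough that sensor noise does not spawn spurious components
        self.variances[0] = max(self.var_floor, self.var_seed)

    def update_and_classify(self, frame: np.ndarray) -> np.ndarray:
        """Classify against the current model, then update it.

        Returns a boolean foreground mask (True = foreground).
        """
        if frame.shape != self.shape:
            raise IncompatibleFrame(
                f"frame {frame.shape} vs model {self.shape}")
        x = frame.astype(np.float32).ravel()
        k, hw = self.max_components, x.size
        w = self.weights.reshape(k, hw)
        mu = self.means.reshape(k, hw)
        var = self.variances.reshape(k, hw)
        diff = x[None] - mu
        d2 = diff * diff / var
        d2[(w <= 0) | (d2 >= self.var_threshold)] = np.inf
        ks = np.argmin(d2, axis=0)
        cols = np.arange(hw)
        has_match = d2[ks, cols] < np.inf

        # background classification: the matched component is background iff
        # the cumulative weight of strictly-heavier components (stable order)
        # is still below the threshold when it is reached
        w_k = w[ks, cols]
        heavier = np.zeros(hw, dtype=np.float32)
        for j in range(k):
            wj = w[j]
            before = (wj > w_k) | ((wj == w_k) & (j < ks))
            heavier += wj * before
        total = np.maximum(w.sum(axis=0), 1e-12)
        matched_is_bg = heavier < self.background_threshold * total
        foreground = ~(has_match & matched_is_bg)

        # online update of the matched component
        alpha = np.float32(self.learning_rate)
        w *= (1.0 - alpha)
        w_k = w[ks, cols] + alpha * has_match
        w[ks, cols] = w_k
        rho = np.where(has_match,
                       np.minimum(alpha / np.maximum(w_k, 1e-6), 1.0),
                       0.0).astype(np.float32)
        d_k = diff[ks, cols]
        mu[ks, cols] += rho * d_k
        var_k = var[ks, cols]
        var[ks, cols] = np.where(
            has_match,
            np.maximum(var_k + rho * (d_k * d_k - var_k), self.var_floor),
            var_k)

        # replace the weakest component where nothing matched
        no_match = np.flatnonzero(~has_match)
        if no_match.size:
            k_weak = np.argmin(w[:, no_match], axis=0)
            w[k_weak, no_match] = alpha
            mu[k_weak, no_match] = x[no_match]
            var[k_weak, no_match] = self.var_init

        w /= np.maximum(w.sum(axis=0, keepdims=True), 1e-12)
        return foreground.reshape(self.shape)


def segment_frame(model: MixtureBackgroundModel, frame: np.ndarray,
                  lighting_cfg: LightingConfig,
                  frames_since_last_change: int,
                  min_area: float = 50.0,
                  polarity: str = "any") -> SegmentationResult:
    """One classify/update step with lighting-change handling.

    If a lighting change is detected the model is reset in place and no
    contours are reported for the frame (the reset frame carries no
    usable foreground).
    """
    raw = model.update_and_classify(frame)
    mask = polarity_filter(model, frame, raw, polarity)
    raw_contours = find_contours(raw, min_area)
    change = check_lighting_change(raw_contours, lighting_cfg,
                                   frames_since_last_change)
    if change:
        model.reset(frame)
        return SegmentationResult(mask=np.zeros_like(raw), contours=[],
                                  lighting_change=True, model_reset=True)
    return SegmentationResult(mask=mask,
                              contours=find_contours(mask, min_area),
                              lighting_change=False, model_reset=False)


def polarity_filter(model: MixtureBackgroundModel, frame: np.ndarray,
                    mask: np.ndarray, polarity: str) -> np.ndarray:
    """Keep foreground pixels whose contrast sign matches the plant's.

    The recording booth is designed so the plant has a known contrast
    polarity against its background (bright against the dark floor cover in
    the overhead view, dark against the white wall in the lateral view).
    Pixels a moving plant part *vacates* revert to the background colour —
    the opposite sign — so this filter removes motion trails and
    post-reset ghosts while keeping the plant itself.
    """
    if polarity == "any":
        return mask
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright', 'dark' or 'any'")
    dom = model.dominant_mean()
    x = frame.astype(np.float32)
    if polarity == "bright":
        return mask & (x > dom)
    return mask & (x < dom)


def reset_model(model: MixtureBackgroundModel,
                frame: np.ndarray) -> MixtureBackgroundModel:
    """Fresh single-component model seeded with ``frame`` (same settings)."""
    fresh = MixtureBackgroundModel(
        model.shape, max_components=model.max_components,
        learning_rate=model.learning_rate,
        background_threshold=model.background_threshold,
        var_threshold=model.var_threshold, var_floor=model.var_floor,
        var_init=model.var_init, var_seed=model.var_seed)
    fresh.reset(frame)
    return fresh


def find_contours(mask: np.ndarray, min_area: float = 50.0) -> list:
    """8-connected foreground regions at least ``min_area`` px^2 in size."""
    lab = label(mask, connectivity=2)
    n = lab.max()
    if n == 0:
        return []
    rows, cols = np.nonzero(lab)
    labs = lab[rows, cols]
    areas = np.bincount(labs, minlength=n + 1)
    order = np.argsort(labs, kind="stable")
    rows, cols, labs = rows[order], cols[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, n + 2))
    out = []
    for lab_id in range(1, n + 1):
        if areas[lab_id] < min_area:
            continue
        lo, hi = bounds[lab_id - 1], bounds[lab_id]
        coords = np.column_stack([rows[lo:hi], cols[lo:hi]])
        out.append(Contour(id=int(lab_id), area=float(areas[lab_id]),
                           coords=coords))
    return out


def total_contour_area(contours) -> float:
    return float(sum(c.area for c in contours))


def check_lighting_change(contours, cfg: LightingConfig,
                          frames_since_last_change: int) -> bool:
    """True iff foreground area exceeds the threshold and cooldown elapsed."""
    if frames_since_last_change < cfg.lighting_change_est_time:
        return False
    return total_contour_area(contours) > cfg.lighting_change_area
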