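"""Per-frame plant-tip candidate extraction.

Overhead (top) view: each retained foreground contour contributes one
candidate — the pixel at maximal geodesic (within-mask shortest-path)
distance from the contour pixel nearest the plant-base anchor. The geodesic
criterion finds the far end of the segmented plant even when the contour
curls back on itself, where a plain Euclidean extremum would fail.

Lateral (side) view: the epipolar line of the top-view tip restricts which
contour fragments can contain the tip; within each selected fragment the
same minimum-path rule localises the candidate. When no top-view estimate
exists for a frame the epipolar filter is skipped and all fragments are
considered.

Shortest paths run on the 8-connected pixel graph with step costs 1 and
sqrt(2). Ties in the maximal distance are broken towards larger v (lower in
the image), then larger u, for determinism.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.graph import MCP_Geometric

from .exceptions import EpipoleCoincidence


@dataclass(frozen=True)
class BaseAnchor:
    """Pixel marking the pot/plant base in one view."""

    view: str
    pixel: tuple  # (u, v)


@dataclass(frozen=True)
class Candidate:
    u: float
    v: float
    contour_id: int
    geodesic_score: float


@dataclass
class CandidateSet:
    frame_id: int
    view: str
    candidates: list = field(default_factory=list)

    @property
    def points(self) -> np.ndarray:
        return np.array([[c.u, c.v] for c in self.candidates]).reshape(-1, 2)


def geodesic_tip(contour, base: BaseAnchor):
    """(candidate_pixel (u, v), geodesic distance) for one contour.

    The source is the contour pixel nearest the base anchor (Euclidean); the
    candidate is the pixel with maximal shortest-path distance from it.
    """
    coords = contour.coords  # (N, 2) row, col
    bu, bv = base.pixel
    d_base = np.hypot(coords[:, 1] - bu, coords[:, 0] - bv)
    src = coords[np.argmin(d_base)]

    r0, c0 = coords[:, 0].min(), coords[:, 1].min()
    r1, c1 = coords[:, 0].max(), coords[:, 1].max()
    sub = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    sub[coords[:, 0] - r0, coords[:, 1] - c0] = True
    costs = np.where(sub, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    dist, _ = mcp.find_costs([(src[0] - r0, src[1] - c0)])
    dist = np.where(sub, dist, -np.inf)
    best = np.max(dist)
    rows, cols = np.nonzero(dist >= best - 1e-9)
    # tie-break: larger v (row), then larger u (col)
    order = np.lexsort((cols, rows))
    r, c = rows[order[-1]], cols[order[-1]]
    return (float(c + c0), float(r + r0)), float(best)


def extract_candidates_top(contours, base: BaseAnchor, max_candidates: int = 5,
                           frame_id: int = 0) -> CandidateSet:
    """One geodesic-farthest candidate per contour, ranked by contour area."""
    ranked = sorted(contours, key=lambda c: -c.area)[:max_candidates]
    cands = []
    for contour in ranked:
        (u, v), score = geodesic_tip(contour, base)
        cands.append(Candidate(u=u, v=v, contour_id=contour.id,
                               geodesic_score=score))
    return CandidateSet(frame_id=frame_id, view="top", candidates=cands)


def epipolar_line(F: np.ndarray, p_top) -> tuple:
    """Normalised epipolar line (a, b, c) in the side view, a^2 + b^2 = 1."""
    p = np.array([p_top[0], p_top[1], 1.0])
    l = np.asarray(F, float) @ p
    norm = np.hypot(l[0], l[1])
    if norm < 1e-12:
        raise EpipoleCoincidence("point maps to the epipole")
    return (l[0] / norm, l[1] / norm, l[2] / norm)


def point_line_distance(line, uv: np.ndarray) -> np.ndarray:
    a, b, c = line
    uv = np.asarray(uv, float)
    return np.abs(a * uv[..., 0] + b * uv[..., 1] + c)


def select_fragments_near_line(contours, line, dist_threshold: float = 20.0):
    """Contours within ``dist_threshold`` px of the line; closest if none."""
    if not contours:
        return []
    dists = []
    for contour in contours:
        uv = contour.coords[:, ::-1]  # (col,row) -> treat as (u, v)
        dists.append(float(point_line_distance(line, uv).min()))
    near = [c for c, d in zip(contours, dists) if d <= dist_threshold]
    if near:
        return near
    return [contours[int(np.argmin(dists))]]


def min_path_tip(contour, base: BaseAnchor) -> Candidate:
    """Minimum-path tip candidate for one fragment (see :func:`geodesic_tip`)."""
    (u, v), score = geodesic_tip(contour, base)
    return Candidate(u=u, v=v, contour_id=contour.id, geodesic_score=score)


def extract_candidates_side(contours, base: BaseAnchor, line=None,
                            dist_threshold: float = 20.0,
                            max_candidates: int = 5,
                            frame_id: int = 0) -> CandidateSet:
    """Epipolar fragment selection followed by minimum-path localisation."""
    if line is not None:
        frags = select_fragments_near_line(contours, line, dist_threshold)
    else:
        frags = list(contours)
    frags = sorted(frags, key=lambda c: -c.area)[:max_candidates]
    cands = [min_path_tip(c, base) for c in frags]
    return CandidateSet(frame_id=frame_id, view="side", candidates=cands)
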