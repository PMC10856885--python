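"""Temporal tip selection, gap interpolation, corrections and stereo sync.

Selection rule: a single candidate is taken as-is (label ``automatic``);
among several, the candidate closest to the previously selected point wins
(label ``estimated``; highest-ranked candidate if there is no history).
Frames with no candidate are filled afterwards by per-coordinate linear
interpolation between the bounding observations (label ``interpolated``);
leading/trailing gaps hold the nearest observation. User corrections
replace points (label ``manual``) and any interpolated stretch whose
bounding observation changed is recomputed, keeping the track
self-consistent.

Stereo synchronisation exploits the photoperiod: the cameras' free-running
clocks are aligned by locating the sharp global-luminance steps of the
light/dark transitions in both sequences and differencing their frame
indices.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidCorrection,
    NothingToInterpolate,
    Unsynchronizable,
)

LABELS = ("automatic", "estimated", "interpolated", "manual")


@dataclass(frozen=True)
class TipObservation:
    frame_id: int
    view: str
    u: float
    v: float
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class SyncResult:
    offset_frames: int
    transition_frames_top: list
    transition_frames_side: list


class CorrectionTable:
    """Manual tip positions keyed by (frame_id, view)."""

    def __init__(self, entries=None):
        self._map = dict(entries or {})

    def __len__(self):
        return len(self._map)

    def add(self, frame_id: int, view: str, u: float, v: float):
        self._map[(int(frame_id), view)] = (float(u), float(v))

    def get(self, frame_id: int, view: str):
        return self._map.get((frame_id, view))

    def items(self):
        return self._map.items()

    @classmethod
    def from_csv(cls, path) -> "CorrectionTable":
        df = pd.read_csv(path)
        required = {"frame_id", "view", "u", "v"}
        if not required.issubset(df.columns):
            raise ValueError(f"corrections CSV needs columns {sorted(required)}")
        table = cls()
        for row in df.itertuples():
            table.add(row.frame_id, row.view, row.u, row.v)
        return table

    def to_csv(self, path) -> None:
        rows = [
            {"frame_id": f, "view": view, "u": u, "v": v}
            for (f, view), (u, v) in sorted(self._map.items())
        ]
        pd.DataFrame(rows, columns=["frame_id", "view", "u", "v"]).to_csv(
            path, index=False)


def select_tip(candidates, previous: TipObservation | None
               ) -> TipObservation | None:
    """Pick one tip observation from a CandidateSet, or None if empty."""
    cands = candidates.candidates
    if not cands:
        return None
    if len(cands) == 1:
        c = cands[0]
        return TipObservation(candidates.frame_id, candidates.view,
                              c.u, c.v, "automatic")
    if previous is None:
        c = cands[0]  # highest-ranked
    else:
        d = [np.hypot(c.u - previous.u, c.v - previous.v) for c in cands]
        c = cands[int(np.argmin(d))]  # ties: lower candidate index
    return TipObservation(candidates.frame_id, candidates.view,
                          c.u, c.v, "estimated")


def interpolate_gaps(observations: dict, frame_range, view: str) -> list:
    """Gap-free track over ``frame_range`` = (start, end) inclusive.

    ``observations`` maps frame_id -> TipObservation for observed frames.
    Interior gaps are linearly interpolated; leading/trailing gaps hold the
    nearest observation. All fill-ins carry the ``interpolated`` label.
    """
    start, end = frame_range
    frames = [f for f in sorted(observations) if start <= f <= end]
    if not frames:
        raise NothingToInterpolate("no observed frames in range")
    track = []
    for f in range(start, end + 1):
        if f in observations:
            track.append(observations[f])
            continue
        prev = max((g for g in frames if g < f), default=None)
        nxt = min((g for g in frames if g > f), default=None)
        if prev is None:
            src = observations[nxt]
            u, v = src.u, src.v
        elif nxt is None:
            src = observations[prev]
            u, v = src.u, src.v
        else:
            a, b = observations[prev], observations[nxt]
            w = (f - prev) / (nxt - prev)
            u = a.u + w * (b.u - a.u)
            v = a.v + w * (b.v - a.v)
        track.append(TipObservation(f, view, float(u), float(v),
                                    "interpolated"))
    return track


def apply_corrections(track: list, corrections: CorrectionTable) -> list:
    """Merge manual corrections into a gap-free track.

    Corrected frames become ``manual``; interpolated stretches are then
    recomputed from the updated set of anchored (non-interpolated)
    observations, so fills bounded by a corrected point stay consistent.
    """
    if not track:
        return track
    view = track[0].view
    start, end = track[0].frame_id, track[-1].frame_id
    by_frame = {o.frame_id: o for o in track}
    relevant = {f: (u, v) for (f, w), (u, v) in corrections.items()
                if w == view}
    for f in relevant:
        if f < start or f > end:
            raise InvalidCorrection(
                f"correction frame {f} outside range [{start}, {end}]")
    if not relevant:
        return list(track)
    anchored = {f: o for f, o in by_frame.items()
                if o.label != "interpolated"}
    for f, (u, v) in relevant.items():
        anchored[f] = TipObservation(f, view, u, v, "manual")
    return interpolate_gaps(anchored, (start, end), view)


def find_transitions(series: np.ndarray) -> list:
    """Frame indices where the luminance steps by > half its dynamic range."""
    series = np.asarray(series, float)
    rng = series.max() - series.min()
    if rng <= 0:
        return []
    d = np.abs(np.diff(series))
    return [int(i) + 1 for i in np.flatnonzero(d > 0.5 * rng)]


def estimate_offset(luminance_top: np.ndarray,
                    luminance_side: np.ndarray) -> SyncResult:
    """Side-relative-to-top frame offset from photoperiod luminance steps."""
    t_top = find_transitions(luminance_top)
    t_side = find_transitions(luminance_side)
    if not t_top or not t_side:
        raise Unsynchronizable("no photoperiod transition in a series")
    offset = t_side[0] - t_top[0]
    return SyncResult(offset_frames=int(offset),
                      transition_frames_top=t_top,
                      transition_frames_side=t_side)


def detection_summary(track: list) -> dict:
    """Counts per detection label for one gap-free track."""
    counts = {label: 0 for label in LABELS}
    for o in track:
        counts[o.label] += 1
    return counts


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

def track_to_csv(track: list, path) -> None:
    pd.DataFrame(
        [{"frame_id": o.frame_id, "view": o.view, "u": o.u, "v": o.v,
          "label": o.label} for o in track]
    ).to_csv(path, index=False)


def track_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [TipObservation(int(r.frame_id), r.view, float(r.u), float(r.v),
                           r.label) for r in df.itertuples()]
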