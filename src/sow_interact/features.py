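"""Trajectory features computed on a period view of an event window.

Six variable families are derived from the two sows' key points and
postures over a sequence of annotated images:

* ``AvgD_p1_p2`` — mean Euclidean distance between a key-point pair;
* ``D_evolution_p1_p2`` — distance in the last image minus distance in
  the first image (negative means the points converge);
* ``Speed_p1_p2`` — rate of change of the pairwise distance (m/s);
* ``D_travelled_sowK`` — straight-line nose displacement of one sow
  between the first and last image;
* posture proportions — per-sow, pooled over both sows, plus the
  fraction of images with at least one sow standing and with both
  sows lying;
* ``duration_s`` — elapsed time between first and last image.

All distances are in meters; only ``D_evolution`` is signed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import (
    EventWindow,
    PairFrame,
    PERIODS,
    Point2D,
    Posture,
)

__all__ = [
    "KEY_POINT_PAIRS",
    "PairFeatureVector",
    "euclidean_distance",
    "avg_distance",
    "distance_evolution",
    "duration",
    "pair_speed",
    "individual_displacement",
    "posture_proportions",
    "extract_features",
    "features_dataframe",
]

#: The five key-point combinations used throughout: nose1-nose2,
#: nose1-neck2, nose2-neck1, nose1-tail2, nose2-tail1.
KEY_POINT_PAIRS: tuple[str, ...] = (
    "nose1_nose2", "nose1_neck2", "nose2_neck1", "nose1_tail2", "nose2_tail1",
)

_SPEED_MODES = ("endpoint", "cumulative")


def _pair_points(frame: PairFrame, pair: str) -> tuple[Point2D, Point2D]:
    part_a, part_b = pair.split("_")  # e.g. "nose1", "tail2"
    def resolve(tag: str) -> Point2D:
        sow = frame.sow1 if tag.endswith("1") else frame.sow2
        return getattr(sow.keypoints, tag[:-1])
    return resolve(part_a), resolve(part_b)


def euclidean_distance(a: Point2D, b: Point2D) -> float:
    """Planar Euclidean distance between two key points (meters)."""
    if not all(math.isfinite(v) for v in (a.x, a.y, b.x, b.y)):
        raise ValueError("non-finite coordinates")
    return math.hypot(b.x - a.x, b.y - a.y)


def _pair_distances(frames: Sequence[PairFrame], pair: str) -> list[float]:
    if pair not in KEY_POINT_PAIRS:
        raise ValueError(f"unknown key-point pair {pair!r}")
    return [euclidean_distance(*_pair_points(f, pair)) for f in frames]


def avg_distance(frames: Sequence[PairFrame], pair: str) -> float:
    """Mean per-image distance for one key-point pair (AvgD)."""
    if not frames:
        raise ValueError("avg_distance requires at least one frame")
    d = _pair_distances(frames, pair)
    return sum(d) / len(d)


def distance_evolution(frames: Sequence[PairFrame], pair: str) -> float:
    """Last-image distance minus first-image distance (signed meters)."""
    if len(frames) < 2:
        raise ValueError("distance_evolution requires at least two frames")
    d = _pair_distances(frames, pair)
    return d[-1] - d[0]


def duration(frames_or_timestamps: Sequence) -> float:
    """Elapsed seconds between the first and last time point.

    Accepts a frame sequence or a bare timestamp sequence.  For
    annotated windows this equals (n_frames - 1) x sampling interval.
    """
    seq = list(frames_or_timestamps)
    if len(seq) < 2:
        raise ValueError("duration requires at least two time points")
    ts = [f.timestamp_s if isinstance(f, PairFrame) else float(f) for f in seq]
    return ts[-1] - ts[0]


def pair_speed(frames: Sequence[PairFrame], pair: str, mode: str = "endpoint") -> float:
    """Rate of change of the pairwise distance, in m/s (unsigned).

    ``endpoint`` (default): |distance_evolution| / duration — the net
    change of the pairwise distance per second.  ``cumulative``: sum of
    |frame-to-frame distance changes| / duration, which also counts
    back-and-forth movement and is therefore >= the endpoint speed.
    """
    if mode not in _SPEED_MODES:
        raise ValueError(f"speed mode must be one of {_SPEED_MODES}, got {mode!r}")
    dur = duration(frames)
    if dur <= 0:
        raise ValueError("pair_speed requires positive duration")
    d = _pair_distances(frames, pair)
    if mode == "endpoint":
        travelled = abs(d[-1] - d[0])
    else:
        travelled = sum(abs(b - a) for a, b in zip(d, d[1:]))
    return travelled / dur


def individual_displacement(frames: Sequence[PairFrame], sow_role: int) -> float:
    """Straight-line nose displacement of one sow, first to last image."""
    if len(frames) < 2:
        raise ValueError("individual_displacement requires at least two frames")
    if sow_role not in (1, 2):
        raise ValueError("sow_role must be 1 or 2")
    sow = "sow1" if sow_role == 1 else "sow2"
    first = getattr(frames[0], sow).keypoints.nose
    last = getattr(frames[-1], sow).keypoints.nose
    return euclidean_distance(first, last)


def posture_proportions(frames: Sequence[PairFrame]) -> dict:
    """Posture occupancy over a frame sequence.

    Returns per-sow proportions (each summing to 1), proportions pooled
    over the 2n sow-frames, the fraction of images where at least one
    sow stands, and the fraction where both sows lie.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("posture_proportions requires at least one frame")
    per_sow = {1: {p: 0 for p in Posture}, 2: {p: 0 for p in Posture}}
    any_standing = both_lying = 0
    for f in frames:
        per_sow[1][f.sow1.posture] += 1
        per_sow[2][f.sow2.posture] += 1
        postures = (f.sow1.posture, f.sow2.posture)
        if Posture.STANDING in postures:
            any_standing += 1
        if postures == (Posture.LYING, Posture.LYING):
            both_lying += 1
    prop1 = {p: c / n for p, c in per_sow[1].items()}
    prop2 = {p: c / n for p, c in per_sow[2].items()}
    pooled = {p: (per_sow[1][p] + per_sow[2][p]) / (2 * n) for p in Posture}
    return {
        "sow1": prop1,
        "sow2": prop2,
        "pooled": pooled,
        "any_standing": any_standing / n,
        "both_lying": both_lying / n,
    }


@dataclass(frozen=True)
class PairFeatureVector:
    """All features of one (event, period) pair."""

    event_id: str
    period: str
    avg_d: Mapping[str, float]
    d_evolution: Mapping[str, float]
    speed: Mapping[str, float]
    d_travelled_sow1: float
    d_travelled_sow2: float
    posture_prop_sow1: Mapping[Posture, float]
    posture_prop_sow2: Mapping[Posture, float]
    pooled_prop: Mapping[Posture, float]
    any_standing_prop: float
    both_lying_prop: float
    duration_s: float

    def to_flat_dict(self) -> dict[str, float]:
        """Flatten under the stable column names used by rules and CSVs."""
        out: dict[str, float] = {}
        for pair in KEY_POINT_PAIRS:
            out[f"avg_d_{pair}"] = self.avg_d[pair]
            out[f"d_evolution_{pair}"] = self.d_evolution[pair]
            out[f"speed_{pair}"] = self.speed[pair]
        out["d_travelled_sow1"] = self.d_travelled_sow1
        out["d_travelled_sow2"] = self.d_travelled_sow2
        for p in Posture:
            out[f"prop_sow1_{p.value}"] = self.posture_prop_sow1[p]
            out[f"prop_sow2_{p.value}"] = self.posture_prop_sow2[p]
            out[f"prop_pooled_{p.value}"] = self.pooled_prop[p]
        out["prop_any_standing"] = self.any_standing_prop
        out["prop_both_lying"] = self.both_lying_prop
        out["duration_s"] = self.duration_s
        return out


#: Flat feature-column names, in serialization order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"{fam}_{pair}" for pair in KEY_POINT_PAIRS
     for fam in ("avg_d", "d_evolution", "speed")]
    + ["d_travelled_sow1", "d_travelled_sow2"]
    + [f"prop_{who}_{p.value}" for who in ("sow1", "sow2", "pooled") for p in Posture]
    + ["prop_any_standing", "prop_both_lying", "duration_s"]
)


def extract_features(event: EventWindow, period: str,
                     speed_mode: str = "endpoint") -> PairFeatureVector:
    """Compute the full feature vector for one period view of an event."""
    frames = event.period_frames(period)
    props = posture_proportions(frames)
    return PairFeatureVector(
        event_id=event.event_id,
        period=period,
        avg_d={p: avg_distance(frames, p) for p in KEY_POINT_PAIRS},
        d_evolution={p: distance_evolution(frames, p) for p in KEY_POINT_PAIRS},
        speed={p: pair_speed(frames, p, speed_mode) for p in KEY_POINT_PAIRS},
        d_travelled_sow1=individual_displacement(frames, 1),
        d_travelled_sow2=individual_displacement(frames, 2),
        posture_prop_sow1=props["sow1"],
        posture_prop_sow2=props["sow2"],
        pooled_prop=props["pooled"],
        any_standing_prop=props["any_standing"],
        both_lying_prop=props["both_lying"],
        duration_s=duration(frames),
    )


def features_dataframe(events: Iterable[EventWindow],
                       periods: Sequence[str] = PERIODS,
                       speed_mode: str = "endpoint") -> pd.DataFrame:
    """One row per (event, period) with flattened features and labels."""
    rows = []
    for ev in events:
        for period in periods:
            fv = extract_features(ev, period, speed_mode=speed_mode)
            row = {"event_id": ev.event_id, "period": period,
                   "situation": ev.situation.value,
                   "valence": ev.valence.value if ev.valence else "",
                   "orientation": ev.orientation.value if ev.orientation else ""}
            row.update(fv.to_flat_dict())
            rows.append(row)
    cols = ["event_id", "period", "situation", "valence", "orientation",
            *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
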