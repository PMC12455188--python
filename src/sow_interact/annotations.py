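"""Data model and CSV round-tripping for annotated two-sow event windows.

An *event window* is the unit of annotation: 10 images sampled every
0.5 s around one social interaction (4 before, start, end, 4 after) or
around a moment with no interaction.  Each image carries, for both sows
of the observed pair, a posture label and the planar coordinates of
three anatomical key points (nose, neck, tail).

Coordinates are stored internally in meters.  The annotation CSV keeps
pixel coordinates, so a :class:`CalibrationSpec` (pixels per meter) is
applied at read time and inverted at write time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AnnotationError",
    "MalformedPairError",
    "VocabularyError",
    "OrderingError",
    "InconsistencyError",
    "Point2D",
    "KeyPoints",
    "Posture",
    "SowFrame",
    "PairFrame",
    "EventWindow",
    "CalibrationSpec",
    "INTERACTION_PHASES",
    "NON_INTERACTION_PHASES",
    "CSV_COLUMNS",
    "pair_rows",
    "read_annotations",
    "write_annotations",
    "write_manifest",
]


class AnnotationError(ValueError):
    """Base class for malformed annotation input."""


class MalformedPairError(AnnotationError):
    """An image does not contribute exactly two sow rows."""


class VocabularyError(AnnotationError):
    """Unknown posture / situation / valence / orientation token."""


class OrderingError(AnnotationError):
    """Timestamps not strictly increasing within an event."""


class InconsistencyError(AnnotationError):
    """The two rows of one image disagree on shared labels."""


class Posture(str, enum.Enum):
    STANDING = "standing"
    SITTING = "sitting"
    LYING = "lying"


class Situation(str, enum.Enum):
    INTERACTION = "interaction"
    NO_INTERACTION = "no_interaction"


class Valence(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Orientation(str, enum.Enum):
    NOSE_NOSE = "nose_nose"
    NOSE_NECK = "nose_neck"
    NOSE_TAIL = "nose_tail"


#: Phase tags of the ten annotated images of an interaction window:
#: four before (B1-B4), start (S), end (E), four after (A1-A4).
INTERACTION_PHASES: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "S", "E", "A1", "A2", "A3", "A4",
)

#: Non-interaction windows have no start/end landmarks; frames are
#: tagged N01..N10 and period views use the same index convention.
NON_INTERACTION_PHASES: tuple[str, ...] = tuple(f"N{i:02d}" for i in range(1, 11))

#: Fixed column order of the annotation CSV dialect (two rows per image).
CSV_COLUMNS: tuple[str, ...] = (
    "event_id", "frame_index", "phase", "timestamp_s", "sow_role",
    "sow_label", "posture", "nose_x", "nose_y", "neck_x", "neck_y",
    "tail_x", "tail_y", "situation", "valence", "orientation",
)

_COORD_FMT = "{:.6f}"


@dataclass(frozen=True)
class Point2D:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise AnnotationError(f"non-finite coordinate: ({self.x}, {self.y})")


@dataclass(frozen=True)
class KeyPoints:
    nose: Point2D
    neck: Point2D
    tail: Point2D


@dataclass(frozen=True)
class SowFrame:
    sow_label: str
    role_index: int  # 1 or 2, arbitrary designation within the pair
    posture: Posture
    keypoints: KeyPoints

    def __post_init__(self) -> None:
        if self.role_index not in (1, 2):
            raise AnnotationError(f"role_index must be 1 or 2, got {self.role_index}")


@dataclass(frozen=True)
class PairFrame:
    """One annotated image: both sows of the pair plus event metadata."""

    event_id: str
    frame_index: int
    timestamp_s: float
    phase: str
    sow1: SowFrame
    sow2: SowFrame
    situation: Situation
    valence: Valence | None = None
    orientation: Orientation | None = None

    def __post_init__(self) -> None:
        if self.situation is Situation.INTERACTION:
            if self.valence is None or self.orientation is None:
                raise AnnotationError(
                    f"{self.event_id}[{self.frame_index}]: interaction frames "
                    "require valence and orientation labels"
                )
            if self.phase not in INTERACTION_PHASES:
                raise AnnotationError(
                    f"{self.event_id}: unknown interaction phase {self.phase!r}"
                )
        else:
            if self.valence is not None or self.orientation is not None:
                raise AnnotationError(
                    f"{self.event_id}: non-interaction frames must not carry "
                    "valence/orientation labels"
                )
            if self.phase not in NON_INTERACTION_PHASES:
                raise AnnotationError(
                    f"{self.event_id}: unknown non-interaction phase {self.phase!r}"
                )


# Period views over the ten frames.  "before" = the four pre-event
# images plus the start image, "during" = start and end, "after" = the
# end image plus the four post-event images.  Non-interaction windows
# use the same positional convention.
_PERIOD_SLICES: Mapping[str, slice] = {
    "before": slice(0, 5),
    "during": slice(4, 6),
    "after": slice(5, 10),
}

PERIODS: tuple[str, ...] = ("before", "during", "after")


@dataclass(frozen=True)
class EventWindow:
    """Ordered 10-frame annotation window for a single event."""

    event_id: str
    frames: tuple[PairFrame, ...]

    def __post_init__(self) -> None:
        if len(self.frames) != 10:
            raise AnnotationError(
                f"{self.event_id}: an event window has exactly 10 frames, "
                f"got {len(self.frames)}"
            )
        ts = [f.timestamp_s for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise OrderingError(f"{self.event_id}: timestamps not strictly increasing")
        for f in self.frames:
            if f.event_id != self.event_id:
                raise AnnotationError(
                    f"frame event_id {f.event_id!r} != window {self.event_id!r}"
                )

    @property
    def situation(self) -> Situation:
        return self.frames[0].situation

    @property
    def valence(self) -> Valence | None:
        return self.frames[0].valence

    @property
    def orientation(self) -> Orientation | None:
        return self.frames[0].orientation

    def period_frames(self, period: str) -> tuple[PairFrame, ...]:
        try:
            sl = _PERIOD_SLICES[period]
        except KeyError:
            raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
        return self.frames[sl]

    @property
    def before(self) -> tuple[PairFrame, ...]:
        return self.period_frames("before")

    @property
    def during(self) -> tuple[PairFrame, ...]:
        return self.period_frames("during")

    @property
    def after(self) -> tuple[PairFrame, ...]:
        return self.period_frames("after")


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel-to-meter scale and timing of the source video.

    ``pixels_per_meter`` converts annotation pixel coordinates to the
    canonical meter scale used by every feature and published
    threshold.  ``fps`` is the native video rate; annotated frames are
    subsampled at ``sampling_interval_s``.
    """

    pixels_per_meter: float = 1.0
    fps: float = 12.0
    sampling_interval_s: float = 0.5

    def __post_init__(self) -> None:
        if self.pixels_per_meter <= 0:
            raise ValueError("pixels_per_meter must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be > 0")


def _parse_enum(cls, token: str, context: str):
    try:
        return cls(token)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise VocabularyError(
            f"{context}: unknown {cls.__name__.lower()} token {token!r} "
            f"(expected one of: {valid})"
        ) from None


def _row_to_sow(row: Mapping, ppm: float) -> SowFrame:
    def pt(prefix: str) -> Point2D:
        return Point2D(float(row[f"{prefix}_x"]) / ppm, float(row[f"{prefix}_y"]) / ppm)

    context = f"{row['event_id']}[{row['frame_index']}] sow {row['sow_role']}"
    return SowFrame(
        sow_label=str(row["sow_label"]),
        role_index=int(row["sow_role"]),
        posture=_parse_enum(Posture, str(row["posture"]), context),
        keypoints=KeyPoints(pt("nose"), pt("neck"), pt("tail")),
    )


def pair_rows(row_sow1: Mapping, row_sow2: Mapping,
              calibration: CalibrationSpec | None = None) -> PairFrame:
    """Combine the two sow rows of one annotated image into a PairFrame.

    Rows may be given in either role order.  Shared labels (event,
    frame, phase, timestamp, situation, valence, orientation) must
    agree between the two rows.
    """
    calibration = calibration or CalibrationSpec()
    rows = sorted([row_sow1, row_sow2], key=lambda r: int(r["sow_role"]))
    roles = [int(r["sow_role"]) for r in rows]
    context = f"{rows[0]['event_id']}[{rows[0]['frame_index']}]"
    if roles != [1, 2]:
        raise MalformedPairError(f"{context}: expected sow roles {{1, 2}}, got {roles}")
    shared = ("event_id", "frame_index", "phase", "timestamp_s",
              "situation", "valence", "orientation")
    for key in shared:
        a, b = rows[0].get(key), rows[1].get(key)
        if _norm(a) != _norm(b):
            raise InconsistencyError(
                f"{context}: rows disagree on {key!r} ({a!r} vs {b!r})"
            )
    r = rows[0]
    situation = _parse_enum(Situation, _norm(r["situation"]) or "", context)
    valence = orientation = None
    if _norm(r.get("valence")):
        valence = _parse_enum(Valence, _norm(r["valence"]), context)
    if _norm(r.get("orientation")):
        orientation = _parse_enum(Orientation, _norm(r["orientation"]), context)
    return PairFrame(
        event_id=str(r["event_id"]),
        frame_index=int(r["frame_index"]),
        timestamp_s=float(r["timestamp_s"]),
        phase=str(r["phase"]),
        sow1=_row_to_sow(rows[0], calibration.pixels_per_meter),
        sow2=_row_to_sow(rows[1], calibration.pixels_per_meter),
        situation=situation,
        valence=valence,
        orientation=orientation,
    )


def _norm(value) -> str | None:
    """Missing optional labels may surface as None, NaN or ''."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    return s or None


def read_annotations(path, calibration: CalibrationSpec | None = None) -> list[EventWindow]:
    """Read an annotation CSV (two rows per image) into event windows.

    Events are returned in file order; frames within an event are
    ordered by ``frame_index``.  Pixel coordinates are divided by
    ``calibration.pixels_per_meter``.
    """
    calibration = calibration or CalibrationSpec()
    df = pd.read_csv(path, dtype={"event_id": str, "sow_label": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation file missing columns: {sorted(missing)}")

    windows: list[EventWindow] = []
    for event_id, ev in df.groupby("event_id", sort=False):
        frames: list[PairFrame] = []
        for frame_index, img in ev.groupby("frame_index", sort=True):
            if len(img) != 2:
                raise MalformedPairError(
                    f"event {event_id!r} frame {frame_index}: expected 2 sow "
                    f"rows, found {len(img)}"
                )
            recs = img.to_dict("records")
            frames.append(pair_rows(recs[0], recs[1], calibration))
        windows.append(EventWindow(event_id=str(event_id), frames=tuple(frames)))
    return windows


def events_to_dataframe(events: Iterable[EventWindow],
                        calibration: CalibrationSpec | None = None) -> pd.DataFrame:
    """Flatten event windows into the two-rows-per-image CSV layout."""
    calibration = calibration or CalibrationSpec()
    ppm = calibration.pixels_per_meter
    rows = []
    for ev in events:
        for fr in ev.frames:
            for sow in (fr.sow1, fr.sow2):
                kp = sow.keypoints
                rows.append({
                    "event_id": fr.event_id,
                    "frame_index": fr.frame_index,
                    "phase": fr.phase,
                    "timestamp_s": fr.timestamp_s,
                    "sow_role": sow.role_index,
                    "sow_label": sow.sow_label,
                    "posture": sow.posture.value,
                    "nose_x": kp.nose.x * ppm, "nose_y": kp.nose.y * ppm,
                    "neck_x": kp.neck.x * ppm, "neck_y": kp.neck.y * ppm,
                    "tail_x": kp.tail.x * ppm, "tail_y": kp.tail.y * ppm,
                    "situation": fr.situation.value,
                    "valence": fr.valence.value if fr.valence else "",
                    "orientation": fr.orientation.value if fr.orientation else "",
                })
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_annotations(events: Sequence[EventWindow], path,
                      calibration: CalibrationSpec | None = None) -> None:
    """Write event windows as the annotation CSV dialect.

    Coordinates are multiplied back to pixels and serialized with six
    decimals, so a write/read round trip reproduces coordinates to that
    precision.  An empty event list yields a header-only file.
    """
    df = events_to_dataframe(events, calibration)
    for col in ("nose_x", "nose_y", "neck_x", "neck_y", "tail_x", "tail_y",
                "timestamp_s"):
        df[col] = df[col].map(_COORD_FMT.format)
    df.to_csv(path, index=False, lineterminator="\n")


def write_manifest(events: Sequence[EventWindow], path) -> None:
    """One row per event: labels plus first/last annotated timestamps."""
    rows = [{
        "event_id": ev.event_id,
        "situation": ev.situation.value,
        "valence": ev.valence.value if ev.valence else "",
        "orientation": ev.orientation.value if ev.orientation else "",
        "t_start_s": _COORD_FMT.format(ev.frames[0].timestamp_s),
        "t_end_s": _COORD_FMT.format(ev.frames[-1].timestamp_s),
    } for ev in events]
    cols = ["event_id", "situation", "valence", "orientation", "t_start_s", "t_end_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, lineterminator="\n")
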