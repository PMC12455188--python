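"""Seeded generator of two-sow event windows.

Emulates the annotation study design: 10-frame windows sampled every
0.5 s (four images before the event, start, end, four after), for 120
positive interactions, 120 negative interactions and 120 non-
interaction moments in a 7.5 m x 8.0 m gestation pen.

The behavioural structure follows the ethogram and the reported
kinematics of each class:

* interactions begin with the initiator's nose converging on the
  recipient's target key point (nose, neck or tail, depending on the
  orientation) down to contact distance, with the initiator standing
  throughout;
* positive interactions end with a slow withdrawal and a recipient
  that stays put; negative interactions show a lunge at contact and a
  fast post-event separation with a marked recipient flight;
* non-interaction windows draw from three ethogram configurations:
  two sows lying side by side, static close proximity (not both
  lying), and distant independent wandering.

All kinematic distributions are truncated normals.  They are surrogate
parameters, not measured values: defaults are chosen so that the
class-conditional features straddle the published decision thresholds
(e.g. negative post-event nose-nose separation speeds around
0.6 m/s > 0.42 m/s, positive around 0.05 m/s).  ``effect_scale``
shrinks every class-specific movement toward immobility: at 0 the
interaction classes become kinematically indistinguishable from static
non-interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import (
    CalibrationSpec,
    EventWindow,
    INTERACTION_PHASES,
    KeyPoints,
    NON_INTERACTION_PHASES,
    Orientation,
    PairFrame,
    Point2D,
    Posture,
    Situation,
    SowFrame,
    Valence,
    write_annotations,
    write_manifest,
)

__all__ = [
    "TruncNormSpec",
    "GeneratorConfig",
    "generate_event",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated normal N(mean, sd) restricted to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside [{self.lo}, {self.hi}]")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def sample(self, rng: np.random.Generator) -> float:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                         random_state=rng))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design replica parameters and surrogate kinematics."""

    # event counts as annotated in the study
    n_positive: int = 120
    n_negative: int = 120
    n_none: int = 120

    # windowing
    frames_per_event: int = 10
    sampling_interval_s: float = 0.5

    # gestation pen (meters)
    arena_width: float = 7.5
    arena_depth: float = 8.0

    # body geometry (surrogate values, not measured)
    nose_neck_m: float = 0.6
    neck_tail_m: float = 1.0
    heading_jitter_rad: float = 0.05

    # approach kinematics
    approach_start_m: TruncNormSpec = TruncNormSpec(1.6, 0.3, 1.0, 2.5)
    contact_distance_m: float = 0.15

    # valence-specific kinematics
    negative_lunge_m: TruncNormSpec = TruncNormSpec(0.55, 0.10, 0.30, 0.90)
    negative_recoil_m: TruncNormSpec = TruncNormSpec(0.35, 0.10, 0.10, 0.60)
    negative_after_speed_ms: TruncNormSpec = TruncNormSpec(0.60, 0.12, 0.45, 0.90)
    flight_fraction: float = 0.7  # share of the post-event divergence borne by the recipient
    positive_after_speed_ms: TruncNormSpec = TruncNormSpec(0.05, 0.03, 0.0, 0.15)
    positive_recipient_drift_m: TruncNormSpec = TruncNormSpec(0.12, 0.08, 0.0, 0.35)

    # non-interaction templates
    lying_gap_m: TruncNormSpec = TruncNormSpec(0.45, 0.10, 0.30, 0.70)
    proximity_separation_m: TruncNormSpec = TruncNormSpec(1.8, 0.4, 1.0, 3.0)
    distant_separation_m: TruncNormSpec = TruncNormSpec(4.5, 0.8, 3.2, 6.2)
    wander_speed_ms: TruncNormSpec = TruncNormSpec(0.08, 0.04, 0.0, 0.20)

    # recipient posture probabilities (standing, sitting, lying)
    recipient_posture_p: tuple[float, float, float] = (0.4, 0.2, 0.4)
    # free posture probabilities for non-interaction sows
    free_posture_p: tuple[float, float, float] = (0.4, 0.2, 0.4)

    # orientation mix over (nose_nose, nose_neck, nose_tail): the
    # observed composition of the annotated interactions (119/68/53)
    orientation_mix: tuple[float, float, float] = (119 / 240, 68 / 240, 53 / 240)

    # measurement noise on every coordinate (meters)
    noise_sd_m: float = 0.01

    # global effect-size dial: 1 = full class contrast, 0 = immobile
    effect_scale: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_none) < 0:
            raise ValueError("event counts must be >= 0")
        if self.contact_distance_m >= self.approach_start_m.lo:
            raise ValueError(
                "infeasible config: contact distance must be below the "
                "smallest pre-approach separation"
            )
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ValueError("effect_scale must be in [0, 1]")
        if not 0.0 < self.flight_fraction < 1.0:
            raise ValueError("flight_fraction must be in (0, 1)")

    @property
    def body_length_m(self) -> float:
        return self.nose_neck_m + self.neck_tail_m


_POSTURES = (Posture.STANDING, Posture.SITTING, Posture.LYING)


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _body_from_nose(nose: np.ndarray, heading: np.ndarray,
                    cfg: GeneratorConfig) -> np.ndarray:
    """Key points (nose, neck, tail) for a body whose nose points along
    ``heading`` (unit vector from tail toward nose)."""
    return np.stack([
        nose,
        nose - cfg.nose_neck_m * heading,
        nose - cfg.body_length_m * heading,
    ])


_ORIENT_GEOMETRY = {
    # target key-point index on the recipient (nose=0, neck=1, tail=2)
    # and approach direction u (unit vector from target toward the
    # initiator's pre-approach position), recipient facing +x
    Orientation.NOSE_NOSE: (0, np.array([1.0, 0.0])),
    Orientation.NOSE_NECK: (1, np.array([0.0, 1.0])),
    Orientation.NOSE_TAIL: (2, np.array([-1.0, 0.0])),
}


def _interaction_tracks(valence: Valence, orientation: Orientation,
                        cfg: GeneratorConfig, rng: np.random.Generator):
    """Local-frame key-point tracks: (n_frames, 2 sows, 3 points, 2)."""
    n = cfg.frames_per_event
    dt = cfg.sampling_interval_s
    eff = cfg.effect_scale
    recipient = _body_from_nose(np.zeros(2), np.array([1.0, 0.0]), cfg)
    target_idx, u = _ORIENT_GEOMETRY[orientation]
    target = recipient[target_idx]
    perp = _rot(u, math.pi / 2)

    s0 = cfg.approach_start_m.sample(rng)
    s_end = s0 - eff * (s0 - cfg.contact_distance_m)

    # initiator nose distance to the target point, per frame
    dist = np.empty(n)
    dist[:5] = np.linspace(s0, s_end, 5)  # B1..B4, S
    dist[5:] = s_end                       # E, A1..A4 (separation added below)

    init_nose = np.stack([target + d * u for d in dist])
    recip_shift = np.zeros((n, 2))

    if valence is Valence.NEGATIVE:
        lunge = cfg.negative_lunge_m.sample(rng) * eff
        recoil = cfg.negative_recoil_m.sample(rng) * eff
        divergence = cfg.negative_after_speed_ms.sample(rng) * eff * 4 * dt
        flight = cfg.flight_fraction * divergence
        retreat = (1 - cfg.flight_fraction) * divergence
        lunge_sign = rng.choice([-1.0, 1.0])
        init_nose[5:] += lunge_sign * lunge * perp   # knock sweeps sideways at E
        recip_shift[5:] -= recoil * u                # recipient recoils away
        for j in range(1, 5):                        # A1..A4: flight + retreat
            init_nose[5 + j] += (j / 4) * retreat * u
            recip_shift[5 + j] -= (j / 4) * flight * u
    else:
        withdraw = cfg.positive_after_speed_ms.sample(rng) * eff * 4 * dt
        drift = cfg.positive_recipient_drift_m.sample(rng) * eff
        drift_dir = _rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
        for j in range(1, 5):
            init_nose[5 + j] += (j / 4) * withdraw * u
            recip_shift[5 + j] += (j / 4) * drift * drift_dir

    frames = np.empty((n, 2, 3, 2))
    for k in range(n):
        heading = _rot(-u, rng.normal(0.0, cfg.heading_jitter_rad))
        frames[k, 0] = _body_from_nose(init_nose[k], heading, cfg)
        frames[k, 1] = recipient + recip_shift[k]
    return frames


def _none_tracks(cfg: GeneratorConfig, rng: np.random.Generator):
    """Local-frame tracks for one non-interaction window plus postures."""
    n = cfg.frames_per_event
    dt = cfg.sampling_interval_s
    template = rng.choice(["lying", "proximity", "distant"])
    frames = np.empty((n, 2, 3, 2))

    def free_posture() -> Posture:
        return _POSTURES[rng.choice(3, p=cfg.free_posture_p)]

    if template == "lying":
        gap = cfg.lying_gap_m.sample(rng)
        shift = rng.normal(0.0, 0.2)
        a = _body_from_nose(np.zeros(2), np.array([1.0, 0.0]), cfg)
        b = _body_from_nose(np.array([shift, gap]), np.array([1.0, 0.0]), cfg)
        frames[:] = np.stack([a, b])
        postures = (Posture.LYING, Posture.LYING)
    elif template == "proximity":
        sep = cfg.proximity_separation_m.sample(rng)
        ang = rng.uniform(0, 2 * math.pi)
        ha = _rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
        hb = _rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
        a = _body_from_nose(np.zeros(2), ha, cfg)
        b = _body_from_nose(sep * _rot(np.array([1.0, 0.0]), ang), hb, cfg)
        frames[:] = np.stack([a, b])
        while True:
            postures = (free_posture(), free_posture())
            if postures != (Posture.LYING, Posture.LYING):
                break
    else:  # distant independent wander
        sep = cfg.distant_separation_m.sample(rng)
        ang = rng.uniform(0, 2 * math.pi)
        noses = [np.zeros(2), sep * _rot(np.array([1.0, 0.0]), ang)]
        headings = [_rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
                    for _ in range(2)]
        speeds = [cfg.wander_speed_ms.sample(rng) for _ in range(2)]
        walk_dirs = [_rot(np.array([1.0, 0.0]), rng.uniform(0, 2 * math.pi))
                     for _ in range(2)]
        for k in range(n):
            for s in range(2):
                pos = noses[s] + k * dt * speeds[s] * walk_dirs[s]
                frames[k, s] = _body_from_nose(pos, headings[s], cfg)
        while True:  # both-lying is reserved for the side-by-side template
            postures = (free_posture(), free_posture())
            if postures != (Posture.LYING, Posture.LYING):
                break
    return frames, postures, template


def _place_in_arena(frames: np.ndarray, cfg: GeneratorConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Random rotation + translation keeping all points inside the pen."""
    angle = rng.uniform(0, 2 * math.pi)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    out = frames @ rot.T
    margin = 0.05
    for axis, extent in ((0, cfg.arena_width), (1, cfg.arena_depth)):
        lo = out[..., axis].min()
        hi = out[..., axis].max()
        t_min = margin - lo
        t_max = extent - margin - hi
        if t_min <= t_max:
            t = rng.uniform(t_min, t_max)
        else:  # scene larger than the pen: center it, clipping will trim
            t = ((extent - (hi - lo)) / 2) - lo
        out[..., axis] += t
    out[..., 0] = np.clip(out[..., 0], 0.0, cfg.arena_width)
    out[..., 1] = np.clip(out[..., 1], 0.0, cfg.arena_depth)
    return out


def _sow_frame(label: str, role: int, posture: Posture,
               pts: np.ndarray) -> SowFrame:
    return SowFrame(
        sow_label=label, role_index=role, posture=posture,
        keypoints=KeyPoints(
            nose=Point2D(float(pts[0, 0]), float(pts[0, 1])),
            neck=Point2D(float(pts[1, 0]), float(pts[1, 1])),
            tail=Point2D(float(pts[2, 0]), float(pts[2, 1])),
        ),
    )


def generate_event(event_id: str, situation: Situation,
                   cfg: GeneratorConfig, rng: np.random.Generator,
                   valence: Valence | None = None,
                   orientation: Orientation | None = None) -> EventWindow:
    """Generate one 10-frame event window of the requested class.

    For interactions the initiator/recipient are assigned to roles 1/2
    at random, mirroring the arbitrary sow-1/sow-2 designation of the
    annotation protocol.
    """
    if situation is Situation.INTERACTION:
        if valence is None or orientation is None:
            raise ValueError("interaction events need valence and orientation")
        tracks = _interaction_tracks(valence, orientation, cfg, rng)
        recip_posture = _POSTURES[rng.choice(3, p=cfg.recipient_posture_p)]
        postures = (Posture.STANDING, recip_posture)  # initiator stands
        phases = INTERACTION_PHASES
    else:
        if valence is not None or orientation is not None:
            raise ValueError("non-interaction events carry no valence/orientation")
        tracks, postures, _ = _none_tracks(cfg, rng)
        phases = NON_INTERACTION_PHASES

    tracks = tracks + rng.normal(0.0, cfg.noise_sd_m, size=tracks.shape)
    tracks = _place_in_arena(tracks, cfg, rng)

    # arbitrary sow-1/sow-2 designation
    swap = bool(rng.integers(0, 2))
    order = (1, 0) if swap else (0, 1)
    ids = rng.choice(np.arange(1, 40), size=2, replace=False)
    labels = (f"S{ids[0]:02d}", f"S{ids[1]:02d}")

    t0 = 0.5 * float(rng.integers(0, 14400))
    frames = []
    for k in range(cfg.frames_per_event):
        sows = []
        for role, src in zip((1, 2), order):
            sows.append(_sow_frame(labels[role - 1], role, postures[src],
                                   tracks[k, src]))
        frames.append(PairFrame(
            event_id=event_id,
            frame_index=k,
            timestamp_s=t0 + k * cfg.sampling_interval_s,
            phase=phases[k],
            sow1=sows[0],
            sow2=sows[1],
            situation=situation,
            valence=valence,
            orientation=orientation,
        ))
    return EventWindow(event_id=event_id, frames=tuple(frames))


def generate_dataset(cfg: GeneratorConfig) -> list[EventWindow]:
    """Generate the full replica dataset, deterministic for a fixed seed.

    Returns ``n_positive + n_negative`` interaction windows (with
    orientations drawn from the configured mix) followed by ``n_none``
    non-interaction windows.
    """
    rng = np.random.default_rng(cfg.seed)
    orientations = list(Orientation)
    events: list[EventWindow] = []
    for valence, count, prefix in ((Valence.POSITIVE, cfg.n_positive, "pos"),
                                   (Valence.NEGATIVE, cfg.n_negative, "neg")):
        for i in range(count):
            orient = orientations[rng.choice(3, p=cfg.orientation_mix)]
            events.append(generate_event(
                f"{prefix}{i + 1:04d}", Situation.INTERACTION, cfg, rng,
                valence=valence, orientation=orient,
            ))
    for i in range(cfg.n_none):
        events.append(generate_event(
            f"non{i + 1:04d}", Situation.NO_INTERACTION, cfg, rng,
        ))
    return events


def write_dataset(cfg: GeneratorConfig, annotations_path, manifest_path=None,
                  calibration: CalibrationSpec | None = None) -> list[EventWindow]:
    """Generate and serialize a dataset (annotation CSV plus manifest)."""
    events = generate_dataset(cfg)
    write_annotations(events, annotations_path, calibration)
    if manifest_path is not None:
        write_manifest(events, manifest_path)
    return events
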