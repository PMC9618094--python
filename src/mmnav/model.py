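"""Data model for open-arena object-location-memory experiments.

The task being modelled: participants freely explore a walled open arena
containing 12 object chests on a regular grid (two training phases, capped at
600 s each, ending early once all 12 distinct chests are found), then are
teleported to one of four equidistant corner spawns and asked to place each
object where they believe it was (cued test trials, 180 s each, two test
sessions). A tracking mod logs position and facing direction every step; this
module defines the in-memory containers for those logs and their invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Point2D",
    "TrajectorySample",
    "TrialTrajectory",
    "EnvironmentSpec",
    "ParticipantSession",
    "CohortDataset",
    "ValidationIssue",
    "ValidationReport",
    "validate_dataset",
    "default_environment",
    "DEFAULT_OBJECT_IDS",
    "PHASES",
    "TEST_PHASES",
    "TRAINING_PHASES",
    "EVENTS",
    "TEST_TIME_CAP_S",
    "TRAINING_TIME_CAP_S",
]

PHASES = ("training1", "training2", "test1", "test2")
TRAINING_PHASES = ("training1", "training2")
TEST_PHASES = ("test1", "test2")
EVENTS = ("move", "open_chest", "place_chest", "spawn")

TEST_TIME_CAP_S = 180.0
TRAINING_TIME_CAP_S = 600.0

#: Twelve unique chest objects, in grid order (names in the style of the task's
#: household-object inventory items).
DEFAULT_OBJECT_IDS = (
    "axe", "clay_pot", "feather", "gold_bar", "bottle", "book",
    "compass", "apple", "helmet", "ladder", "lantern", "saddle",
)


@dataclass(frozen=True)
class Point2D:
    """A point on the arena's horizontal plane, in blocks."""

    x: float
    z: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.z)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.z})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.z - other.z)


@dataclass(frozen=True)
class TrajectorySample:
    """One logged step: time, position, facing direction, and event tag.

    ``heading_deg`` is the math-convention bearing (see :mod:`mmnav.geometry`),
    wrapped into (-180, +180].
    """

    step_index: int
    t: float
    pos: Point2D
    heading_deg: float
    event: str = "move"


@dataclass
class TrialTrajectory:
    """Ordered samples for one training phase or one cued placement trial.

    Training trials have no ``object_id``, ``spawn_corner`` or ``placement``;
    a test trial that reached placement ends with a ``place_chest`` event and
    carries the placed block's position.
    """

    phase: str
    samples: list[TrajectorySample]
    object_id: Optional[str] = None
    spawn_corner: Optional[int] = None
    placement: Optional[Point2D] = None

    @property
    def is_test(self) -> bool:
        return self.phase in TEST_PHASES

    @property
    def duration_s(self) -> float:
        if not self.samples:
            return 0.0
        return self.samples[-1].t - self.samples[0].t


@dataclass
class EnvironmentSpec:
    """Arena geometry: bounds, 12 chest locations on a regular grid, 4 corner
    spawns each equidistant from its nearest chest."""

    env_id: int
    arena_width: float
    arena_depth: float
    chest_locations: dict[str, Point2D]
    spawn_corners: list[Point2D]

    def validate(self, tol: float = 1e-6) -> None:
        """Raise ValueError on any structural violation."""
        if len(self.chest_locations) != 12:
            raise ValueError(
                f"environment {self.env_id}: expected 12 chests, "
                f"got {len(self.chest_locations)}"
            )
        for oid, p in self.chest_locations.items():
            if not (0 <= p.x <= self.arena_width and 0 <= p.z <= self.arena_depth):
                raise ValueError(f"chest {oid!r} lies outside the arena")
        self._check_regular_grid(tol)
        if len(self.spawn_corners) != 4:
            raise ValueError("expected exactly 4 spawn corners")
        for i, a in enumerate(self.spawn_corners):
            for b in self.spawn_corners[i + 1:]:
                if a.distance_to(b) <= tol:
                    raise ValueError("spawn corners are not mutually distinct")
        d = [self._nearest_chest_distance(c) for c in self.spawn_corners]
        if max(d) - min(d) > tol:
            raise ValueError(
                "corner-to-nearest-chest distances unequal: "
                + ", ".join(f"{x:.6f}" for x in d)
            )

    def _nearest_chest_distance(self, p: Point2D) -> float:
        return min(p.distance_to(c) for c in self.chest_locations.values())

    def _check_regular_grid(self, tol: float) -> None:
        xs = sorted({round(p.x / tol) * tol for p in self.chest_locations.values()})
        zs = sorted({round(p.z / tol) * tol for p in self.chest_locations.values()})
        xs = _dedupe(xs, tol)
        zs = _dedupe(zs, tol)
        if len(xs) * len(zs) != 12:
            raise ValueError("chest locations do not form a complete grid")
        want = {(x, z) for x in xs for z in zs}
        have = {(p.x, p.z) for p in self.chest_locations.values()}
        for hx, hz in have:
            if not any(abs(hx - wx) <= tol and abs(hz - wz) <= tol for wx, wz in want):
                raise ValueError("chest locations do not form a complete grid")
        for axis in (xs, zs):
            gaps = [b - a for a, b in zip(axis, axis[1:])]
            if gaps and max(gaps) - min(gaps) > tol:
                raise ValueError("chest grid spacing is irregular")


@dataclass
class ParticipantSession:
    """One participant's run through one environment under one condition."""

    participant_id: str
    condition: str  # "sleep" | "wake"
    environment: EnvironmentSpec
    trials: list[TrialTrajectory] = field(default_factory=list)

    def trials_in_phase(self, phase: str) -> list[TrialTrajectory]:
        return [t for t in self.trials if t.phase == phase]


@dataclass
class CohortDataset:
    """All sessions of one study.

    ``study1``: between-subject environment validation, one session per
    participant, test1 only. ``study2``: within-subject sleep/wake design,
    two sessions per participant (one per condition).
    """

    sessions: list[ParticipantSession]
    study_label: str = "study2"
    ground_truth: Optional[object] = None  # pandas.DataFrame from the simulator


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationIssue:
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, location: str, message: str) -> None:
        self.issues.append(ValidationIssue(location, message))

    def __str__(self) -> str:
        if self.ok:
            return "dataset valid (no issues)"
        return "\n".join(str(i) for i in self.issues)


def validate_dataset(ds: CohortDataset) -> ValidationReport:
    """Check every dataset invariant; violations are reported, never raised."""
    rep = ValidationReport()
    if ds.study_label not in ("study1", "study2"):
        rep.add("dataset", f"unknown study label {ds.study_label!r}")
    by_participant: dict[str, list[ParticipantSession]] = {}
    for si, sess in enumerate(ds.sessions):
        loc = f"session[{si}] ({sess.participant_id}/{sess.condition})"
        by_participant.setdefault(sess.participant_id, []).append(sess)
        if sess.condition not in ("sleep", "wake"):
            rep.add(loc, f"unknown condition {sess.condition!r}")
        try:
            sess.environment.validate()
        except ValueError as e:
            rep.add(loc, f"environment invalid: {e}")
        for phase in TEST_PHASES:
            trials = sess.trials_in_phase(phase)
            oids = [t.object_id for t in trials]
            if len(trials) > 12:
                rep.add(loc, f"{phase}: {len(trials)} trials (> 12)")
            if len(set(oids)) != len(oids):
                rep.add(loc, f"{phase}: duplicate object ids")
            for oid in oids:
                if oid is not None and oid not in sess.environment.chest_locations:
                    rep.add(loc, f"{phase}: object {oid!r} not in environment")
        if ds.study_label == "study1" and sess.trials_in_phase("test2"):
            rep.add(loc, "study1 session contains test2 trials")
        for ti, trial in enumerate(sess.trials):
            _validate_trial(trial, f"{loc}.trial[{ti}]({trial.phase})", rep)
    if ds.study_label == "study2":
        for pid, sessions in by_participant.items():
            conds = sorted(s.condition for s in sessions)
            if conds != ["sleep", "wake"]:
                rep.add(
                    f"participant {pid}",
                    f"expected one sleep and one wake session, got {conds}",
                )
    return rep


def _validate_trial(trial: TrialTrajectory, loc: str, rep: ValidationReport) -> None:
    if trial.phase not in PHASES:
        rep.add(loc, f"unknown phase {trial.phase!r}")
        return
    if not trial.samples:
        rep.add(loc, "trial has no samples")
        return
    spawn_idx = [i for i, s in enumerate(trial.samples) if s.event == "spawn"]
    if spawn_idx != [0]:
        rep.add(loc, f"expected exactly one spawn event at step 0, got {spawn_idx}")
    prev_t = None
    for i, s in enumerate(trial.samples):
        if s.step_index != i:
            rep.add(loc, f"step indices not consecutive at sample {i}")
            break
        if s.t < 0:
            rep.add(loc, f"negative time at sample {i}")
        if prev_t is not None and s.t < prev_t:
            rep.add(loc, f"non-monotone time at sample {i}")
        prev_t = s.t
        if not (-180.0 < s.heading_deg <= 180.0):
            rep.add(loc, f"heading {s.heading_deg} outside (-180, 180] at sample {i}")
        if s.event not in EVENTS:
            rep.add(loc, f"unknown event {s.event!r} at sample {i}")
    if trial.is_test:
        ends_placed = trial.samples[-1].event == "place_chest"
        if ends_placed != (trial.placement is not None):
            rep.add(loc, "place_chest terminal event and placement field disagree")
        if trial.object_id is None:
            rep.add(loc, "test trial without object id")
        if trial.spawn_corner is not None and trial.spawn_corner not in (1, 2, 3, 4):
            rep.add(loc, f"spawn corner {trial.spawn_corner} outside 1-4")
        if trial.duration_s > TEST_TIME_CAP_S + 1e-9:
            rep.add(loc, f"test trial duration {trial.duration_s:.1f}s exceeds 180s")
    else:
        if trial.object_id is not None:
            rep.add(loc, "training trial carries an object id")
        if trial.placement is not None:
            rep.add(loc, "training trial carries a placement")
        if trial.duration_s > TRAINING_TIME_CAP_S + 1e-9:
            rep.add(loc, f"training duration {trial.duration_s:.1f}s exceeds 600s")


def default_environment(env_id: int = 1) -> EnvironmentSpec:
    """The bundled reference arena: 100 x 100 blocks, a 3 x 4 chest grid inset
    20 blocks from the walls, and the four arena corners as spawn points.

    Every corner's nearest chest is the adjacent grid corner at distance
    20*sqrt(2), satisfying the equidistance requirement. Proximity radii of
    10/20/30 blocks are small relative to this arena.
    """
    xs = (20.0, 50.0, 80.0)
    zs = (20.0, 40.0, 60.0, 80.0)
    chests = {}
    ids = iter(DEFAULT_OBJECT_IDS)
    for z in zs:
        for x in xs:
            chests[next(ids)] = Point2D(x, z)
    corners = [Point2D(0, 0), Point2D(100, 0), Point2D(100, 100), Point2D(0, 100)]
    env = EnvironmentSpec(
        env_id=env_id,
        arena_width=100.0,
        arena_depth=100.0,
        chest_locations=chests,
        spawn_corners=corners,
    )
    env.validate()
    return env


def _dedupe(sorted_vals, tol):
    out = []
    for v in sorted_vals:
        if not out or v - out[-1] > tol:
            out.append(v)
    return out
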