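"""Reading and writing the canonical trajectory-log and environment files.

Trajectory log: UTF-8 comma-delimited text, one row per sample, mandatory
header, columns::

    participant_id,condition,phase,object_id,spawn_corner,step_index,t,x,z,heading_deg,event

One file holds one participant session (one condition). Training rows leave
``object_id``/``spawn_corner`` empty. Rows are grouped into trials by
(phase, object_id). Headings are wrapped into (-180, +180] on read.

Environment spec: JSON with keys ``env_id``, ``arena {width, depth}``,
``chests [{object_id, x, z} x 12]``, ``spawn_corners [{id, x, z} x 4]``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional

from .geometry import wrap_deg
from .model import (
    CohortDataset,
    EnvironmentSpec,
    ParticipantSession,
    Point2D,
    TrajectorySample,
    TrialTrajectory,
    EVENTS,
    PHASES,
)

__all__ = [
    "LOG_COLUMNS",
    "read_trajectory_log",
    "write_trajectory_log",
    "read_environment_spec",
    "write_environment_spec",
    "read_cohort",
    "write_cohort",
    "collapse_jitter",
    "LogParseError",
]

LOG_COLUMNS = (
    "participant_id", "condition", "phase", "object_id", "spawn_corner",
    "step_index", "t", "x", "z", "heading_deg", "event",
)


class LogParseError(ValueError):
    """Malformed trajectory-log content; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def write_trajectory_log(session: ParticipantSession, path) -> Path:
    """Write a session in the canonical format.

    Deterministic: fixed column order, fixed numeric formatting (10 decimal
    places for coordinates and headings, 3 for time), so two writes of the
    same session are byte-identical.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for trial in session.trials:
            oid = trial.object_id or ""
            corner = "" if trial.spawn_corner is None else str(trial.spawn_corner)
            for s in trial.samples:
                fh.write(
                    f"{session.participant_id},{session.condition},{trial.phase},"
                    f"{oid},{corner},{s.step_index},{s.t:.3f},"
                    f"{s.pos.x:.10f},{s.pos.z:.10f},{s.heading_deg:.10f},{s.event}\n"
                )
    return path


def read_trajectory_log(path, env: EnvironmentSpec) -> ParticipantSession:
    """Parse a canonical log into a validated :class:`ParticipantSession`.

    Raises :class:`LogParseError` (with line number) on malformed rows and
    ``ValueError`` on semantic violations (non-monotone time within a trial,
    unknown object id).
    """
    path = Path(path)
    rows_by_trial: dict[tuple[str, str], list[dict]] = {}
    trial_order: list[tuple[str, str]] = []
    pid = cond = None
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogParseError(path, 1, "empty file (header row mandatory)")
        if tuple(h.strip() for h in header) != LOG_COLUMNS:
            raise LogParseError(path, 1, f"bad header {header!r}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(LOG_COLUMNS):
                raise LogParseError(
                    path, line_no, f"expected {len(LOG_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(LOG_COLUMNS, row))
            try:
                rec["step_index"] = int(rec["step_index"])
                rec["t"] = float(rec["t"])
                rec["x"] = float(rec["x"])
                rec["z"] = float(rec["z"])
                rec["heading_deg"] = float(rec["heading_deg"])
            except ValueError as e:
                raise LogParseError(path, line_no, f"bad numeric field: {e}")
            if rec["phase"] not in PHASES:
                raise LogParseError(path, line_no, f"unknown phase {rec['phase']!r}")
            if rec["event"] not in EVENTS:
                raise LogParseError(path, line_no, f"unknown event {rec['event']!r}")
            if not math.isfinite(rec["x"]) or not math.isfinite(rec["z"]):
                raise LogParseError(path, line_no, "non-finite coordinates")
            pid = pid or rec["participant_id"]
            cond = cond or rec["condition"]
            if rec["participant_id"] != pid or rec["condition"] != cond:
                raise LogParseError(
                    path, line_no,
                    "mixed participant_id/condition in one log file",
                )
            key = (rec["phase"], rec["object_id"])
            if key not in rows_by_trial:
                rows_by_trial[key] = []
                trial_order.append(key)
            rows_by_trial[key].append(rec)
    if pid is None:
        raise LogParseError(path, 2, "log contains no sample rows")

    trials = []
    for phase, oid in trial_order:
        recs = rows_by_trial[(phase, oid)]
        is_test = phase in ("test1", "test2")
        if is_test:
            if not oid:
                raise ValueError(f"{path}: test trial without object id in {phase}")
            if oid not in env.chest_locations:
                raise ValueError(f"{path}: unknown object id {oid!r}")
        samples = []
        prev_t = None
        for rec in recs:
            if prev_t is not None and rec["t"] < prev_t:
                raise ValueError(
                    f"{path}: non-monotone time within trial "
                    f"({phase}, {oid or 'training'}) at step {rec['step_index']}"
                )
            prev_t = rec["t"]
            samples.append(
                TrajectorySample(
                    step_index=rec["step_index"],
                    t=rec["t"],
                    pos=Point2D(rec["x"], rec["z"]),
                    heading_deg=wrap_deg(rec["heading_deg"]),
                    event=rec["event"],
                )
            )
        placement = None
        corner = None
        if is_test:
            corner = int(recs[0]["spawn_corner"]) if recs[0]["spawn_corner"] else None
            if samples and samples[-1].event == "place_chest":
                placement = samples[-1].pos
        trials.append(
            TrialTrajectory(
                phase=phase,
                samples=samples,
                object_id=oid if is_test else None,
                spawn_corner=corner,
                placement=placement,
            )
        )
    return ParticipantSession(
        participant_id=pid, condition=cond, environment=env, trials=trials
    )


# ---------------------------------------------------------------------------
# environment spec


def write_environment_spec(env: EnvironmentSpec, path) -> Path:
    path = Path(path)
    doc = {
        "env_id": env.env_id,
        "arena": {"width": env.arena_width, "depth": env.arena_depth},
        "chests": [
            {"object_id": oid, "x": p.x, "z": p.z}
            for oid, p in env.chest_locations.items()
        ],
        "spawn_corners": [
            {"id": i + 1, "x": p.x, "z": p.z}
            for i, p in enumerate(env.spawn_corners)
        ],
    }
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path


def read_environment_spec(path) -> EnvironmentSpec:
    """Load and validate an environment spec (grid regularity and corner
    equidistance are enforced to 1e-6 blocks)."""
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    try:
        chests = {
            c["object_id"]: Point2D(float(c["x"]), float(c["z"]))
            for c in doc["chests"]
        }
        corners = [
            Point2D(float(c["x"]), float(c["z"]))
            for c in sorted(doc["spawn_corners"], key=lambda c: c["id"])
        ]
        env = EnvironmentSpec(
            env_id=int(doc["env_id"]),
            arena_width=float(doc["arena"]["width"]),
            arena_depth=float(doc["arena"]["depth"]),
            chest_locations=chests,
            spawn_corners=corners,
        )
    except (KeyError, TypeError) as e:
        raise ValueError(f"{path}: malformed environment spec ({e})")
    if len(doc["chests"]) != len(chests):
        raise ValueError(f"{path}: duplicate object ids in chest list")
    env.validate()
    return env


# ---------------------------------------------------------------------------
# cohort directories


def write_cohort(ds: CohortDataset, outdir) -> list[Path]:
    """Write one log per session plus the environment specs, under ``outdir``.

    File names are ``<participant>_<condition>.csv`` and ``env<id>.json``;
    deterministic given the dataset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    envs = {}
    for sess in ds.sessions:
        p = outdir / f"{sess.participant_id}_{sess.condition}.csv"
        written.append(write_trajectory_log(sess, p))
        envs[sess.environment.env_id] = sess.environment
    for env_id in sorted(envs):
        written.append(
            write_environment_spec(envs[env_id], outdir / f"env{env_id}.json")
        )
    meta = {
        "study_label": ds.study_label,
        "sessions": [
            {
                "participant_id": s.participant_id,
                "condition": s.condition,
                "env_id": s.environment.env_id,
            }
            for s in ds.sessions
        ],
    }
    mp = outdir / "cohort.json"
    mp.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    written.append(mp)
    return written


def read_cohort(indir, study_label: Optional[str] = None) -> CohortDataset:
    """Read a directory written by :func:`write_cohort`."""
    indir = Path(indir)
    meta = json.loads((indir / "cohort.json").read_text(encoding="utf-8"))
    envs = {}
    for p in sorted(indir.glob("env*.json")):
        env = read_environment_spec(p)
        envs[env.env_id] = env
    sessions = []
    for rec in meta["sessions"]:
        path = indir / f"{rec['participant_id']}_{rec['condition']}.csv"
        sessions.append(read_trajectory_log(path, envs[rec["env_id"]]))
    return CohortDataset(
        sessions=sessions, study_label=study_label or meta["study_label"]
    )


# ---------------------------------------------------------------------------
# resampling


def collapse_jitter(trial: TrialTrajectory, min_displacement: float = 0.2
                    ) -> TrialTrajectory:
    """Collapse sub-block jitter in densely sampled logs.

    Consecutive samples whose horizontal displacement is below
    ``min_displacement`` blocks are merged (the later sample is dropped,
    unless it carries a non-move event, which is always kept). Step indices
    are renumbered consecutively. The canonical one-row-per-block-step format
    is unaffected; this adapter serves denser (e.g. per-tick) logs.
    """
    if not trial.samples:
        return trial
    kept = [trial.samples[0]]
    for s in trial.samples[1:]:
        if s.event != "move" or s.pos.distance_to(kept[-1].pos) >= min_displacement:
            kept.append(s)
    renumbered = [
        TrajectorySample(i, s.t, s.pos, s.heading_deg, s.event)
        for i, s in enumerate(kept)
    ]
    return TrialTrajectory(
        phase=trial.phase,
        samples=renumbered,
        object_id=trial.object_id,
        spawn_corner=trial.spawn_corner,
        placement=trial.placement,
    )
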