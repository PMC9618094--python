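"""Per-trial spatial-memory and navigation metrics, and their aggregation.

The suite mirrors the open-arena task's analysis battery:

* **placement error** — Euclidean distance (blocks) between the placed object
  and its true learned location; the spatial-memory measure proper.
* **path length** — number of movement steps from trial start to placement
  (or across a whole training phase).
* **header direction** — absolute value of the *mean signed* per-step
  deviation between the facing direction and the bearing to the true object
  location; 0 deg means a straight line at the target, and opposite
  deviations cancel.
* **cumulative error** — sum of the *absolute* per-step deviations over the
  same steps; backtracking inflates it instead of cancelling.
* **initial orientation** — header direction restricted to the first five
  movement steps after spawning; a proxy for immediate allocentric orienting.
* **approach angle** — mean movement bearing over the last few steps before
  reaching a chest; two angles within +/-22.5 deg (half the 45 deg field of
  view) count as the same viewpoint.
* **proximity dwell** — fraction of a trial's steps spent within concentric
  circles of 10/20/30 blocks around the true location (the open-arena
  analogue of a water-maze probe trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import angular_deviation, bearing, circular_mean_deg
from .model import (
    CohortDataset,
    EnvironmentSpec,
    Point2D,
    TrialTrajectory,
    TEST_PHASES,
    TRAINING_PHASES,
)

__all__ = [
    "MetricConfig",
    "TrialMetrics",
    "TrainingSummary",
    "DegenerateTrialError",
    "NoApproachError",
    "placement_error",
    "path_length",
    "header_direction",
    "cumulative_error",
    "initial_orientation",
    "approach_angle",
    "same_viewpoint",
    "proximity_dwell",
    "training_summaries",
    "compute_trial_metrics",
    "trial_metric_table",
    "training_summary_table",
    "aggregate",
]

SAME_VIEWPOINT_HALF_ANGLE = 22.5  # half the 45-degree field of view


class DegenerateTrialError(ValueError):
    """Raised for trials with no movement steps: the angle metrics are
    undefined (teleport-then-place); such trials are excluded from angle
    aggregates but keep their placement error."""


class NoApproachError(ValueError):
    """Raised when a trajectory never comes within the arrival radius of the
    requested target."""


@dataclass(frozen=True)
class MetricConfig:
    """Tunable metric definitions.

    heading_reference
        ``instantaneous`` (default): each step's deviation is measured against
        the bearing from the *current* position to the true object location,
        so a straight walk at the target scores exactly 0 along the whole
        path. ``fixed_start_line``: against the fixed spawn-to-target bearing.
    header_mode
        ``signed_mean`` (default): header direction = |mean(signed
        deviations)|, so opposite deviations cancel. ``mean_abs``:
        mean(|deviation|).
    use_movement_bearing
        Derive the per-step direction from consecutive positions instead of
        the logged facing, for logs without facing data.
    step_threshold
        Displacement (blocks) below which a transition counts as stationary.
    """

    heading_reference: str = "instantaneous"
    header_mode: str = "signed_mean"
    use_movement_bearing: bool = False
    step_threshold: float = 0.2
    approach_k: int = 5
    approach_radius: float = 3.0
    dwell_radii: tuple[float, ...] = (10.0, 20.0, 30.0)
    dwell_units: str = "steps"  # or "seconds"

    def __post_init__(self):
        if self.heading_reference not in ("instantaneous", "fixed_start_line"):
            raise ValueError(f"bad heading_reference {self.heading_reference!r}")
        if self.header_mode not in ("signed_mean", "mean_abs"):
            raise ValueError(f"bad header_mode {self.header_mode!r}")
        if self.dwell_units not in ("steps", "seconds"):
            raise ValueError(f"bad dwell_units {self.dwell_units!r}")


DEFAULT_CONFIG = MetricConfig()


# ---------------------------------------------------------------------------
# per-trial metrics


def placement_error(trial: TrialTrajectory, env: EnvironmentSpec) -> float:
    """Euclidean distance (blocks) between the placement and the true
    location of the trial's object."""
    if not trial.is_test:
        raise ValueError("placement_error is defined for test trials only")
    if trial.placement is None:
        raise ValueError("untested trial: no placement recorded")
    true = _true_location(trial, env)
    return trial.placement.distance_to(true)


def path_length(trial: TrialTrajectory,
                config: MetricConfig = DEFAULT_CONFIG) -> int:
    """Number of movement steps (inter-sample transitions with displacement
    >= the stationary threshold)."""
    if not trial.samples:
        raise ValueError("trial has no samples")
    xs, zs = _positions(trial)
    disp = np.hypot(np.diff(xs), np.diff(zs))
    return int(np.count_nonzero(disp >= config.step_threshold))


def header_direction(trial: TrialTrajectory, env: EnvironmentSpec,
                     config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Absolute mean signed per-step heading deviation from the bearing to
    the true location, over all movement steps from spawn to placement."""
    d = _step_deviations(trial, env, config)
    if config.header_mode == "mean_abs":
        return float(np.mean(np.abs(d)))
    return float(abs(np.mean(d)))


def cumulative_error(trial: TrialTrajectory, env: EnvironmentSpec,
                     config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Sum of absolute per-step heading deviations; monotone non-decreasing
    as steps are appended, and inflated (not cancelled) by backtracking."""
    d = _step_deviations(trial, env, config)
    return float(np.sum(np.abs(d)))


def initial_orientation(trial: TrialTrajectory, env: EnvironmentSpec,
                        config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Header direction over the first min(5, available) movement steps."""
    d = _step_deviations(trial, env, config)
    head = d[:5]
    if config.header_mode == "mean_abs":
        return float(np.mean(np.abs(head)))
    return float(abs(np.mean(head)))


def approach_angle(trial: TrialTrajectory, target: Point2D,
                   k: int = 5, radius: float = 3.0,
                   config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Circular-mean movement bearing over the final ``k`` movement steps
    before the trajectory reaches ``target``.

    Tests anchor on the terminal ``place_chest`` sample; training trials on
    the first ``open_chest`` event within ``radius`` of the target; otherwise
    the sample nearest the target is used. Raises :class:`NoApproachError`
    if the trajectory never comes within ``radius`` of the target.
    """
    xs, zs = _positions(trial)
    dist = np.hypot(xs - target.x, zs - target.z)
    if dist.min() > radius:
        raise NoApproachError(f"trajectory never within {radius} blocks of target")
    anchor = None
    if trial.is_test and trial.samples[-1].event == "place_chest":
        anchor = len(trial.samples) - 1
    else:
        for i, s in enumerate(trial.samples):
            if s.event == "open_chest" and dist[i] <= radius:
                anchor = i
                break
    if anchor is None:
        anchor = int(np.argmin(dist))
    disp = np.hypot(np.diff(xs), np.diff(zs))
    bearings = [
        bearing(trial.samples[i].pos, trial.samples[i + 1].pos)
        for i in range(anchor)
        if disp[i] >= config.step_threshold
    ]
    if not bearings:
        raise DegenerateTrialError("no movement steps before the approach anchor")
    return circular_mean_deg(bearings[-k:])


def same_viewpoint(a: float, b: float) -> bool:
    """True iff the two angles lie within the same 45-degree field of view
    (|wrapped difference| <= 22.5 deg, boundary inclusive)."""
    return abs(angular_deviation(a, b)) <= SAME_VIEWPOINT_HALF_ANGLE


def proximity_dwell(trial: TrialTrajectory, env: EnvironmentSpec,
                    radii=(10.0, 20.0, 30.0),
                    config: MetricConfig = DEFAULT_CONFIG) -> dict[float, float]:
    """Fraction of the trial spent within each concentric radius of the true
    object location. Step units (default): fraction of samples; seconds
    units: fraction of trial duration."""
    if not trial.is_test:
        raise ValueError("proximity_dwell is defined for test trials only")
    if not trial.samples:
        raise ValueError("trial has no samples")
    true = _true_location(trial, env)
    xs, zs = _positions(trial)
    dist = np.hypot(xs - true.x, zs - true.z)
    out = {}
    if config.dwell_units == "seconds" and len(trial.samples) > 1:
        t = np.array([s.t for s in trial.samples])
        dt = np.diff(t)
        total = dt.sum()
        for r in radii:
            inside = dist[:-1] <= r
            out[float(r)] = float(dt[inside].sum() / total) if total > 0 else 0.0
    else:
        for r in radii:
            out[float(r)] = float(np.count_nonzero(dist <= r) / len(dist))
    return out


@dataclass(frozen=True)
class TrainingSummary:
    time_in_phase_s: float
    chests_opened_distinct: int
    chests_opened_total: int
    total_steps: int


def training_summaries(trial: TrialTrajectory,
                       env: Optional[EnvironmentSpec] = None,
                       config: MetricConfig = DEFAULT_CONFIG) -> TrainingSummary:
    """Elapsed time, chest-opening counts and step count for a training phase.

    Re-opening an already-found chest counts toward the total but not the
    distinct count. Chest identity is resolved to the nearest chest when
    ``env`` is given (unambiguous for detection ranges below half the grid
    spacing); otherwise distinct event positions are used.
    """
    if trial.is_test:
        raise ValueError("training_summaries is defined for training trials only")
    if not trial.samples:
        raise ValueError("trial has no samples")
    time_in_phase = trial.samples[-1].t - trial.samples[0].t
    opens = [s for s in trial.samples if s.event == "open_chest"]
    if env is not None:
        chest_items = list(env.chest_locations.items())
        seen = set()
        for s in opens:
            oid = min(chest_items, key=lambda kv: s.pos.distance_to(kv[1]))[0]
            seen.add(oid)
        distinct = len(seen)
    else:
        distinct = len({(s.pos.x, s.pos.z) for s in opens})
    return TrainingSummary(
        time_in_phase_s=float(time_in_phase),
        chests_opened_distinct=distinct,
        chests_opened_total=len(opens),
        total_steps=path_length(trial, config),
    )


# ---------------------------------------------------------------------------
# internals


def _true_location(trial: TrialTrajectory, env: EnvironmentSpec) -> Point2D:
    if trial.object_id is None:
        raise ValueError("trial has no object id")
    try:
        return env.chest_locations[trial.object_id]
    except KeyError:
        raise ValueError(f"unknown object id {trial.object_id!r}")


def _positions(trial: TrialTrajectory):
    xs = np.array([s.pos.x for s in trial.samples], dtype=float)
    zs = np.array([s.pos.z for s in trial.samples], dtype=float)
    return xs, zs


def _step_deviations(trial: TrialTrajectory, env: EnvironmentSpec,
                     config: MetricConfig) -> np.ndarray:
    """Signed per-movement-step deviations d_i between the step's direction
    and the reference bearing toward the true object location.

    Steps run from spawn until placement (test trials end at the terminal
    place_chest sample). Stationary transitions are skipped, as are the rare
    steps taken from exactly the true location (instantaneous bearing
    undefined there).
    """
    if not trial.is_test:
        raise ValueError("heading metrics are defined for test trials only")
    true = _true_location(trial, env)
    xs, zs = _positions(trial)
    if len(xs) < 2:
        raise DegenerateTrialError("trial has no movement steps")
    disp = np.hypot(np.diff(xs), np.diff(zs))
    fixed_ref = None
    if config.heading_reference == "fixed_start_line":
        fixed_ref = bearing(trial.samples[0].pos, true)
    devs = []
    for i in range(len(xs) - 1):
        if disp[i] < config.step_threshold:
            continue
        if config.use_movement_bearing:
            direction = bearing(trial.samples[i].pos, trial.samples[i + 1].pos)
        else:
            direction = trial.samples[i].heading_deg
        if fixed_ref is not None:
            ref = fixed_ref
        else:
            if xs[i] == true.x and zs[i] == true.z:
                continue
            ref = bearing(trial.samples[i].pos, true)
        devs.append(angular_deviation(direction, ref))
    if not devs:
        raise DegenerateTrialError("trial has no movement steps")
    return np.asarray(devs, dtype=float)


# ---------------------------------------------------------------------------
# trial-level metric records and aggregation


@dataclass
class TrialMetrics:
    """All metrics for one test trial; undefined angle metrics are ``None``
    with the reason recorded."""

    placement_error: Optional[float] = None
    path_length: Optional[int] = None
    header_direction: Optional[float] = None
    cumulative_error: Optional[float] = None
    initial_orientation: Optional[float] = None
    initial_orientation_few_steps: bool = False
    approach_angle: Optional[float] = None
    proximity_dwell: dict[float, float] = field(default_factory=dict)
    test_time_s: Optional[float] = None
    degenerate_reason: Optional[str] = None


def compute_trial_metrics(trial: TrialTrajectory, env: EnvironmentSpec,
                          config: MetricConfig = DEFAULT_CONFIG) -> TrialMetrics:
    """Compute every metric for one test trial, tolerating degenerate trials
    (missing placement, zero movement): undefined entries come back ``None``
    with a reason instead of raising."""
    m = TrialMetrics()
    m.test_time_s = trial.duration_s
    m.path_length = path_length(trial, config)
    try:
        m.placement_error = placement_error(trial, env)
    except ValueError as e:
        m.degenerate_reason = str(e)
    try:
        d = _step_deviations(trial, env, config)
    except DegenerateTrialError as e:
        m.degenerate_reason = m.degenerate_reason or str(e)
    else:
        if config.header_mode == "mean_abs":
            m.header_direction = float(np.mean(np.abs(d)))
            m.initial_orientation = float(np.mean(np.abs(d[:5])))
        else:
            m.header_direction = float(abs(np.mean(d)))
            m.initial_orientation = float(abs(np.mean(d[:5])))
        m.cumulative_error = float(np.sum(np.abs(d)))
        m.initial_orientation_few_steps = len(d) < 5
    try:
        m.approach_angle = approach_angle(
            trial, _true_location(trial, env),
            k=config.approach_k, radius=config.approach_radius, config=config,
        )
    except (NoApproachError, DegenerateTrialError):
        m.approach_angle = None
    m.proximity_dwell = proximity_dwell(trial, env, config.dwell_radii, config)
    return m


def trial_metric_table(ds: CohortDataset,
                       config: MetricConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One row per test trial across the cohort, NaN-free in the sense that
    undefined metrics carry a reason column."""
    rows = []
    for sess in ds.sessions:
        for phase in TEST_PHASES:
            for trial in sess.trials_in_phase(phase):
                m = compute_trial_metrics(trial, sess.environment, config)
                row = {
                    "participant_id": sess.participant_id,
                    "condition": sess.condition,
                    "phase": phase,
                    "object_id": trial.object_id,
                    "spawn_corner": trial.spawn_corner,
                    "placement_error": m.placement_error,
                    "path_length": m.path_length,
                    "header_direction": m.header_direction,
                    "cumulative_error": m.cumulative_error,
                    "initial_orientation": m.initial_orientation,
                    "initial_orientation_few_steps": m.initial_orientation_few_steps,
                    "approach_angle": m.approach_angle,
                    "test_time_s": m.test_time_s,
                    "degenerate_reason": m.degenerate_reason or "",
                }
                for r, frac in m.proximity_dwell.items():
                    row[f"dwell_{r:g}"] = frac
                rows.append(row)
    return pd.DataFrame(rows)


def training_summary_table(ds: CohortDataset,
                           config: MetricConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One row per training phase per session."""
    rows = []
    for sess in ds.sessions:
        for phase in TRAINING_PHASES:
            for trial in sess.trials_in_phase(phase):
                s = training_summaries(trial, sess.environment, config)
                rows.append({
                    "participant_id": sess.participant_id,
                    "condition": sess.condition,
                    "phase": phase,
                    "time_in_phase_s": s.time_in_phase_s,
                    "chests_opened_distinct": s.chests_opened_distinct,
                    "chests_opened_total": s.chests_opened_total,
                    "total_steps": s.total_steps,
                })
    return pd.DataFrame(rows)


MEAN_COLUMNS = (
    "placement_error", "path_length", "header_direction", "cumulative_error",
    "initial_orientation", "test_time_s",
)


def aggregate(ds: CohortDataset, config: MetricConfig = DEFAULT_CONFIG,
              item_filter_sd: Optional[float] = 2.5) -> tuple[pd.DataFrame,
                                                              pd.DataFrame]:
    """Participant-level and item-level metric tables.

    The item table carries one row per (participant, condition, phase,
    object) with an ``excluded_item`` flag: items beyond ``item_filter_sd``
    SDs (two-sided) of the placement-error mean within (condition, phase) are
    excluded, as are objects missing from one of a session's two tests.
    Participant means are computed only over surviving, non-degenerate items.
    """
    trial_tab = trial_metric_table(ds, config)
    if trial_tab.empty:
        return trial_tab.copy(), trial_tab.copy()
    item = trial_tab.copy()
    item["excluded_item"] = False
    item["exclusion_reason"] = ""

    if item_filter_sd is not None:
        for (_, _), idx in item.groupby(["condition", "phase"]).groups.items():
            vals = item.loc[idx, "placement_error"]
            mu, sd = vals.mean(), vals.std(ddof=0)
            if sd > 0:
                far = (vals - mu).abs() > item_filter_sd * sd
                item.loc[vals.index[far], "excluded_item"] = True
                item.loc[vals.index[far], "exclusion_reason"] = (
                    f"placement error beyond {item_filter_sd} SD"
                )
    # objects missing (untested / unplaced) in one test of a session
    has_both = len({p for p in item["phase"]}) == 2
    if has_both:
        ok = item["placement_error"].notna()
        counts = (
            item[ok]
            .groupby(["participant_id", "condition", "object_id"])["phase"]
            .nunique()
        )
        incomplete = counts[counts < 2].index
        if len(incomplete):
            key = list(zip(item["participant_id"], item["condition"],
                           item["object_id"]))
            mask = pd.Series(key).isin(set(incomplete)).to_numpy()
            item.loc[mask & ~item["excluded_item"].to_numpy(),
                     "exclusion_reason"] = "object missing in one test"
            item.loc[mask, "excluded_item"] = True
        item.loc[item["placement_error"].isna() & ~item["excluded_item"],
                 "excluded_item"] = True

    surviving = item[~item["excluded_item"]]
    dwell_cols = [c for c in item.columns if c.startswith("dwell_")]
    part = (
        surviving
        .groupby(["participant_id", "condition", "phase"], as_index=False)
        [list(MEAN_COLUMNS) + dwell_cols]
        .mean()
    )
    n_items = (
        surviving
        .groupby(["participant_id", "condition", "phase"])
        .size()
        .rename("n_items")
        .reset_index()
    )
    part = part.merge(n_items, on=["participant_id", "condition", "phase"])
    return part, item
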