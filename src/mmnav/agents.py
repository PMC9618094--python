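"""Goal-directed navigating agents with tunable memory and heading noise.

The generator emulates the open-arena task end to end with known ground
truth, so the metric and statistical layers can be exercised without any
participant data:

* **Training** is a persistent random walk (heading held for a geometric run,
  then redrawn) with boundary reflection; a chest fires an ``open_chest``
  event when the agent comes within the detection radius, and the phase ends
  at 12 distinct chests or the 600 s cap.
* **Test trials** spawn at a random corner. The agent's remembered (believed)
  location of each object is the true location corrupted by isotropic 2-D
  Gaussian noise with per-axis SD sigma; each step it faces the bearing to
  the believed location plus von-Mises heading noise (concentration kappa;
  kappa = inf means exactly zero noise) and walks one step. It places the
  chest on reaching the believed spot, or wherever it stands at the 180 s
  cap.
* **Cohorts** pair a sleep and a wake session per participant on
  counterbalanced environments. Memory noise at each test is scaled by the
  condition's per-test sigma multiplier (e.g. wake test2 x 1.3 models
  retention declining over a waking day while sleep maintains it); believed
  locations share a participant-by-object map component across the two tests
  of a session, plus independent per-test retrieval noise, so test-retest
  performance is positively correlated.

One simulated step equals one second of task time by default, so the 600 s /
180 s phase caps translate directly into step caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import wrap_deg
from .model import (
    CohortDataset,
    EnvironmentSpec,
    ParticipantSession,
    Point2D,
    TrajectorySample,
    TrialTrajectory,
    TEST_TIME_CAP_S,
    TRAINING_TIME_CAP_S,
)

__all__ = [
    "AgentParams",
    "CohortDesign",
    "simulate_training",
    "simulate_test_trial",
    "simulate_cohort",
    "simulate_study1_cohort",
    "cohort_metric_table",
]

RngLike = Union[int, np.random.Generator]


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of the synthetic navigator.

    memory_sd
        Per-axis SD (blocks) of the isotropic Gaussian corruption of each
        remembered chest location.
    heading_kappa
        von-Mises concentration of the heading noise around the goal bearing;
        ``inf`` disables the noise entirely.
    heading_persistence
        Mean run length (steps) over which one heading-noise offset is held
        before being redrawn. Navigators commit to a (possibly wrong)
        direction for a stretch and re-orient periodically; white per-step
        noise (persistence 1) would average out over a trial and leave the
        directness metrics insensitive to kappa.
    step_size
        Blocks travelled per step (one step = ``step_duration_s`` seconds).
    explore_persistence
        Mean run length (steps) before the exploration heading is redrawn.
    detection_radius
        Distance (blocks) at which an unopened chest fires its open event in
        training (chests sit in the ground: they are opened up close).
    sight_radius
        Distance (blocks) at which the floating marker over an unopened
        chest is visible; exploration steers toward the nearest visible
        marker, falling back to the persistent random walk when none is in
        sight. Set to 0 for a pure random walk.
    memory_shared_frac
        Fraction of the memory-noise *variance* shared between a session's
        two tests (the stable map error); the remainder is per-test retrieval
        noise.
    """

    memory_sd: float = 4.0
    heading_kappa: float = 8.0
    heading_persistence: float = 8.0
    step_size: float = 1.0
    explore_persistence: float = 25.0
    detection_radius: float = 2.5
    sight_radius: float = 30.0
    memory_shared_frac: float = 0.6
    step_duration_s: float = 1.0

    def __post_init__(self):
        if self.memory_sd < 0:
            raise ValueError("memory_sd must be >= 0")
        if self.heading_kappa < 0:
            raise ValueError("heading_kappa must be >= 0")
        if self.heading_persistence < 1:
            raise ValueError("heading_persistence must be >= 1 step")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.explore_persistence < 1:
            raise ValueError("explore_persistence must be >= 1 step")
        if self.detection_radius < 0:
            raise ValueError("detection_radius must be >= 0")
        if self.sight_radius < 0:
            raise ValueError("sight_radius must be >= 0")
        if not 0.0 <= self.memory_shared_frac <= 1.0:
            raise ValueError("memory_shared_frac must be in [0, 1]")
        if self.step_duration_s <= 0:
            raise ValueError("step_duration_s must be > 0")


def _default_condition_effects():
    return {
        "sleep": {"test1": 1.0, "test2": 1.0},
        "wake": {"test1": 1.0, "test2": 1.3},
    }


def _default_kappa_multipliers():
    return {"test1": 1.0, "test2": 1.0}


@dataclass(frozen=True)
class CohortDesign:
    """Study-level design of a simulated within-subject cohort.

    ``condition_effects`` maps each condition to per-test multipliers on the
    memory SD; the default models performance maintained across a night of
    sleep but declining across a waking day. ``kappa_test_multipliers``
    applies equally to both conditions and models directness improving with
    test repetition. ``ability_sd`` is the SD of a log-normal per-participant
    multiplier on the memory SD (stable individual ability differences).
    """

    n_participants: int = 29
    condition_effects: dict = field(default_factory=_default_condition_effects)
    kappa_test_multipliers: dict = field(default_factory=_default_kappa_multipliers)
    ability_sd: float = 0.2
    counterbalance: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for cond, mults in self.condition_effects.items():
            for test, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier {cond}/{test} must be > 0")


def _rng(seed: Optional[RngLike]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _vonmises_deg(rng: np.random.Generator, kappa: np.ndarray, size) -> np.ndarray:
    """von-Mises heading noise in degrees; kappa = inf gives exact zeros."""
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), size)
    out = np.zeros(size, dtype=float)
    finite = np.isfinite(kappa)
    if finite.any():
        out[finite] = np.degrees(rng.vonmises(0.0, kappa[finite]))
    return out


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] (boundary-wall reflection)."""
    span = hi - lo
    w = np.mod(v - lo, 2.0 * span)
    w = np.where(w > span, 2.0 * span - w, w)
    return w + lo


# ---------------------------------------------------------------------------
# training


def simulate_training(env: EnvironmentSpec, params: AgentParams,
                      seed: Optional[RngLike] = None,
                      phase: str = "training1") -> TrialTrajectory:
    """One free-exploration phase: persistent random walk until all 12
    distinct chests are found or the 600 s cap. Reproducible per seed."""
    rng = _rng(seed)
    max_steps = int(round(TRAINING_TIME_CAP_S / params.step_duration_s))
    chest_ids = list(env.chest_locations.keys())
    chest_xy = np.array(
        [[p.x, p.z] for p in env.chest_locations.values()], dtype=float
    )
    corner = int(rng.integers(0, 4))
    pos = np.array(
        [env.spawn_corners[corner].x, env.spawn_corners[corner].z], dtype=float
    )
    heading = float(rng.uniform(-180.0, 180.0))
    run_left = int(rng.geometric(1.0 / params.explore_persistence))

    found: set[str] = set()
    in_zone = np.zeros(len(chest_ids), dtype=bool)
    positions = [pos.copy()]
    headings: list[float] = []
    events = ["spawn"]

    def chest_event(p: np.ndarray) -> Optional[str]:
        dist = np.hypot(chest_xy[:, 0] - p[0], chest_xy[:, 1] - p[1])
        inside = dist <= params.detection_radius
        in_zone[:] = in_zone & inside  # leaving the zone re-arms the chest
        candidates = np.flatnonzero(inside & ~in_zone)
        if candidates.size == 0:
            return None
        j = int(candidates[np.argmin(dist[candidates])])
        in_zone[j] = True
        found.add(chest_ids[j])
        return "open_chest"

    unopened_mask = np.ones(len(chest_ids), dtype=bool)

    for _ in range(max_steps):
        if len(found) >= 12:
            break
        unopened_mask[:] = [cid not in found for cid in chest_ids]
        steered = False
        if params.sight_radius > 0 and unopened_mask.any():
            dist = np.hypot(chest_xy[:, 0] - pos[0], chest_xy[:, 1] - pos[1])
            dist[~unopened_mask] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= params.sight_radius:
                # a floating marker is in sight: head for it (noisily)
                aim = math.degrees(
                    math.atan2(chest_xy[j, 1] - pos[1], chest_xy[j, 0] - pos[0])
                )
                noise = float(
                    _vonmises_deg(rng, params.heading_kappa, (1,))[0]
                )
                heading = float(wrap_deg(aim + noise))
                steered = True
        if not steered and run_left <= 0:
            heading = float(rng.uniform(-180.0, 180.0))
            run_left = int(rng.geometric(1.0 / params.explore_persistence))
        rad = math.radians(heading)
        nxt = pos + params.step_size * np.array([math.cos(rad), math.sin(rad)])
        # specular wall reflection: fold the position and flip the heading
        # component, so the walk leaves the boundary instead of grinding on it
        if nxt[0] < 0.0 or nxt[0] > env.arena_width:
            nxt[0] = _reflect(nxt[0], 0.0, env.arena_width)
            heading = wrap_deg(180.0 - heading)
        if nxt[1] < 0.0 or nxt[1] > env.arena_depth:
            nxt[1] = _reflect(nxt[1], 0.0, env.arena_depth)
            heading = wrap_deg(-heading)
        headings.append(heading)
        pos = nxt
        positions.append(pos.copy())
        events.append(chest_event(pos) or "move")
        run_left -= 1

    headings.append(headings[-1] if headings else heading)
    samples = [
        TrajectorySample(
            step_index=i,
            t=i * params.step_duration_s,
            pos=Point2D(float(p[0]), float(p[1])),
            heading_deg=wrap_deg(h),
            event=e,
        )
        for i, (p, h, e) in enumerate(zip(positions, headings, events))
    ]
    return TrialTrajectory(phase=phase, samples=samples)


# ---------------------------------------------------------------------------
# cued test walks (vectorized engine)


@dataclass
class WalkBatch:
    """Padded arrays for a batch of goal-directed walks.

    ``pos`` has shape (T+1, n, 2) (positions are forward-filled after
    placement), ``heading`` (T, n), ``n_steps`` the per-walk transition
    count (walk i has ``n_steps[i] + 1`` samples), ``placement`` (n, 2) and
    ``capped`` whether the 180 s deadline forced the placement.
    """

    pos: np.ndarray
    heading: np.ndarray
    n_steps: np.ndarray
    placement: np.ndarray
    capped: np.ndarray


def _walk_batch(env: EnvironmentSpec, starts: np.ndarray, believed: np.ndarray,
                kappa, params: AgentParams, rng: np.random.Generator,
                ) -> WalkBatch:
    n = starts.shape[0]
    max_steps = int(round(TEST_TIME_CAP_S / params.step_duration_s))
    kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (n,))
    pos = np.empty((max_steps + 1, n, 2), dtype=float)
    pos[0] = starts
    heading = np.zeros((max_steps, n), dtype=float)
    n_steps = np.full(n, max_steps, dtype=int)
    active = np.ones(n, dtype=bool)
    step = params.step_size
    # run-correlated heading error: each walk holds one von-Mises offset for
    # a geometric run of steps before redrawing it
    noise = np.zeros(n, dtype=float)
    run_left = np.zeros(n, dtype=int)
    p_redraw = 1.0 / params.heading_persistence
    t_used = 0
    for t in range(max_steps):
        if not active.any():
            break
        t_used = t + 1
        cur = pos[t]
        dx = believed[:, 0] - cur[:, 0]
        dz = believed[:, 1] - cur[:, 1]
        dist = np.hypot(dx, dz)
        goal_bearing = np.degrees(np.arctan2(dz, dx))
        arriving = active & (dist <= step)
        expired = run_left <= 0
        if expired.any():
            fresh = _vonmises_deg(rng, kappa, (n,))
            noise = np.where(expired, fresh, noise)
            run_left = np.where(expired, rng.geometric(p_redraw, size=n),
                                run_left)
        run_left -= 1
        h = wrap_deg(goal_bearing + noise)
        # the final hop snaps exactly onto the believed location, facing it
        h = np.where(arriving, wrap_deg(goal_bearing), h)
        h = np.where(active, h, heading[t - 1] if t > 0 else 0.0)
        heading[t] = h
        rad = np.radians(h)
        nxt = cur + step * np.stack([np.cos(rad), np.sin(rad)], axis=1)
        nxt[:, 0] = _reflect(nxt[:, 0], 0.0, env.arena_width)
        nxt[:, 1] = _reflect(nxt[:, 1], 0.0, env.arena_depth)
        nxt = np.where(arriving[:, None], believed, nxt)
        nxt = np.where(active[:, None], nxt, cur)
        pos[t + 1] = nxt
        n_steps[arriving] = t + 1
        active &= ~arriving
    pos = pos[: t_used + 1] if t_used else pos[:1]
    heading = heading[:t_used]
    capped = active.copy()
    n_steps = np.where(capped, t_used, n_steps)
    placement = pos[n_steps, np.arange(n)]
    return WalkBatch(pos=pos, heading=heading, n_steps=n_steps,
                     placement=placement, capped=capped)


def _trial_from_walk(walk: WalkBatch, i: int, phase: str, object_id: str,
                     corner: int, params: AgentParams) -> TrialTrajectory:
    n = int(walk.n_steps[i])
    samples = []
    for j in range(n + 1):
        if j == 0:
            event = "spawn"
        elif j == n:
            event = "place_chest"
        else:
            event = "move"
        h = walk.heading[min(j, n - 1), i] if n > 0 else 0.0
        samples.append(
            TrajectorySample(
                step_index=j,
                t=j * params.step_duration_s,
                pos=Point2D(float(walk.pos[j, i, 0]), float(walk.pos[j, i, 1])),
                heading_deg=wrap_deg(float(h)),
                event=event,
            )
        )
    return TrialTrajectory(
        phase=phase,
        samples=samples,
        object_id=object_id,
        spawn_corner=corner + 1,
        placement=Point2D(float(walk.placement[i, 0]), float(walk.placement[i, 1])),
    )


def simulate_test_trial(env: EnvironmentSpec, object_id: str,
                        params: AgentParams, seed: Optional[RngLike] = None,
                        phase: str = "test1",
                        spawn_corner: Optional[int] = None,
                        believed: Optional[Point2D] = None) -> TrialTrajectory:
    """One cued placement trial.

    The believed location defaults to the true location plus isotropic
    Gaussian noise with SD ``params.memory_sd`` (clipped to the arena);
    pass ``believed`` explicitly to control it. ``spawn_corner`` is 1-4 or
    drawn uniformly.
    """
    if object_id not in env.chest_locations:
        raise ValueError(f"unknown object id {object_id!r}")
    rng = _rng(seed)
    true = env.chest_locations[object_id]
    if spawn_corner is None:
        corner = int(rng.integers(0, 4))
    else:
        corner = spawn_corner - 1
    if believed is None:
        bx = true.x + rng.normal(0.0, params.memory_sd)
        bz = true.z + rng.normal(0.0, params.memory_sd)
    else:
        bx, bz = believed.x, believed.z
    bel = np.array([[np.clip(bx, 0.0, env.arena_width),
                     np.clip(bz, 0.0, env.arena_depth)]])
    start = np.array([[env.spawn_corners[corner].x, env.spawn_corners[corner].z]])
    walk = _walk_batch(env, start, bel, params.heading_kappa, params, rng)
    return _trial_from_walk(walk, 0, phase, object_id, corner, params)


# ---------------------------------------------------------------------------
# vectorized metrics on walk batches (used by the replicate-study fast path)

STEP_THRESHOLD = 0.2


def _batch_metrics(walk: WalkBatch, true_xz: np.ndarray,
                   radii=(10.0, 20.0, 30.0)) -> dict[str, np.ndarray]:
    """Default-configuration trial metrics computed directly on the padded
    walk arrays; agrees with :mod:`mmnav.metrics` on the materialized trials
    (covered by tests)."""
    pos, heading, n_steps = walk.pos, walk.heading, walk.n_steps
    T, n = heading.shape
    idx = np.arange(T)[:, None]
    valid = idx < n_steps[None, :]
    diff = pos[1:] - pos[:-1]
    disp = np.hypot(diff[..., 0], diff[..., 1])
    moving = valid & (disp >= STEP_THRESHOLD)
    dx = true_xz[None, :, 0] - pos[:-1, :, 0]
    dz = true_xz[None, :, 1] - pos[:-1, :, 1]
    dist_true = np.hypot(dx, dz)
    ref = np.degrees(np.arctan2(dz, dx))
    d = wrap_deg(heading - ref)
    use = moving & (dist_true > 0)
    cnt = use.sum(axis=0)
    sum_d = np.where(use, d, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        header = np.abs(sum_d / cnt)
    cum = np.where(use, np.abs(d), 0.0).sum(axis=0)
    rank = np.cumsum(use, axis=0)
    first5 = use & (rank <= 5)
    cnt5 = first5.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        init = np.abs(np.where(first5, d, 0.0).sum(axis=0) / cnt5)
    header = np.where(cnt > 0, header, np.nan)
    init = np.where(cnt5 > 0, init, np.nan)
    out = {
        "placement_error": np.hypot(walk.placement[:, 0] - true_xz[:, 0],
                                    walk.placement[:, 1] - true_xz[:, 1]),
        "path_length": moving.sum(axis=0).astype(float),
        "header_direction": header,
        "cumulative_error": np.where(cnt > 0, cum, np.nan),
        "initial_orientation": init,
    }
    sample_valid = np.arange(pos.shape[0])[:, None] <= n_steps[None, :]
    sdx = true_xz[None, :, 0] - pos[:, :, 0]
    sdz = true_xz[None, :, 1] - pos[:, :, 1]
    sdist = np.hypot(sdx, sdz)
    n_samples = n_steps + 1
    for r in radii:
        inside = sample_valid & (sdist <= r)
        out[f"dwell_{r:g}"] = inside.sum(axis=0) / n_samples
    return out


# ---------------------------------------------------------------------------
# cohorts


def simulate_test_batch(env: EnvironmentSpec, object_id: str,
                        params: AgentParams, n: int,
                        seed: Optional[RngLike] = None) -> pd.DataFrame:
    """Simulate ``n`` independent cued trials for one object and return the
    per-trial default metrics (placement error, path length, header
    direction, cumulative error, initial orientation, dwell fractions).

    Each trial draws a fresh believed location (true + Gaussian(sigma)) and a
    uniform spawn corner; used for parameter-recovery and noise-sweep
    analyses where per-sample trajectories need not be materialized.
    """
    if object_id not in env.chest_locations:
        raise ValueError(f"unknown object id {object_id!r}")
    rng = _rng(seed)
    true = env.chest_locations[object_id]
    true_xz = np.tile(np.array([[true.x, true.z]]), (n, 1))
    bel = true_xz + params.memory_sd * rng.normal(size=(n, 2))
    bel[:, 0] = np.clip(bel[:, 0], 0.0, env.arena_width)
    bel[:, 1] = np.clip(bel[:, 1], 0.0, env.arena_depth)
    corners_xy = np.array([[c.x, c.z] for c in env.spawn_corners])
    starts = corners_xy[rng.integers(0, 4, size=n)]
    walk = _walk_batch(env, starts, bel, params.heading_kappa, params, rng)
    out = _batch_metrics(walk, true_xz)
    out["capped"] = walk.capped
    return pd.DataFrame(out)


def _believed_batch(rng, true_xz, sigma_p, shared_frac, mult, shared_noise, env):
    retrieval = rng.normal(size=true_xz.shape)
    sd_r = sigma_p * math.sqrt(1.0 - shared_frac)
    bel = true_xz + mult * (shared_noise + sd_r * retrieval)
    bel[:, 0] = np.clip(bel[:, 0], 0.0, env.arena_width)
    bel[:, 1] = np.clip(bel[:, 1], 0.0, env.arena_depth)
    return bel


def simulate_cohort(envs: Union[EnvironmentSpec, Sequence[EnvironmentSpec]],
                    design: CohortDesign,
                    params: AgentParams = AgentParams()) -> CohortDataset:
    """A full within-subject cohort: per participant one sleep and one wake
    session on counterbalanced environments, each with training1/2 and two
    12-trial tests. Fully reproducible from ``design.master_seed``; the
    returned dataset carries a ground-truth table (per trial: the sigma in
    force, the believed location, the spawn corner)."""
    if isinstance(envs, EnvironmentSpec):
        envs = [envs]
    ss = np.random.SeedSequence(design.master_seed)
    part_seeds = ss.spawn(design.n_participants)
    sessions = []
    gt_rows = []
    for p_i in range(design.n_participants):
        rng = np.random.default_rng(part_seeds[p_i])
        pid = f"p{p_i + 1:03d}"
        if design.counterbalance:
            conds = ("sleep", "wake") if p_i % 2 == 0 else ("wake", "sleep")
        else:
            conds = ("sleep", "wake")
        env_pair = (envs[p_i % len(envs)], envs[(p_i + 1) % len(envs)])
        sigma_p = params.memory_sd * float(
            np.exp(rng.normal(0.0, design.ability_sd))
        )
        for cond, env in zip(conds, env_pair):
            trials = [
                simulate_training(env, params, rng, phase="training1"),
                simulate_training(env, params, rng, phase="training2"),
            ]
            object_ids = list(env.chest_locations.keys())
            true_xz = np.array(
                [[env.chest_locations[o].x, env.chest_locations[o].z]
                 for o in object_ids]
            )
            sd_shared = sigma_p * math.sqrt(params.memory_shared_frac)
            shared_noise = sd_shared * rng.normal(size=true_xz.shape)
            for test in ("test1", "test2"):
                mult = design.condition_effects[cond][test]
                kappa = params.heading_kappa * design.kappa_test_multipliers[test]
                bel = _believed_batch(rng, true_xz, sigma_p,
                                      params.memory_shared_frac, mult,
                                      shared_noise, env)
                order = rng.permutation(len(object_ids))
                corners = rng.integers(0, 4, size=len(object_ids))
                corner_xy = np.array(
                    [[env.spawn_corners[c].x, env.spawn_corners[c].z]
                     for c in corners]
                )
                walk = _walk_batch(env, corner_xy[order], bel[order],
                                   kappa, params, rng)
                for k, oi in enumerate(order):
                    oid = object_ids[oi]
                    trials.append(
                        _trial_from_walk(walk, k, test, oid,
                                         int(corners[oi]), params)
                    )
                    gt_rows.append({
                        "participant_id": pid,
                        "condition": cond,
                        "phase": test,
                        "object_id": oid,
                        "sigma_used": sigma_p * mult,
                        "kappa_used": kappa,
                        "believed_x": bel[oi, 0],
                        "believed_z": bel[oi, 1],
                        "spawn_corner": int(corners[oi]) + 1,
                        "capped": bool(walk.capped[k]),
                    })
            sessions.append(
                ParticipantSession(
                    participant_id=pid, condition=cond,
                    environment=env, trials=trials,
                )
            )
    return CohortDataset(
        sessions=sessions, study_label="study2",
        ground_truth=pd.DataFrame(gt_rows),
    )


def simulate_study1_cohort(envs: Sequence[EnvironmentSpec],
                           n_participants: int,
                           params: AgentParams = AgentParams(),
                           seed: int = 0,
                           env_sigma_multipliers: Optional[dict] = None,
                           ability_sd: float = 0.2) -> CohortDataset:
    """A between-subject environment-validation cohort: one session per
    participant (environments assigned round-robin), training1/2 and test1
    only. ``env_sigma_multipliers`` (env_id -> factor) lets one environment's
    agents carry inflated memory noise for sensitivity checks.

    The session type requires a condition label; study-1 sessions are all
    tagged ``wake`` as a placeholder (condition is not a study-1 factor).
    """
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(n_participants)
    sessions = []
    gt_rows = []
    for p_i in range(n_participants):
        rng = np.random.default_rng(part_seeds[p_i])
        pid = f"s1p{p_i + 1:03d}"
        env = envs[p_i % len(envs)]
        mult_env = (env_sigma_multipliers or {}).get(env.env_id, 1.0)
        sigma_p = params.memory_sd * mult_env * float(
            np.exp(rng.normal(0.0, ability_sd))
        )
        trials = [
            simulate_training(env, params, rng, phase="training1"),
            simulate_training(env, params, rng, phase="training2"),
        ]
        object_ids = list(env.chest_locations.keys())
        true_xz = np.array(
            [[env.chest_locations[o].x, env.chest_locations[o].z]
             for o in object_ids]
        )
        bel = true_xz + sigma_p * rng.normal(size=true_xz.shape)
        bel[:, 0] = np.clip(bel[:, 0], 0.0, env.arena_width)
        bel[:, 1] = np.clip(bel[:, 1], 0.0, env.arena_depth)
        order = rng.permutation(len(object_ids))
        corners = rng.integers(0, 4, size=len(object_ids))
        corner_xy = np.array(
            [[env.spawn_corners[c].x, env.spawn_corners[c].z] for c in corners]
        )
        walk = _walk_batch(env, corner_xy[order], bel[order],
                           params.heading_kappa, params, rng)
        for k, oi in enumerate(order):
            trials.append(
                _trial_from_walk(walk, k, "test1", object_ids[oi],
                                 int(corners[oi]), params)
            )
            gt_rows.append({
                "participant_id": pid,
                "env_id": env.env_id,
                "object_id": object_ids[oi],
                "sigma_used": sigma_p,
                "believed_x": bel[oi, 0],
                "believed_z": bel[oi, 1],
            })
        sessions.append(
            ParticipantSession(
                participant_id=pid, condition="wake",
                environment=env, trials=trials,
            )
        )
    return CohortDataset(
        sessions=sessions, study_label="study1",
        ground_truth=pd.DataFrame(gt_rows),
    )


def cohort_metric_table(env: EnvironmentSpec, design: CohortDesign,
                        params: AgentParams = AgentParams(),
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Fast path for replicate studies: simulate every test trial of a
    within-subject cohort in one vectorized batch (no training phases, no
    per-sample objects) and return participant-level mean metrics.

    Statistically identical to ``simulate_cohort`` followed by the metric
    layer (same generative model, same metric definitions — the per-trial
    agreement of the batched metrics is covered by tests); used where
    hundreds of replicate cohorts are needed.
    """
    rng = np.random.default_rng(design.master_seed if seed is None else seed)
    n_p = design.n_participants
    object_ids = list(env.chest_locations.keys())
    n_obj = len(object_ids)
    true_xz = np.array(
        [[env.chest_locations[o].x, env.chest_locations[o].z]
         for o in object_ids]
    )
    corners_xy = np.array([[c.x, c.z] for c in env.spawn_corners])
    rows = []
    starts_all, bel_all, kappa_all, meta = [], [], [], []
    for p_i in range(n_p):
        sigma_p = params.memory_sd * float(
            np.exp(rng.normal(0.0, design.ability_sd))
        )
        for cond in ("sleep", "wake"):
            sd_shared = sigma_p * math.sqrt(params.memory_shared_frac)
            shared_noise = sd_shared * rng.normal(size=true_xz.shape)
            for test in ("test1", "test2"):
                mult = design.condition_effects[cond][test]
                kappa = params.heading_kappa * design.kappa_test_multipliers[test]
                bel = _believed_batch(rng, true_xz, sigma_p,
                                      params.memory_shared_frac, mult,
                                      shared_noise, env)
                corners = rng.integers(0, 4, size=n_obj)
                starts_all.append(corners_xy[corners])
                bel_all.append(bel)
                kappa_all.append(np.full(n_obj, kappa))
                meta.append((p_i, cond, test))
    starts = np.concatenate(starts_all)
    believed = np.concatenate(bel_all)
    kappas = np.concatenate(kappa_all)
    walk = _walk_batch(env, starts, believed, kappas, params, rng)
    true_rep = np.concatenate([true_xz] * len(meta))
    mets = _batch_metrics(walk, true_rep)
    cols = list(mets.keys())
    for b, (p_i, cond, test) in enumerate(meta):
        sl = slice(b * n_obj, (b + 1) * n_obj)
        row = {
            "participant_id": f"p{p_i + 1:03d}",
            "condition": cond,
            "phase": test,
        }
        for c in cols:
            row[c] = float(np.nanmean(mets[c][sl]))
        rows.append(row)
    return pd.DataFrame(rows)
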