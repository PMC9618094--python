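import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mmnav import (
    AgentParams,
    CohortDesign,
    Point2D,
    TrajectorySample,
    TrialTrajectory,
    default_environment,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env():
    return default_environment()


@pytest.fixture(scope="session")
def params():
    return AgentParams()


@pytest.fixture(scope="session")
def small_cohort(env):
    """An 8-participant within-subject cohort shared across tests."""
    design = CohortDesign(n_participants=8, master_seed=11)
    return simulate_cohort(env, design)


def make_test_trial(points, headings, object_id="axe", phase="test1",
                    spawn_corner=1, placed=True, events=None):
    """Hand-build a test trial from (x, z) points and per-step headings.

    ``headings`` has one entry per transition; the terminal sample reuses the
    last heading. ``events`` overrides the default spawn/move/place pattern.
    """
    n = len(points)
    assert len(headings) in (n - 1, n)
    samples = []
    for i, (x, z) in enumerate(points):
        if events is not None:
            ev = events[i]
        elif i == 0:
            ev = "spawn"
        elif i == n - 1 and placed:
            ev = "place_chest"
        else:
            ev = "move"
        h = headings[min(i, len(headings) - 1)]
        samples.append(
            TrajectorySample(step_index=i, t=float(i), pos=Point2D(x, z),
                             heading_deg=float(h), event=ev)
        )
    placement = Point2D(*points[-1]) if placed else None
    return TrialTrajectory(phase=phase, samples=samples, object_id=object_id,
                           spawn_corner=spawn_corner, placement=placement)


@pytest.fixture
def make_trial():
    return make_test_trial


def rotate_env_and_trial(env, trial, angle_deg, dx=0.0, dz=0.0):
    """Apply one rigid motion to environment, trajectory and headings."""
    import math

    from mmnav.model import EnvironmentSpec
    from mmnav.geometry import wrap_deg

    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))

    def rot(p):
        return Point2D(c * p.x - s * p.z + dx, s * p.x + c * p.z + dz)

    env2 = EnvironmentSpec(
        env_id=env.env_id, arena_width=1e9, arena_depth=1e9,
        chest_locations={k: rot(v) for k, v in env.chest_locations.items()},
        spawn_corners=[rot(p) for p in env.spawn_corners],
    )
    samples = [
        TrajectorySample(sm.step_index, sm.t, rot(sm.pos),
                         wrap_deg(sm.heading_deg + angle_deg), sm.event)
        for sm in trial.samples
    ]
    trial2 = TrialTrajectory(
        phase=trial.phase, samples=samples, object_id=trial.object_id,
        spawn_corner=trial.spawn_corner,
        placement=rot(trial.placement) if trial.placement else None,
    )
    return env2, trial2


def random_walk_trial(rng, env, object_id="axe", n_steps=None, placed=True):
    """A random (non-goal-directed) test trial inside the arena, for
    oracle-equivalence checks."""
    n = n_steps or int(rng.integers(2, 60))
    pos = np.empty((n + 1, 2))
    pos[0] = rng.uniform(5, 95, size=2)
    headings = rng.uniform(-180.0, 180.0, size=n)
    step = rng.uniform(0.0, 2.0, size=n)  # includes sub-threshold steps
    for i in range(n):
        rad = np.radians(headings[i])
        pos[i + 1] = pos[i] + step[i] * np.array([np.cos(rad), np.sin(rad)])
        pos[i + 1] = np.clip(pos[i + 1], 0.0, 100.0)
    return make_test_trial(
        [tuple(p) for p in pos], list(headings) + [headings[-1]],
        object_id=object_id, placed=placed,
    )
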