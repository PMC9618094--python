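import math

import numpy as np
import pytest

from mmnav import (
    MetricConfig,
    Point2D,
    approach_angle,
    bearing,
    cumulative_error,
    header_direction,
    initial_orientation,
    path_length,
    placement_error,
    proximity_dwell,
    same_viewpoint,
    simulate_test_trial,
    training_summaries,
    aggregate,
    AgentParams,
    CohortDesign,
    simulate_cohort,
)
from mmnav.metrics import DegenerateTrialError, compute_trial_metrics
from mmnav.model import EnvironmentSpec, TrajectorySample, TrialTrajectory
from conftest import make_test_trial, random_walk_trial
import oracles


def straight_line_trial(env, object_id="axe", start=(0.0, 0.0), offset=0.0):
    """Walk straight from start to the chest, facing `offset` degrees off the
    instantaneous bearing at every step."""
    true = env.chest_locations[object_id]
    n = int(math.hypot(true.x - start[0], true.z - start[1]))
    pts = [
        (start[0] + (true.x - start[0]) * i / n,
         start[1] + (true.z - start[1]) * i / n)
        for i in range(n + 1)
    ]
    headings = [
        oracles.wrap(oracles.brute_bearing(*pts[i], true.x, true.z) + offset)
        for i in range(n)
    ]
    return make_test_trial(pts, headings + [headings[-1]],
                           object_id=object_id)


class TestPlacementError:
    def test_three_four_five(self, env):
        trial = make_test_trial([(20, 20), (23, 24)], [0, 0])
        # axe sits at (20, 20); placement 3 east 4 south -> 5 blocks off
        assert placement_error(trial, env) == pytest.approx(5.0)

    def test_exact_placement_is_zero(self, env):
        trial = make_test_trial([(0, 0), (20, 20)], [0, 0])
        assert placement_error(trial, env) == 0.0

    def test_missing_placement_rejected(self, env):
        trial = make_test_trial([(0, 0), (1, 1)], [0, 0], placed=False)
        with pytest.raises(ValueError, match="placement"):
            placement_error(trial, env)

    def test_random_placements_match_hypot_oracle(self, env):
        rng = np.random.default_rng(5)
        for _ in range(500):
            p = rng.uniform(0, 100, 2)
            trial = make_test_trial([(0, 0), tuple(p)], [0, 0])
            assert placement_error(trial, env) == pytest.approx(
                oracles.brute_placement_error(trial, env), abs=1e-9
            )


class TestPathLength:
    def test_all_moving(self, env):
        pts = [(float(i), 0.0) for i in range(11)]
        trial = make_test_trial(pts, [0.0] * 11)
        assert path_length(trial) == 10

    def test_single_sample(self, env):
        trial = TrialTrajectory(
            phase="test1", object_id="axe", spawn_corner=1,
            samples=[TrajectorySample(0, 0.0, Point2D(1, 1), 0.0, "spawn")],
        )
        assert path_length(trial) == 0

    def test_stationary_steps_excluded(self, env):
        pts = [(0, 0), (0.1, 0), (1.1, 0), (1.15, 0), (2.0, 0)]
        trial = make_test_trial(pts, [0.0] * 5)
        assert path_length(trial) == 2


class TestHeaderAndCumulative:
    def test_straight_direct_walk_scores_zero(self, env):
        trial = straight_line_trial(env)
        assert header_direction(trial, env) == pytest.approx(0.0, abs=1e-9)
        assert cumulative_error(trial, env) == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_returns_offset(self, env):
        trial = straight_line_trial(env, offset=30.0)
        assert header_direction(trial, env) == pytest.approx(30.0, abs=1e-9)

    def test_alternating_deviations_cancel_in_header_not_cumulative(self, env):
        # walk along +x toward the chest at (20,20) from (0,20); face
        # alternately +40/-40 off the instantaneous bearing (which is 0)
        n = 10
        pts = [(float(i), 20.0) for i in range(n + 1)]
        headings = [40.0 if i % 2 == 0 else -40.0 for i in range(n)]
        trial = make_test_trial(pts, headings + [headings[-1]])
        assert header_direction(trial, env) == pytest.approx(0.0, abs=1e-9)
        assert cumulative_error(trial, env) == pytest.approx(40.0 * n)

    def test_reversal_inflates_cumulative_only(self, env):
        # out-and-back along +x in front of the chest at (20,20): half the
        # steps face the target, half face directly away (180 deg deviation)
        pts = [(float(i), 20.0) for i in range(6)]
        pts += [(float(i), 20.0) for i in range(4, -1, -1)]
        headings = [0.0] * 5 + [180.0] * 5
        trial = make_test_trial(pts, headings + [headings[-1]])
        assert cumulative_error(trial, env) == pytest.approx(180.0 * 5)
        assert header_direction(trial, env) == pytest.approx(90.0)

    def test_zero_movement_is_degenerate(self, env):
        trial = make_test_trial([(5, 5), (5, 5)], [0, 0])
        with pytest.raises(DegenerateTrialError):
            header_direction(trial, env)

    def test_cumulative_bounds_header_on_random_trials(self, env):
        rng = np.random.default_rng(7)
        for _ in range(100):
            trial = random_walk_trial(rng, env)
            try:
                h = header_direction(trial, env)
            except DegenerateTrialError:
                continue
            c = cumulative_error(trial, env)
            n = len(oracles.brute_deviations(trial, env))
            assert c >= n * h - 1e-9

    def test_fixed_start_line_mode(self, env):
        # face due east the whole way while the start->chest line is fixed:
        # deviation is constant = -(line bearing)
        cfg = MetricConfig(heading_reference="fixed_start_line")
        trial = straight_line_trial(env, start=(0.0, 0.0))
        line = bearing(Point2D(0, 0), env.chest_locations["axe"])
        trial2 = make_test_trial(
            [(s.pos.x, s.pos.z) for s in trial.samples],
            [0.0] * len(trial.samples),
        )
        assert header_direction(trial2, env, cfg) == pytest.approx(abs(line))

    def test_movement_bearing_fallback(self, env):
        # headings are garbage but movement is straight at the chest
        trial = straight_line_trial(env)
        garbled = make_test_trial(
            [(s.pos.x, s.pos.z) for s in trial.samples],
            [123.0] * len(trial.samples),
        )
        cfg = MetricConfig(use_movement_bearing=True)
        assert header_direction(garbled, env, cfg) == pytest.approx(
            0.0, abs=1e-9
        )


class TestInitialOrientation:
    def test_first_five_facing_true_bearing(self, env):
        trial = straight_line_trial(env)
        assert initial_orientation(trial, env) == pytest.approx(0.0, abs=1e-9)

    def test_constant_ten_degrees(self, env):
        trial = straight_line_trial(env, offset=10.0)
        assert initial_orientation(trial, env) == pytest.approx(10.0)

    def test_uses_only_first_five_steps(self, env):
        # big deviations after step 5 must not matter
        n = 10
        pts = [(float(i), 20.0) for i in range(n + 1)]
        headings = [10.0] * 5 + [120.0] * 5
        trial = make_test_trial(pts, headings + [headings[-1]])
        assert initial_orientation(trial, env) == pytest.approx(10.0)

    def test_random_prefixes_match_oracle(self, env):
        rng = np.random.default_rng(9)
        for _ in range(200):
            trial = random_walk_trial(rng, env)
            try:
                got = initial_orientation(trial, env)
            except DegenerateTrialError:
                continue
            assert got == pytest.approx(
                oracles.brute_initial_orientation(trial, env), abs=1e-9
            )


class TestApproachAngle:
    def test_straight_approach_from_east(self, env):
        # approach the axe chest at (20,20) walking due west
        pts = [(20.0 + 10 - i, 20.0) for i in range(11)]
        trial = make_test_trial(pts, [180.0] * 11)
        ang = approach_angle(trial, env.chest_locations["axe"])
        assert ang == pytest.approx(180.0)

    def test_zero_noise_agent_consistent_across_phases(self, env):
        params = AgentParams(memory_sd=0.0, heading_kappa=np.inf)
        t1 = simulate_test_trial(env, "bottle", params, seed=1,
                                 spawn_corner=2, phase="test1")
        t2 = simulate_test_trial(env, "bottle", params, seed=99,
                                 spawn_corner=2, phase="test2")
        a1 = approach_angle(t1, env.chest_locations["bottle"])
        a2 = approach_angle(t2, env.chest_locations["bottle"])
        assert abs(a1 - a2) < 1e-6

    def test_spiral_matches_circular_mean_oracle(self, env):
        true = env.chest_locations["axe"]
        thetas = np.linspace(0, 3 * np.pi, 40)
        radii = np.linspace(25, 0.5, 40)
        pts = [
            (true.x + r * math.cos(t), true.z + r * math.sin(t))
            for r, t in zip(radii, thetas)
        ]
        trial = make_test_trial(pts, [0.0] * len(pts))
        got = approach_angle(trial, true)
        want = oracles.brute_approach_angle(trial, true)
        assert got == pytest.approx(want, abs=1e-9)

    def test_never_approached_marker(self, env):
        pts = [(80.0 + i, 80.0) for i in range(5)]
        trial = make_test_trial(pts, [0.0] * 5, object_id="axe")
        from mmnav.metrics import NoApproachError
        with pytest.raises(NoApproachError):
            approach_angle(trial, env.chest_locations["axe"])


class TestSameViewpoint:
    @pytest.mark.parametrize("a,b,expected", [
        (0.0, 22.5, True),   # boundary inclusive: half the 45-degree view
        (0.0, 23.0, False),
        (350.0, 10.0, True),
        (170.0, -170.0, True),
    ])
    def test_cases(self, a, b, expected):
        assert same_viewpoint(a, b) is expected


class TestProximityDwell:
    def test_all_samples_inside_smallest_radius(self, env):
        true = env.chest_locations["axe"]
        pts = [(true.x + i * 0.5, true.z) for i in range(10)]
        trial = make_test_trial(pts, [0.0] * 10)
        dwell = proximity_dwell(trial, env)
        assert dwell == {10.0: 1.0, 20.0: 1.0, 30.0: 1.0}

    def test_default_radii(self, env):
        trial = make_test_trial([(20, 20), (21, 20)], [0, 0])
        assert set(proximity_dwell(trial, env)) == {10.0, 20.0, 30.0}

    def test_random_trials_match_counting_oracle(self, env):
        rng = np.random.default_rng(13)
        for _ in range(100):
            trial = random_walk_trial(rng, env)
            dwell = proximity_dwell(trial, env)
            for r, frac in dwell.items():
                assert frac == pytest.approx(
                    oracles.brute_dwell(trial, env, r), abs=1e-12
                )

    def test_monotone_in_radius(self, env):
        rng = np.random.default_rng(17)
        for _ in range(50):
            trial = random_walk_trial(rng, env)
            dwell = proximity_dwell(trial, env)
            vals = [dwell[r] for r in sorted(dwell)]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert vals == sorted(vals)


class TestTrainingSummaries:
    def test_hand_counted_events(self, env):
        pts = [(float(i), 20.0) for i in range(6)]
        events = ["spawn", "move", "open_chest", "move", "open_chest", "move"]
        trial = TrialTrajectory(
            phase="training1",
            samples=[
                TrajectorySample(i, float(i) * 2.0, Point2D(*p), 0.0, e)
                for i, (p, e) in enumerate(zip(pts, events))
            ],
        )
        s = training_summaries(trial, env)
        assert s.time_in_phase_s == pytest.approx(10.0)
        assert s.chests_opened_total == 2
        assert s.total_steps == 5

    def test_revisit_counted_in_total_not_distinct(self, env):
        true = env.chest_locations["axe"]
        pts = [(true.x, true.z)] * 3
        events = ["spawn", "open_chest", "open_chest"]
        trial = TrialTrajectory(
            phase="training1",
            samples=[
                TrajectorySample(i, float(i), Point2D(*p), 0.0, e)
                for i, (p, e) in enumerate(zip(pts, events))
            ],
        )
        s = training_summaries(trial, env)
        assert s.chests_opened_total == 2
        assert s.chests_opened_distinct == 1


class TestInvariances:
    @pytest.mark.parametrize("angle,dx,dz", [(37.0, 0, 0), (120.0, 13, -7),
                                             (-90.0, 5, 5)])
    def test_angle_metrics_rotation_translation_invariant(
            self, env, angle, dx, dz):
        from conftest import rotate_env_and_trial
        rng = np.random.default_rng(23)
        for _ in range(20):
            trial = random_walk_trial(rng, env)
            env2, trial2 = rotate_env_and_trial(env, trial, angle, dx, dz)
            try:
                h0 = header_direction(trial, env)
            except DegenerateTrialError:
                continue
            assert header_direction(trial2, env2) == pytest.approx(
                h0, abs=1e-9)
            assert cumulative_error(trial2, env2) == pytest.approx(
                cumulative_error(trial, env), abs=1e-9)
            assert initial_orientation(trial2, env2) == pytest.approx(
                initial_orientation(trial, env), abs=1e-9)
            assert placement_error(trial2, env2) == pytest.approx(
                placement_error(trial, env), abs=1e-9)


class TestAggregate:
    def test_identical_trials_mean_is_common_value(self, env):
        from mmnav.model import CohortDataset, ParticipantSession
        trials = []
        for oid in list(env.chest_locations)[:12]:
            true = env.chest_locations[oid]
            pts = [(true.x - 5 + i, true.z) for i in range(6)]
            trials.append(make_test_trial(pts, [0.0] * 6, object_id=oid))
        sess = ParticipantSession("p1", "sleep", env, trials=trials)
        ds = CohortDataset(sessions=[sess], study_label="study1")
        part, item = aggregate(ds, item_filter_sd=None)
        assert part.loc[0, "placement_error"] == pytest.approx(0.0)
        assert part.loc[0, "path_length"] == pytest.approx(5.0)
        assert part.loc[0, "n_items"] == 12

    def test_item_filter_removes_outlier_object_everywhere(self, small_cohort):
        part, item = aggregate(small_cohort)
        excl = item[item["excluded_item"]]
        surv = item[~item["excluded_item"]]
        # participant means recompute exactly from surviving items
        for _, row in part.head(6).iterrows():
            sub = surv[
                (surv["participant_id"] == row["participant_id"])
                & (surv["condition"] == row["condition"])
                & (surv["phase"] == row["phase"])
            ]
            assert row["placement_error"] == pytest.approx(
                sub["placement_error"].mean()
            )
            assert row["n_items"] == len(sub)

    def test_means_match_bruteforce(self, small_cohort):
        part, item = aggregate(small_cohort, item_filter_sd=None)
        surv = item[~item["excluded_item"]]
        row = part.iloc[3]
        sub = surv[
            (surv["participant_id"] == row["participant_id"])
            & (surv["condition"] == row["condition"])
            & (surv["phase"] == row["phase"])
        ]
        vals = [v for v in sub["header_direction"] if v == v]
        assert row["header_direction"] == pytest.approx(
            sum(vals) / len(vals)
        )
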