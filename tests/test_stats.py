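import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mmnav.stats import (
    DegenerateVarianceError,
    IncompleteDesignError,
    mixed_anova,
    one_way_anova,
    pearson_bonferroni,
    rm_anova,
    rm_anova_2x2,
    sd_outlier_filter,
)
import oracles


def long_2x2(values_by_cell):
    rows = []
    n = len(next(iter(values_by_cell.values())))
    for (a, b), vals in values_by_cell.items():
        for i in range(n):
            rows.append({"subject": f"s{i}", "A": a, "B": b, "y": vals[i]})
    return pd.DataFrame(rows)


def random_2x2(rng, n=6):
    return {
        (a, b): list(rng.normal(size=n))
        for a in ("a1", "a2") for b in ("b1", "b2")
    }


class TestRmAnova2x2:
    def test_subject_offsets_only_give_zero_f(self):
        cells = {(a, b): [1.0, 2.0, 5.0, -3.0]
                 for a in ("a1", "a2") for b in ("b1", "b2")}
        res = rm_anova_2x2(long_2x2(cells), "y", ["A", "B"], "subject")
        for eff in res.effects.values():
            assert eff.F == 0.0
            assert eff.p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sum_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_2x2(rng)
        res = rm_anova_2x2(long_2x2(cells), "y", ["A", "B"], "subject")
        want = oracles.brute_rm_2x2(cells)
        for mine, theirs in (("A", "A"), ("B", "B"), ("A x B", "A x B")):
            F, df1, df2, ss_eff, ss_err = want[theirs]
            eff = res[mine]
            assert eff.F == pytest.approx(F, abs=1e-9)
            assert (eff.df_num, eff.df_den) == (df1, df2)
            assert eff.partial_eta2 == pytest.approx(
                ss_eff / (ss_eff + ss_err), abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_f_equals_squared_paired_t(self, seed):
        """Each two-level effect's F equals the square of the paired t on
        the corresponding within-subject contrast."""
        rng = np.random.default_rng(100 + seed)
        cells = random_2x2(rng, n=9)
        res = rm_anova_2x2(long_2x2(cells), "y", ["A", "B"], "subject")
        c = {k: np.array(v) for k, v in cells.items()}
        contrasts = {
            "A": (c[("a1", "b1")] + c[("a1", "b2")]
                  - c[("a2", "b1")] - c[("a2", "b2")]) / 2,
            "B": (c[("a1", "b1")] - c[("a1", "b2")]
                  + c[("a2", "b1")] - c[("a2", "b2")]) / 2,
            "A x B": (c[("a1", "b1")] - c[("a1", "b2")]
                      - c[("a2", "b1")] + c[("a2", "b2")]),
        }
        for name, d in contrasts.items():
            t = sps.ttest_1samp(d, 0.0)
            assert res[name].F == pytest.approx(t.statistic ** 2, abs=1e-9)
            assert res[name].p == pytest.approx(t.pvalue, abs=1e-12)

    def test_missing_cell_rejected(self):
        df = long_2x2(random_2x2(np.random.default_rng(0))).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            rm_anova_2x2(df, "y", ["A", "B"], "subject")

    def test_constant_data_degenerate(self):
        cells = {(a, b): [3.0, 3.0, 3.0] for a in "xy" for b in "uv"}
        res = rm_anova_2x2(long_2x2(cells), "y", ["A", "B"], "subject")
        for eff in res.effects.values():
            assert eff.F == 0.0

    def test_zero_error_with_effect_raises(self):
        # a pure A effect identical in every subject: error SS is exactly 0
        cells = {("a1", b): [1.0, 1.0, 1.0] for b in ("b1", "b2")}
        cells.update({("a2", b): [2.0, 2.0, 2.0] for b in ("b1", "b2")})
        with pytest.raises(DegenerateVarianceError):
            rm_anova_2x2(long_2x2(cells), "y", ["A", "B"], "subject")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pingouin_two_way(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(40 + seed)
        df = long_2x2(random_2x2(rng, n=8))
        res = rm_anova_2x2(df, "y", ["A", "B"], "subject")
        tab = pg.rm_anova(data=df, dv="y", within=["A", "B"],
                          subject="subject", detailed=True)
        for name, row in (("A", "A"), ("B", "B"), ("A x B", "A * B")):
            pg_row = tab[tab["Source"] == row].iloc[0]
            assert res[name].F == pytest.approx(pg_row["F"], rel=1e-9)
            assert res[name].p == pytest.approx(pg_row["p_unc"], rel=1e-6)


class TestThreeWayRmAnova:
    def test_marginalizing_third_factor_preserves_other_effects(self):
        """Effects not involving a factor equal the two-way ANOVA on data
        averaged over that factor's levels (balanced-design identity)."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            for a in ("sleep", "wake"):
                for r in (10, 20, 30):
                    for t in ("t1", "t2"):
                        rows.append({
                            "subject": f"s{i}", "A": a, "R": r, "T": t,
                            "y": rng.normal() + 0.01 * r,
                        })
        df = pd.DataFrame(rows)
        full = rm_anova(df, "y", ["A", "R", "T"], "subject")
        avg = (df.groupby(["subject", "A", "T"], as_index=False)["y"].mean())
        two = rm_anova_2x2(avg, "y", ["A", "T"], "subject")
        for name in ("A", "T", "A x T"):
            assert full[name].F == pytest.approx(two[name].F, abs=1e-9)
        assert full["R"].df_num == 2
        assert full["A x R x T"].df_num == 2

    def test_strong_radius_effect_detected(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(10):
            for a in ("sleep", "wake"):
                for r in (10, 20, 30):
                    for t in ("t1", "t2"):
                        rows.append({
                            "subject": f"s{i}", "A": a, "R": r, "T": t,
                            "y": r / 100.0 + rng.normal(scale=0.02),
                        })
        res = rm_anova(pd.DataFrame(rows), "y", ["A", "R", "T"], "subject")
        assert res["R"].p < 1e-6
        assert res["R"].partial_eta2 > 0.9


class TestMixedAnova:
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pingouin(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7 + seed)
        rows = []
        for g in ("g1", "g2", "g3"):
            for i in range(6):
                sid = f"{g}_s{i}"
                base = rng.normal()
                for w in ("w1", "w2"):
                    rows.append({"subject": sid, "group": g, "time": w,
                                 "y": base + rng.normal()})
        df = pd.DataFrame(rows)
        res = mixed_anova(df, "y", "time", "group", "subject")
        tab = pg.mixed_anova(data=df, dv="y", within="time",
                             between="group", subject="subject")
        for name, src in (("group", "group"), ("time", "time"),
                          ("time x group", "Interaction")):
            row = tab[tab["Source"] == src].iloc[0]
            assert res[name].F == pytest.approx(row["F"], rel=1e-9)
            assert res[name].p == pytest.approx(row["p_unc"], rel=1e-6)
            if not np.isnan(row["np2"]):
                assert res[name].partial_eta2 == pytest.approx(
                    row["np2"], rel=1e-6)

    def test_two_group_between_f_equals_t_squared(self):
        rng = np.random.default_rng(15)
        rows = []
        for g in ("g1", "g2"):
            for i in range(8):
                sid = f"{g}_s{i}"
                base = rng.normal()
                for w in ("w1", "w2"):
                    rows.append({"subject": sid, "group": g, "time": w,
                                 "y": base + rng.normal()})
        df = pd.DataFrame(rows)
        res = mixed_anova(df, "y", "time", "group", "subject")
        sub_means = df.groupby(["subject", "group"])["y"].mean().reset_index()
        g1 = sub_means[sub_means["group"] == "g1"]["y"]
        g2 = sub_means[sub_means["group"] == "g2"]["y"]
        t = sps.ttest_ind(g1, g2)
        assert res["group"].F == pytest.approx(t.statistic ** 2, abs=1e-9)

    def test_small_group_rejected(self):
        df = pd.DataFrame({
            "subject": ["s1", "s1", "s2", "s2", "s3", "s3"],
            "group": ["g1", "g1", "g1", "g1", "g2", "g2"],
            "time": ["w1", "w2"] * 3,
            "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        with pytest.raises(IncompleteDesignError, match="< 2 subjects"):
            mixed_anova(df, "y", "time", "group", "subject")


class TestOneWayAnova:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=10), rng.normal(loc=0.5, size=12)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)
        assert res["group"].F == pytest.approx(t.statistic ** 2, abs=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(22)
        groups = [rng.normal(loc=m, size=9) for m in (0, 0.3, 1.0, -0.2)]
        res = one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert res["group"].F == pytest.approx(F, rel=1e-12)
        assert res["group"].p == pytest.approx(p, rel=1e-9)

    def test_separated_group_is_extreme(self):
        groups = [[0.0, 0.1, -0.1, 0.05], [0.02, -0.02, 0.08, 0.0],
                  [100.0, 100.1, 99.9, 100.05]]
        res = one_way_anova(groups)
        assert res["group"].p < 1e-6


class TestPearsonBonferroni:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = 2 * df["x"] + 1
        res = pearson_bonferroni(df)
        assert res.pairs[0].r == pytest.approx(1.0)

    def test_six_pair_family_alpha(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(rng.normal(size=(20, 4)),
                          columns=["a", "b", "c", "d"])
        res = pearson_bonferroni(df, alpha=0.05)
        assert len(res.pairs) == 6
        assert res.corrected_alpha == pytest.approx(0.05 / 6)
        assert res.corrected_alpha == pytest.approx(0.00833, abs=5e-5)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(33)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        res = pearson_bonferroni(df)
        for pc in res.pairs:
            x, y = df[pc.a].to_numpy(), df[pc.b].to_numpy()
            r_brute = (
                np.mean((x - x.mean()) * (y - y.mean()))
                / (x.std() * y.std())
            )
            assert pc.r == pytest.approx(r_brute, abs=1e-12)

    def test_corrected_significance_implies_nominal(self):
        rng = np.random.default_rng(34)
        x = rng.normal(size=25)
        df = pd.DataFrame({
            "a": x, "b": x + rng.normal(scale=0.3, size=25),
            "c": rng.normal(size=25), "d": rng.normal(size=25),
        })
        res = pearson_bonferroni(df, alpha=0.05)
        for pc in res.pairs:
            if pc.significant:
                assert pc.p <= res.alpha

    def test_zero_variance_marker(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                           "b": [1.0, 2.0, 3.0, 4.0]})
        res = pearson_bonferroni(df, family=[("a", "b")])
        assert np.isnan(res.pairs[0].r)
        assert res.pairs[0].note == "zero variance"


class TestSdOutlierFilter:
    def test_spike_z_below_threshold_is_kept(self):
        # z of 100 within {1,1,1,1,100} is exactly 2.0 (population SD), so
        # the default 2.5 SD filter keeps it; a 1.9 SD filter removes it
        vals = [1.0, 1.0, 1.0, 1.0, 100.0]
        res = sd_outlier_filter(vals, 2.5, "two_sided")
        z = (100.0 - np.mean(vals)) / np.std(vals)
        assert z == pytest.approx(2.0)
        assert res.n_removed == 0
        res19 = sd_outlier_filter(vals, 1.9, "two_sided")
        assert list(res19.removed) == [4]

    def test_all_equal_removes_nothing_flagged(self):
        res = sd_outlier_filter([2.0, 2.0, 2.0], 2.5)
        assert res.zero_sd
        assert res.n_removed == 0

    def test_above_only_ignores_low_outliers(self):
        rng = np.random.default_rng(41)
        vals = np.concatenate([rng.normal(size=40), [-30.0]])
        res = sd_outlier_filter(vals, 2.5, "above_only")
        assert 40 not in res.removed
        res2 = sd_outlier_filter(vals, 2.5, "two_sided")
        assert 40 in res2.removed

    def test_single_pass_uses_full_sample_moments(self):
        rng = np.random.default_rng(42)
        vals = np.concatenate([rng.normal(size=50), [40.0, 45.0]])
        res = sd_outlier_filter(vals, 2.5, "two_sided")
        z = (vals - vals.mean()) / vals.std()
        assert set(res.removed) == set(np.flatnonzero(np.abs(z) > 2.5))

    def test_default_threshold(self):
        import inspect
        sig = inspect.signature(sd_outlier_filter)
        assert sig.parameters["threshold_sd"].default == 2.5
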