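import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cfrd.errors import ValidationError
from cfrd.pipeline import BIN_COLS, CfrdPanel
from cfrd.stats import (
    LongitudinalDesign,
    StatBundle,
    analyze,
    ats_f2_ld_f1,
    ats_table,
    games_howell,
    mann_whitney_bonferroni,
    normality_check,
    paired_t_bonferroni,
    rm_anova_gg,
    welch_anova,
)

from oracles import (
    ats_oracle,
    games_howell_oracle,
    mann_whitney_exact_oracle,
    welch_oracle,
)

# Frozen from the independent contrast-matrix oracle on the seeded
# fixture below (effect -> (ATS, box df)); the oracle is also re-run at
# test time.
ATS_FIXTURE = {
    "size": (0.16178666279075185, 1.731392708287514),
    "perf": (0.016186068259472202, 1.9289628551340177),
    "time": (49.733633223427624, 7.791945953488496),
    "size:perf": (1.8231071626092892, 3.019134453776835),
    "size:time": (0.5964497455073671, 11.617108090537952),
    "perf:time": (0.4809181521465915, 11.933218482410084),
    "size:perf:time": (1.2613061908283667, 15.945733424947909),
}


def fixture_design(n_per=4, seed=20240917, trend=0.3):
    rng = np.random.default_rng(seed)
    fa = np.repeat([1, 4, 10], 3 * n_per)
    fb = np.tile(np.repeat([1, 2, 3], n_per), 3)
    X = rng.normal(size=(len(fa), 12)) + trend * np.arange(12)
    return X, fa, fb


class TestAts:
    def test_matches_independent_oracle_and_frozen_values(self):
        X, fa, fb = fixture_design()
        mine = {r.effect: r for r in
                ats_f2_ld_f1(LongitudinalDesign(X, fa, fb))}
        orc = ats_oracle(X, fa, fb)
        for effect, (ats, df) in ATS_FIXTURE.items():
            assert mine[effect].statistic == pytest.approx(ats, abs=1e-6)
            assert mine[effect].df == pytest.approx(df, abs=1e-6)
            assert mine[effect].statistic == pytest.approx(orc[effect][0], abs=1e-9)
            assert mine[effect].df == pytest.approx(orc[effect][1], abs=1e-9)
            assert mine[effect].p == pytest.approx(orc[effect][2], abs=1e-9)

    def test_invariant_under_strictly_monotone_transform(self):
        X, fa, fb = fixture_design(seed=5)
        base = ats_f2_ld_f1(LongitudinalDesign(X, fa, fb))
        trans = ats_f2_ld_f1(LongitudinalDesign(np.exp(X / 3), fa, fb))
        for r1, r2 in zip(base, trans):
            assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
            assert r1.df == pytest.approx(r2.df, rel=1e-12)

    def test_invariant_under_subject_permutation(self):
        X, fa, fb = fixture_design(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(fa))
        base = ats_f2_ld_f1(LongitudinalDesign(X, fa, fb))
        shuf = ats_f2_ld_f1(LongitudinalDesign(X[perm], fa[perm], fb[perm]))
        for r1, r2 in zip(base, shuf):
            assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_small_cell_rejected_naming_cell(self):
        X, fa, fb = fixture_design(n_per=2)
        fa = fa.copy()
        fa[0] = 4  # leaves cell (1, 1) with a single subject
        with pytest.raises(ValidationError, match=r"size=1, perf=1"):
            LongitudinalDesign(X, fa, fb)

    def test_constant_response_rejected(self):
        _, fa, fb = fixture_design()
        with pytest.raises(ValidationError, match="constant"):
            ats_f2_ld_f1(LongitudinalDesign(np.ones((len(fa), 12)), fa, fb))

    def test_power_monotone_in_injected_trend(self):
        """A larger time-trend in one cell never lowers size:time on average."""
        rng = np.random.default_rng(42)
        n_per = 6
        fa = np.repeat([1, 4, 10], 3 * n_per)
        fb = np.tile(np.repeat([1, 2, 3], n_per), 3)
        cell = (fa == 1)
        stats_small, stats_big = [], []
        for _ in range(200):
            X = rng.normal(size=(len(fa), 12))
            bump = np.linspace(0, 1, 12)
            for scale, out in ((0.5, stats_small), (1.5, stats_big)):
                Y = X.copy()
                Y[cell] += scale * bump
                res = ats_f2_ld_f1(LongitudinalDesign(Y, fa, fb),
                                   effects=["size:time"])
                out.append(res[0].statistic)
        assert np.mean(stats_big) > np.mean(stats_small)


class TestWelchAnova:
    def test_two_groups_equals_welch_t_squared(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 2, 20)
        res = welch_anova([g1, g2])
        t, p = sps.ttest_ind(g1, g2, equal_var=False)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_three_group_hand_computed_oracle(self):
        groups = [
            np.array([27.0, 26.2, 28.8, 33.5, 28.8]),
            np.array([22.8, 23.1, 27.7, 27.6, 24.0, 25.0]),
            np.array([21.9, 23.4, 20.1, 27.8, 19.3, 26.2, 24.5]),
        ]
        res = welch_anova(groups)
        F, df1, df2, p = welch_oracle(groups)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.df1 == pytest.approx(df1, abs=1e-10)
        assert res.df2 == pytest.approx(df2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_exact_classical_equivalence_with_two_equal_variance_groups(self):
        # with k=2 and identical sample variances Welch == classical F
        base = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        groups = [base, base + 3.0]
        res = welch_anova(groups)
        F_classic = sps.f_oneway(*groups).statistic
        assert res.F == pytest.approx(F_classic, rel=1e-10)

    def test_approaches_classical_anova_for_large_balanced_groups(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, 4000) for m in (0.0, 0.05, 0.1)]
        res = welch_anova(groups)
        assert res.F == pytest.approx(sps.f_oneway(*groups).statistic, rel=5e-3)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [welch_anova([rng.normal(size=10), rng.normal(size=15)]).p
              for _ in range(1000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            welch_anova([np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])])


class TestGamesHowell:
    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(0, 1, 10), rng.normal(1, 3, 14)
        gh = games_howell([g1, g2])
        _, p_welch = sps.ttest_ind(g1, g2, equal_var=False)
        assert gh["p_adj"].iloc[0] == pytest.approx(p_welch, rel=1e-6)

    def test_equal_groups_all_p_near_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        gh = games_howell([base, base + 1e-9, base - 1e-9])
        assert (gh["p_adj"] > 0.999).all()

    def test_matches_hand_formula_oracle(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 8), rng.normal(1, 2, 12), rng.normal(2, 0.5, 6)]
        gh = games_howell(groups)
        orc = games_howell_oracle(groups)
        for row in gh.itertuples(index=False):
            t_o, df_o, p_o = orc[(int(row.group_a), int(row.group_b))]
            assert row.statistic == pytest.approx(t_o, rel=1e-6)
            assert row.df == pytest.approx(df_o, rel=1e-6)
            assert row.p_adj == pytest.approx(p_o, rel=1e-5, abs=1e-8)


class TestRmAnova:
    def test_two_timepoints_equals_paired_t_squared(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 2))
        res = rm_anova_gg(X)
        t, p = sps.ttest_rel(X[:, 0], X[:, 1])
        assert res.epsilon == 1.0
        assert res.F == pytest.approx(t**2, rel=1e-8)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(1)
        n, t = 200, 6
        subj = rng.normal(size=(n, 1))
        X = subj + rng.normal(size=(n, t))
        res = rm_anova_gg(X)
        assert res.epsilon > 0.95

    def test_maximally_nonspherical_epsilon_at_lower_bound(self):
        rng = np.random.default_rng(2)
        n, t = 60, 4
        load = rng.normal(size=(n, 1))
        v = np.array([1.0, -1.0, 0.5, -0.5])
        X = load * v + 1e-4 * rng.normal(size=(n, t))
        res = rm_anova_gg(X)
        assert res.epsilon == pytest.approx(1 / (t - 1), abs=0.01)

    def test_rank_deficient_covariance_warns_and_applies_gg(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 12))
        with pytest.warns(UserWarning, match="rank deficient"):
            res = rm_anova_gg(X)
        assert res.gg_applied and res.epsilon < 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError, match="3 subjects"):
            rm_anova_gg(np.ones((2, 5)))


class TestPairedT:
    def test_identical_columns_p_one_d_flagged(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 12))
        out = paired_t_bonferroni(X)
        assert len(out) == 66
        assert (out["p_adj"] == 1.0).all()
        assert out["d_undefined"].all()

    def test_single_shifted_column_makes_all_its_pairs_significant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 12))
        X[:, 5] += 50.0
        out = paired_t_bonferroni(X)
        involving = out[(out["time_a"] == 6) | (out["time_b"] == 6)]
        assert len(involving) == 11
        assert involving["significant"].all()
        assert (involving["cohen_d"].abs() > 5).all()

    def test_matches_bruteforce_loop_and_bonferroni_bound(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6)) + np.linspace(0, 1, 6)
        out = paired_t_bonferroni(X)
        m = 15
        for row in out.itertuples(index=False):
            s, u = int(row.time_a) - 1, int(row.time_b) - 1
            t, p = sps.ttest_rel(X[:, u], X[:, s])
            d = np.mean(X[:, u] - X[:, s]) / np.std(X[:, u] - X[:, s], ddof=1)
            assert row.t == pytest.approx(t, rel=1e-10)
            assert row.p_adj == pytest.approx(min(1.0, p * m), rel=1e-10)
            assert row.cohen_d == pytest.approx(d, rel=1e-10)
            assert row.p_adj >= row.p_raw

    def test_avg_sd_variant(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        out = paired_t_bonferroni(X, d_method="avg_sd")
        s, u = 0, 1
        expected = np.mean(X[:, u] - X[:, s]) / (
            (np.std(X[:, s], ddof=1) + np.std(X[:, u], ddof=1)) / 2)
        assert out["cohen_d"].iloc[0] == pytest.approx(expected)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        out = mann_whitney_bonferroni(
            {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}, [("a", "b")])
        assert out["U"].iloc[0] == 0.0

    def test_identical_samples_p_one(self):
        s = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        out = mann_whitney_bonferroni(s, [("a", "b")])
        assert out["p_adj"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(100)[: int(rng.integers(3, 7))].astype(float)
        y = np.setdiff1d(rng.permutation(100).astype(float), x)[
            : int(rng.integers(3, 7))]
        out = mann_whitney_bonferroni({"x": x, "y": y}, [("x", "y")])
        u_o, p_o = mann_whitney_exact_oracle(x, y)
        assert out["U"].iloc[0] == u_o
        assert out["p_raw"].iloc[0] == pytest.approx(p_o, abs=1e-12)

    def test_bonferroni_scales_by_family_size(self):
        s = {"a": [1.0, 2.0, 5.0], "b": [3.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
        fam = [("a", "b"), ("a", "c"), ("b", "c")]
        out = mann_whitney_bonferroni(s, fam)
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 3))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            mann_whitney_bonferroni({"a": [], "b": [1.0]}, [("a", "b")])


class TestNormalityCheck:
    def test_detects_normal_and_heavy_tails(self):
        rng = np.random.default_rng(0)
        ok = sum(normality_check(rng.normal(size=100))[1] > 0.05
                 for _ in range(1000))
        assert ok >= 900
        heavy = sum(normality_check(rng.standard_cauchy(size=500))[1] < 0.05
                    for _ in range(1000))
        assert heavy >= 900

    def test_range_and_constant_errors(self):
        with pytest.raises(ValidationError):
            normality_check(np.array([1.0, 2.0]))
        with pytest.raises(ValidationError, match="constant"):
            normality_check(np.ones(10))


def _null_panel(rng, n_per_cell=6):
    """A panel whose factors are pure labels on iid responses."""
    n = 9 * n_per_cell
    df = pd.DataFrame(rng.normal(size=(n, 12)) + np.linspace(2, 0, 12),
                      columns=BIN_COLS)
    df.insert(0, "event_year", 2022)
    df.insert(1, "team_size", np.repeat([1, 4, 10], 3 * n_per_cell))
    df.insert(2, "team_id", [f"t{k}" for k in range(n)])
    df.insert(3, "perf_level", np.tile(np.repeat([1, 2, 3], n_per_cell), 3))
    df.insert(4, "terminated_early", False)
    df.insert(5, "n_bins_imputed", 0)
    return CfrdPanel(df=df)


class TestAnalyze:
    def test_null_factors_rarely_gate_simple_effects(self):
        """Interaction stays non-significant for >= 93% of null cohorts."""
        rng = np.random.default_rng(0)
        nonsig = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                bundle = analyze(_null_panel(rng))
                nonsig += bundle.settings["interaction_p"] >= 0.05
        assert nonsig >= 93

    def test_single_cell_cohort_skips_omnibus_runs_time_effects(self):
        rng = np.random.default_rng(1)
        panel = _null_panel(rng, n_per_cell=8)
        panel.df = panel.df[(panel.df["team_size"] == 1)
                            & (panel.df["perf_level"] == 2)]
        with pytest.warns(UserWarning, match="degenerate design"):
            bundle = analyze(panel)
        assert bundle.omnibus is None and bundle.welch_size is None
        assert len(bundle.rm_time) == 1
        assert len(bundle.paired_time) == 66

    def test_full_bundle_on_synthetic_cohort(self, multiyear_panel,
                                             multiyear_cohort):
        from cfrd.pipeline import build_variation
        variation = build_variation(multiyear_cohort, panel=multiyear_panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = analyze(multiyear_panel, variation=variation)
        assert set(bundle.omnibus["effect"]) == {
            "size", "perf", "time", "size:perf", "size:time", "perf:time",
            "size:perf:time"}
        assert ((bundle.omnibus["p"] >= 0) & (bundle.omnibus["p"] <= 1)).all()
        assert len(bundle.rm_time) == 9
        assert bundle.variation_tests is not None
        assert (bundle.variation_tests["p_adj"] >= bundle.variation_tests["p_raw"]
                - 1e-12).all()

    def test_bundle_save_load_round_trip(self, tmp_path, multiyear_panel):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = analyze(multiyear_panel)
        bundle.save(tmp_path / "stats")
        loaded = StatBundle.load(tmp_path / "stats")
        pd.testing.assert_frame_equal(loaded.rm_time, bundle.rm_time)
        assert loaded.settings["alpha"] == 0.05
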