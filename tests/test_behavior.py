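"""Behavioral metrics: curves, criteria, bracketing, strategy and peripherals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbrl.behavior import (
    LearningCurve,
    TrialTableError,
    acquisition_trial,
    average_curves,
    bracket_trials,
    choice_bias,
    conditional_performance,
    curve_distance,
    exploration_radius,
    filter_aborts,
    gated_location_test,
    is_learned,
    learning_curve,
    lick_rate,
    rt_epoch_summary,
    wsls_fraction,
)
from conftest import make_session_frame


class TestFilterAborts:
    def test_late_rt_flagged_as_abort(self):
        df = make_session_frame(["correct", "correct"], rts=[2900.0, 500.0])
        clean, frac = filter_aborts(df)
        assert len(clean) == 1 and clean.iloc[0]["rt"] == 500.0

    def test_empty_table(self):
        clean, frac = filter_aborts(pd.DataFrame(columns=["outcome", "rt"]))
        assert len(clean) == 0 and frac == {}

    def test_counts_on_fixture(self):
        outcomes = ["correct"] * 60 + ["wrong"] * 34 + ["abort"] * 6
        df = make_session_frame(outcomes)
        df["condition"] = "saline"
        clean, frac = filter_aborts(df)
        assert len(clean) == 94
        assert frac["saline"] == pytest.approx(0.06)

    def test_conserves_rows(self, small_dataset):
        table, _, _ = small_dataset
        clean, frac = filter_aborts(table)
        n_removed = sum(
            frac[c] * (table["condition"] == c).sum() for c in frac)
        assert len(clean) + round(n_removed) == len(table)

    def test_malformed_rows_reported_not_dropped(self):
        df = make_session_frame(["correct", "correct"])
        df.loc[1, "outcome"] = "banana"
        with pytest.raises(TrialTableError) as err:
            filter_aborts(df)
        assert err.value.bad_rows is not None and len(err.value.bad_rows) == 1


class TestLearningCurve:
    def test_all_correct_gives_19_bins_of_100(self):
        curve = learning_curve([True] * 100)
        assert len(curve) == 19
        assert np.all(curve.percent_correct == 100.0)
        assert curve.bin_start_trials[0] == 1 and curve.bin_start_trials[-1] == 91

    def test_alternating_gives_50_everywhere(self):
        curve = learning_curve([True, False] * 50)
        assert np.all(curve.percent_correct == 50.0)

    @pytest.mark.parametrize("n,expected", [(100, 19), (10, 1), (14, 1), (15, 2)])
    def test_bin_count_formula(self, n, expected):
        curve = learning_curve([True] * n)
        assert len(curve) == (n - 10) // 5 + 1 == expected

    def test_truncates_to_first_100_trials(self):
        # 150 trials: correct up to 100, all wrong after; the tail is unused
        curve = learning_curve([True] * 100 + [False] * 50)
        assert np.all(curve.percent_correct == 100.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            learning_curve([True] * 9)


class TestAverageCurves:
    def test_identity_and_midpoint(self):
        a = learning_curve([True] * 100)
        b = learning_curve([True, False] * 50)
        avg = average_curves([a, a])
        np.testing.assert_array_equal(avg.percent_correct, a.percent_correct)
        mid = average_curves([a, b])
        assert np.all(mid.percent_correct == 75.0)

    def test_pointwise_mean_of_simulated_repetitions(self):
        rng = np.random.default_rng(0)
        seqs = [rng.random(100) < 0.7 for _ in range(3)]
        avg = average_curves([learning_curve(s) for s in seqs])
        brute = np.mean([learning_curve(s).percent_correct for s in seqs], axis=0)
        np.testing.assert_allclose(avg.percent_correct, brute)
        assert avg.n_sessions_averaged == 3

    def test_truncation_and_mixed_conventions(self):
        long = learning_curve([True] * 100)
        short = learning_curve([True] * 50)
        assert len(average_curves([long, short])) == len(short)
        other = learning_curve([True] * 100, window=20, step=10)
        with pytest.raises(ValueError):
            average_curves([long, other])


class TestCriteria:
    def test_acquisition_first_crossing(self):
        curve = LearningCurve(np.array([1, 6, 11, 16, 21]),
                              np.array([50.0, 60.0, 85.0, 95.0, 97.0]))
        assert acquisition_trial(curve) == 16

    def test_not_acquired_below_threshold(self):
        curve = LearningCurve(np.array([1, 6, 11]), np.array([50.0, 70.0, 85.0]))
        assert acquisition_trial(curve) is None

    def test_learned_requires_hold_above_80(self):
        starts = np.arange(1, 52, 5)
        dips = np.array([50, 60, 70, 80, 92, 70, 85, 90, 95, 95, 95.0])
        assert not is_learned(LearningCurve(starts, dips))
        holds = np.array([50, 60, 70, 80, 92, 85, 88, 90, 95, 95, 95.0])
        assert is_learned(LearningCurve(starts, holds))
        # exactly 80% after crossing fails the strictly-above rule
        edge = np.array([50, 60, 70, 80, 92, 80, 80, 80, 80, 95, 95.0])
        assert not is_learned(LearningCurve(starts, edge))


class TestBracketing:
    def test_monotone_crossing(self):
        starts = np.arange(1, 100, 5)
        vals = np.linspace(50, 100, len(starts))
        curve = LearningCurve(starts, vals)
        # the triplet surrounds the interpolated 90% crossing
        trip = bracket_trials(curve, 0.9)
        assert trip is not None and trip[1] == trip[0] + 1 and trip[2] == trip[0] + 2
        assert np.interp(trip[0], starts.astype(float), vals) < 90.0
        assert np.interp(trip[1], starts.astype(float), vals) >= 90.0

    def test_level_already_met_at_first_trial(self):
        curve = LearningCurve(np.array([1, 6, 11]), np.array([50.0, 60.0, 70.0]))
        assert bracket_trials(curve, 0.5) == (1, 2, 3)

    def test_unreached_level_returns_none(self):
        curve = LearningCurve(np.array([1, 6, 11]), np.array([50.0, 80.0, 92.0]))
        assert bracket_trials(curve, 1.0) is None

    def test_invalid_level_rejected(self):
        curve = LearningCurve(np.array([1, 6]), np.array([50.0, 60.0]))
        for p in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                bracket_trials(curve, p)


class TestConditionalPerformance:
    def test_identity_readouts_equal(self, clean_small_dataset):
        """With identical tables the muscimol read-out equals the saline one
        exactly at every attainable level."""
        clean, _, _ = clean_small_dataset
        sal = clean[clean["condition"] == "saline"]
        res = conditional_performance(sal, sal)
        attained = res.per_pair[res.per_pair["muscimol_pc"].notna()]
        assert len(attained) > 0
        np.testing.assert_allclose(attained["muscimol_pc"],
                                   attained["saline_pc"], atol=1e-12)

    def test_muscimol_below_saline_at_high_levels(self, clean_small_dataset):
        clean, _, _ = clean_small_dataset
        res = conditional_performance(clean[clean["condition"] == "saline"],
                                      clean[clean["condition"] == "muscimol"])
        high = res.summary[res.summary["level"] >= 0.9]
        ok = high[high["n_pairs"] > 0]
        assert (ok["muscimol_pc_mean"] < ok["saline_pc_mean"]).all()

    def test_disjoint_pairs_rejected(self, clean_small_dataset):
        clean, _, _ = clean_small_dataset
        sal = clean[clean["condition"] == "saline"]
        other = sal.copy()
        other["pair_id"] = other["pair_id"] + "_X"
        with pytest.raises(ValueError):
            conditional_performance(sal, other)

    def test_partial_overlap_warns(self, clean_small_dataset):
        clean, _, _ = clean_small_dataset
        sal = clean[clean["condition"] == "saline"]
        mus = clean[clean["condition"] == "muscimol"]
        mus = mus[mus["pair_id"] != mus["pair_id"].unique()[0]]
        with pytest.warns(UserWarning, match="excluded"):
            conditional_performance(sal, mus)


class TestStrategyMetrics:
    def test_perfect_wsls_agent(self):
        rng = np.random.default_rng(0)
        rewarded = rng.random(40) < 0.5
        chosen = [0]
        for t in range(1, 40):
            chosen.append(chosen[-1] if rewarded[t - 1] else 1 - chosen[-1])
        df = make_session_frame(
            ["correct" if r else "wrong" for r in rewarded], chosen=chosen)
        assert np.all(wsls_fraction(df).to_numpy() == 1.0)

    def test_anti_wsls_agent(self):
        rewarded = [True, False] * 20
        chosen = [0]
        for t in range(1, 40):
            chosen.append(1 - chosen[-1] if rewarded[t - 1] else chosen[-1])
        df = make_session_frame(
            ["correct" if r else "wrong" for r in rewarded], chosen=chosen)
        assert np.all(wsls_fraction(df).to_numpy() == 0.0)

    def test_always_left_agent_enumerated(self):
        # always-left: consistent exactly when the previous trial was rewarded
        rewarded = [True, False, True, True, False, False, True, False, True,
                    True, False, True, True, True, False, True, False, False,
                    True, True]
        df = make_session_frame(
            ["correct" if r else "wrong" for r in rewarded], chosen=[0] * 20)
        frac = wsls_fraction(df)
        consistent = np.array(rewarded[:-1])  # 19 consistency values -> 2 windows
        expected = [consistent[s - 1:s + 9].mean() for s in (1, 6)]
        np.testing.assert_allclose(frac.to_numpy(), expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_wsls_invariant_under_hand_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        chosen = rng.integers(0, 2, n)
        outcomes = np.where(rng.random(n) < 0.5, "correct", "wrong")
        df = make_session_frame(list(outcomes), chosen=list(chosen))
        flipped = make_session_frame(list(outcomes), chosen=list(1 - chosen))
        pd.testing.assert_series_equal(wsls_fraction(df), wsls_fraction(flipped))

    def test_choice_bias(self):
        all_left = make_session_frame(["correct"] * 10, chosen=[0] * 10)
        assert choice_bias(all_left) == 1.0
        balanced = make_session_frame(["correct"] * 10, chosen=[0, 1] * 5)
        assert choice_bias(balanced) == 0.0
        split = make_session_frame(["correct"] * 100,
                                   chosen=[0] * 60 + [1] * 40)
        assert choice_bias(split) == pytest.approx(0.2)


class TestCurveDistance:
    def test_identical_curves_zero(self):
        a = learning_curve([True] * 100)
        assert curve_distance(a, a) == 0.0

    def test_constant_offset_rectangle(self):
        a = learning_curve([True] * 100)                  # 100% everywhere
        b = learning_curve([True, False] * 50)            # 50% everywhere
        assert curve_distance(a, b) == pytest.approx(50.0)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(1)
        a = learning_curve(rng.random(100) < 0.7)
        b = learning_curve(rng.random(100) < 0.5)
        assert curve_distance(a, b) >= 0
        assert curve_distance(a, b) == pytest.approx(curve_distance(b, a))

    def test_within_pair_closer_than_cross_pair(self, clean_small_dataset):
        clean, _, _ = clean_small_dataset
        sal = clean[(clean["condition"] == "saline") & (clean["phase"] == "learning")]
        curves = {}
        for (pid, rep), sess in sal.groupby(["pair_id", "repetition_index"],
                                            observed=True):
            curves.setdefault(pid, []).append(learning_curve(sess))
        within, cross = [], []
        pids = sorted(curves)
        for pid in pids:
            cs = curves[pid]
            within += [curve_distance(cs[i], cs[j])
                       for i in range(len(cs)) for j in range(i + 1, len(cs))]
        for i in range(len(pids)):
            for j in range(i + 1, len(pids)):
                cross += [curve_distance(a, b)
                          for a in curves[pids[i]] for b in curves[pids[j]]]
        assert np.mean(within) < np.mean(cross)


class TestRtEpochs:
    def test_constant_rt_equal_means(self):
        ot = make_session_frame(["correct"] * 30, phase="overtrained")
        learn = make_session_frame(["correct"] * 100)
        df = pd.concat([ot, learn], ignore_index=True)
        out = rt_epoch_summary(df)
        assert out.loc[0, ["rt_ot", "rt_l_beg", "rt_l_end"]].tolist() == [500.0] * 3

    def test_missing_epoch_gives_nan(self):
        learn = make_session_frame(["correct"] * 30)
        out = rt_epoch_summary(learn)
        assert math.isnan(out.loc[0, "rt_ot"])
        assert not math.isnan(out.loc[0, "rt_l_beg"])

    def test_learning_shortens_rts_under_saline(self, clean_small_dataset):
        clean, _, _ = clean_small_dataset
        sal = clean[clean["condition"] == "saline"]
        out = rt_epoch_summary(sal).iloc[0]
        assert out["rt_l_end"] < out["rt_l_beg"]


class TestGatedTest:
    def test_identical_paired_samples(self):
        x = np.arange(10.0)
        out = gated_location_test(x, x, paired=True)
        assert out["statistic"] == 0.0 and out["pvalue"] == 1.0

    def test_gaussian_samples_take_t_branch(self):
        rng = np.random.default_rng(0)
        out = gated_location_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
        assert out["test"] == "two-sample t-test" and out["normal"]

    def test_heavy_tails_take_nonparametric_branch(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(60)
        y = rng.standard_cauchy(60)
        out = gated_location_test(x, y)
        assert out["test"] == "Mann-Whitney U" and not out["normal"]

    def test_paired_branches(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        out = gated_location_test(x, x + rng.normal(0, 0.5, 30), paired=True)
        assert out["test"] in ("paired t-test", "Wilcoxon signed-rank")

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            gated_location_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestLickRate:
    def test_zero_traces(self):
        assert np.all(lick_rate(np.zeros((5, 200))) == 0.0)

    def test_constant_traces_stay_constant(self):
        np.testing.assert_allclose(lick_rate(np.ones((3, 300))), 1.0)

    def test_unit_impulse_peak(self):
        trace = np.zeros((1, 801))
        trace[0, 400] = 1.0
        out = lick_rate(trace, sigma=20.0)
        assert out.max() == pytest.approx(1.0 / (20.0 * math.sqrt(2 * math.pi)),
                                          rel=1e-3)


class TestExplorationRadius:
    def test_isotropic_recovery(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 2.0, size=(100000, 2))
        out = exploration_radius(xy)
        expected = 2 * math.sqrt(2 * math.log(2)) * 2.0
        assert out.r_exp == pytest.approx(expected, rel=0.05)
        assert not out.degenerate

    def test_anisotropic_geometric_mean(self):
        rng = np.random.default_rng(1)
        xy = np.column_stack([rng.normal(0, 1.0, 100000),
                              rng.normal(0, 4.0, 100000)])
        out = exploration_radius(xy)
        expected = 2 * math.sqrt(2 * math.log(2)) * 2.0  # sqrt(1 * 4)
        assert out.r_exp == pytest.approx(expected, rel=0.10)

    def test_degenerate_point_cloud(self):
        xy = np.ones((600, 2))
        out = exploration_radius(xy)
        assert out.degenerate and out.r_exp == 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 500"):
            exploration_radius(np.random.default_rng(0).normal(size=(100, 2)))
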