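"""Evaluation-battery tests: concordance statistics, cut-point diagnostics,
odds ratios, level summaries, subgroup and diagnosis breakdowns."""

import numpy as np
import pandas as pd
import pytest

from risktree import (
    DEFAULT_DICHOTOMIES,
    MILD_PLUS,
    SEVERE_PLUS,
    ValidationError,
    c_statistic,
    confusion_at_cut,
    cutpoint_table,
    level_odds_ratios,
    level_summary,
    mean_risk_ratio,
    round_half_up,
    simulate_frame,
    subgroup_summary,
    table1_fixture,
    threshold_by_group,
)
from risktree.cohort import default_config
from risktree.pipeline import derive_algorithm
from risktree.scoring import score_frame


def pairwise_c(levels, outcome, weights=None):
    """O(n^2) pair-counting oracle over all (positive, negative) pairs."""
    levels = np.asarray(levels, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    w = np.ones(len(levels)) if weights is None else np.asarray(weights, dtype=float)
    pos, neg = levels[outcome], levels[~outcome]
    wp, wn = w[outcome], w[~outcome]
    ww = np.outer(wp, wn)
    diff = pos[:, None] - neg[None, :]
    score = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float((ww * score).sum() / ww.sum())


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([0, 0, 6, 6], [False, False, True, True]) == 1.0

    def test_independence_gives_half(self):
        levels = [0, 1, 2, 0, 1, 2]
        outcome = [True, True, True, False, False, False]
        assert c_statistic(levels, outcome) == 0.5

    def test_matches_pair_counting_on_toy(self):
        rng = np.random.default_rng(7)
        levels = rng.integers(0, 7, 12)
        outcome = rng.random(12) < 0.4
        outcome[0], outcome[1] = True, False  # both classes present
        assert c_statistic(levels, outcome) == pytest.approx(pairwise_c(levels, outcome))

    def test_weighted_matches_replication(self):
        levels = np.array([0, 2, 5])
        outcome = np.array([False, True, True])
        weights = np.array([3.0, 2.0, 1.0])
        replicated_levels = np.repeat(levels, [3, 2, 1])
        replicated_outcome = np.repeat(outcome, [3, 2, 1])
        assert c_statistic(levels, outcome, weights) == pytest.approx(
            c_statistic(replicated_levels, replicated_outcome)
        )

    def test_single_class_is_an_error(self):
        with pytest.raises(ValidationError):
            c_statistic([1, 2, 3], [True, True, True])

    def test_equals_trapezoidal_roc_area(self):
        """Pair counting with ties half equals the trapezoidal area under the
        empirical ROC traced over cut-points."""
        rng = np.random.default_rng(19)
        levels = rng.integers(0, 7, 300)
        outcome = rng.random(300) < (0.05 + 0.1 * levels / 6)
        outcome[:2] = [True, False]
        fpr, tpr = [], []
        for cut in range(8):  # cuts 0..7: from all-positive to all-negative
            m = confusion_at_cut(levels, outcome, cut)
            tpr.append(0.0 if np.isnan(m["sensitivity"]) else m["sensitivity"] / 100)
            fpr.append(0.0 if np.isnan(m["specificity"]) else 1 - m["specificity"] / 100)
        area = float(np.trapezoid(tpr[::-1], fpr[::-1]))
        assert c_statistic(levels, outcome) == pytest.approx(area, abs=1e-12)


class TestCutpoints:
    def test_perfect_classifier_all_metrics_100(self):
        frame = pd.DataFrame(
            {"level": [0] * 50 + [6] * 10, "danger": [0.0] * 50 + [4.0] * 10}
        )
        table = cutpoint_table(frame)
        assert (table[["sensitivity", "specificity", "ppv", "npv"]] == 100.0).all().all()

    def test_zero_positives_reported_missing_not_zero(self):
        metrics = confusion_at_cut([0, 1, 2], [False, False, False], cut=2)
        assert np.isnan(metrics["sensitivity"])
        assert not np.isnan(metrics["specificity"])

    def test_monotone_in_cut(self):
        frame = table1_fixture()
        table = cutpoint_table(frame)
        for name in [d.name for d in DEFAULT_DICHOTOMIES]:
            block = table[table["outcome"] == name].sort_values("cut")
            assert block["sensitivity"].is_monotonic_decreasing
            assert block["specificity"].is_monotonic_increasing

    def test_confusion_identities(self):
        """sens*prev + (1-spec)*(1-prev) = P(level >= c), and PPV/NPV follow
        from Bayes' rule, at every cut on the weighted fixture."""
        frame = table1_fixture()
        w = frame["weight"].to_numpy()
        levels = frame["level"].to_numpy()
        outcome = frame["severe"].to_numpy()
        prev = w[outcome].sum() / w.sum()
        for cut in range(1, 5):
            m = confusion_at_cut(levels, outcome, cut, w)
            sens, spec = m["sensitivity"] / 100, m["specificity"] / 100
            p_flag = w[levels >= cut].sum() / w.sum()
            assert sens * prev + (1 - spec) * (1 - prev) == pytest.approx(p_flag)
            assert m["ppv"] / 100 == pytest.approx(sens * prev / p_flag)
            assert m["npv"] / 100 == pytest.approx(
                spec * (1 - prev) / (1 - p_flag)
            )


class TestOddsRatios:
    def test_identical_rates_give_unit_odds_ratio(self):
        frame = pd.DataFrame(
            {
                "level": [0] * 100 + [3] * 100,
                "danger": ([4.0] * 10 + [0.0] * 90) * 2,
            }
        )
        ors = level_odds_ratios(frame, SEVERE_PLUS, method="crude_2x2").set_index("level")
        assert ors.loc[3, "odds_ratio"] == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # level 3: a=10 severe, b=90 not; level 0: c=1 severe, d=99 not
        frame = pd.DataFrame(
            {
                "level": [3] * 100 + [0] * 100,
                "danger": [4.0] * 10 + [0.0] * 90 + [4.0] * 1 + [0.0] * 99,
            }
        )
        ors = level_odds_ratios(frame, SEVERE_PLUS, method="crude_2x2").set_index("level")
        assert ors.loc[3, "odds_ratio"] == pytest.approx(11.0)

    def test_ci_contains_point_and_symmetric_on_log_scale(self):
        frame = pd.DataFrame(
            {
                "level": [3] * 100 + [0] * 100,
                "danger": [4.0] * 10 + [0.0] * 90 + [4.0] * 1 + [0.0] * 99,
            }
        )
        row = level_odds_ratios(frame, SEVERE_PLUS, method="crude_2x2").set_index("level").loc[3]
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]
        log_or = np.log(row["odds_ratio"])
        assert log_or - np.log(row["ci_low"]) == pytest.approx(
            np.log(row["ci_high"]) - log_or
        )

    def test_zero_cell_haldane_correction_flagged(self):
        frame = pd.DataFrame(
            {
                "level": [3] * 50 + [0] * 50,
                "danger": [4.0] * 5 + [0.0] * 45 + [0.0] * 50,
            }
        )
        row = level_odds_ratios(frame, SEVERE_PLUS, method="crude_2x2").set_index("level").loc[3]
        assert row["zero_cell_corrected"]
        assert np.isfinite(row["odds_ratio"])

    def test_cumulative_logit_record_order_invariant(self):
        rng = np.random.default_rng(3)
        n = 600
        level = rng.integers(0, 3, n)
        danger = np.clip(level + rng.integers(-1, 3, n), 0, 4)
        frame = pd.DataFrame({"level": level, "danger": danger.astype(float)})
        a = level_odds_ratios(frame, method="cumulative_logit")
        b = level_odds_ratios(
            frame.sample(frac=1.0, random_state=9).reset_index(drop=True),
            method="cumulative_logit",
        )
        assert np.allclose(a["odds_ratio"][1:], b["odds_ratio"][1:], rtol=1e-4)
        # higher levels carry higher odds of a worse rating
        assert a.set_index("level")["odds_ratio"][2] > a.set_index("level")["odds_ratio"][1] > 1

    def test_cumulative_logit_rejects_fractional_weights(self):
        frame = table1_fixture()
        with pytest.raises(ValidationError):
            level_odds_ratios(frame, method="cumulative_logit")


class TestLevelSummary:
    def test_hand_tallied_toy(self):
        frame = pd.DataFrame(
            {
                "level": [0] * 10 + [1] * 6 + [2] * 4,
                "danger": [0.0] * 9 + [3.0] + [1.0] * 6 + [3.0, 3.0, 4.0, 0.0],
            }
        )
        summary = level_summary(frame)
        t = summary.table
        assert t.loc[0, "pct_of_sample"] == pytest.approx(50.0)
        assert t.loc[1, "pct_of_sample"] == pytest.approx(30.0)
        assert t.loc[2, "pct_of_sample"] == pytest.approx(20.0)
        assert t.loc[0, "mean_risk"] == pytest.approx(0.3)
        assert t.loc[2, "pct_positive"] == pytest.approx(75.0)

    def test_single_level_cohort(self):
        frame = pd.DataFrame({"level": [2] * 5, "danger": [0.0, 1, 2, 3, 4]})
        with pytest.warns(UserWarning):  # levels 0,1 empty
            summary = level_summary(frame)
        assert summary.table.loc[2, "pct_of_sample"] == pytest.approx(100.0)

    def test_fixture_reproduces_printed_level_shares_and_means(self):
        summary = level_summary(table1_fixture())
        t = summary.formatted()
        # renormalization shifts printed shares by at most 0.1 of a point
        printed = [46.3, 12.8, 14.2, 13.7, 6.6, 5.7, 0.8]
        assert np.allclose(t["pct_of_sample"], printed, atol=0.1)
        assert t["mean_risk"].tolist() == [0.08, 0.30, 0.62, 0.85, 1.44, 1.74, 2.28]
        assert t["pct_positive"].tolist() == [0.1, 1.1, 1.5, 3.3, 9.5, 19.5, 42.6]

    def test_mean_risk_ratio_rounds_to_29(self):
        summary = level_summary(table1_fixture())
        ratio = mean_risk_ratio(summary)
        assert ratio == pytest.approx(28.5)
        assert round_half_up(ratio) == 29

    def test_mean_risk_monotone_on_derivation_cohort(self):
        cfg = default_config(20_000, seed=51)
        sim = simulate_frame(cfg)
        algo = derive_algorithm(sim.frame, cfg.dictionary, dss=cfg.dss)
        frame = sim.frame.assign(level=score_frame(sim.frame, algo))
        summary = level_summary(frame)
        means = summary.table["mean_risk"].to_numpy()
        assert np.all(np.diff(means) > 0)
        assert summary.table["pct_of_sample"].sum() == pytest.approx(100.0)


class TestSubgroups:
    @staticmethod
    def _scored_frame(n=20_000, seed=61, **cfg_kw):
        cfg = default_config(n, seed=seed, **cfg_kw)
        sim = simulate_frame(cfg)
        algo = derive_algorithm(sim.frame, cfg.dictionary, dss=cfg.dss)
        return sim.frame.assign(level=score_frame(sim.frame, algo))

    def test_single_stratum_equals_pooled(self):
        frame = self._scored_frame(5000, seed=62)
        males = frame[frame["sex"] == "male"]
        with pytest.warns(UserWarning):  # the female stratum is absent
            sub = subgroup_summary(males, by="sex")
        assert set(sub) == {"male"}
        pooled = level_summary(males)
        pd.testing.assert_frame_equal(sub["male"].table, pooled.table)

    def test_stratum_shares_reconstitute_pooled_table(self):
        from risktree.evaluation import age_band

        frame = self._scored_frame(10_000, seed=63)
        sub = subgroup_summary(frame, by="age_band")
        pooled = level_summary(frame)
        bands = np.array([age_band(a) for a in frame["age_years"]])
        band_frac = {b: float((bands == b).mean()) for b in sub}
        for level in pooled.table.index:
            recon = sum(
                float(np.nan_to_num(s.table.loc[level, "pct_of_sample"]))
                * band_frac[band]
                if level in s.table.index
                else 0.0
                for band, s in sub.items()
            )
            assert recon == pytest.approx(
                pooled.table.loc[level, "pct_of_sample"], abs=1e-9
            )

    def test_age_trend_orders_high_level_occupancy(self):
        """With planted risk-marker prevalence rising in age, 2+ occupancy is
        ordered child < middle < adolescent."""
        frame = self._scored_frame(30_000, seed=64, age_item_slope=0.25)
        shares = {}
        for band, s in subgroup_summary(frame, by="age_band").items():
            t = s.table
            shares[band] = t.loc[t.index >= 2, "pct_of_sample"].sum()
        assert shares["<=7"] < shares["8-11"] < shares[">=12"]


class TestThresholdByGroup:
    def test_hand_counted_proportion(self):
        frame = pd.DataFrame(
            {
                "level": [1, 2, 3, 4, 0, 0, 2, 5, 1, 0],
                "flagged": [True, True, True, True, False, False, False, False, False, False],
            }
        )
        # 4 flagged, 3 of them at level >= 2  -> 75% at 2+
        out = threshold_by_group(frame, ["flagged"]).set_index("group")
        assert out.loc["flagged", "pct_2_plus"] == pytest.approx(75.0)

    def test_all_top_level_group_hits_both_thresholds(self):
        frame = pd.DataFrame({"level": [6, 6, 6], "dx": [True] * 3})
        out = threshold_by_group(frame, ["dx"]).set_index("group")
        assert out.loc["dx", "pct_2_plus"] == 100.0
        assert out.loc["dx", "pct_3_plus"] == 100.0

    def test_monotone_thresholds_and_empty_group(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "level": rng.integers(0, 7, 200),
                "dx_a": rng.random(200) < 0.3,
                "dx_empty": [False] * 200,
            }
        )
        out = threshold_by_group(frame, ["dx_a", "dx_empty"]).set_index("group")
        assert out.loc["dx_a", "pct_3_plus"] <= out.loc["dx_a", "pct_2_plus"]
        assert np.isnan(out.loc["dx_empty", "pct_2_plus"])


class TestMildOutcome:
    def test_dichotomy_switch_uses_danger_column(self):
        frame = pd.DataFrame(
            {"level": [0, 0, 5, 5], "danger": [0.0, 1.0, 2.0, 4.0]}
        )
        summary = level_summary(frame, MILD_PLUS)
        assert summary.table.loc[0, "pct_positive"] == pytest.approx(50.0)
        assert summary.table.loc[5, "pct_positive"] == pytest.approx(100.0)
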