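"""Trajectory statistics: paired tests, slopes, inverse preference, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from primetrack.trajectory import (
    change_score_correlation,
    group_timepoint_contrasts,
    inverse_preference_by_group,
    inverse_preference_regression,
    participant_slopes,
    surprisal_drops,
    timepoint_comparisons,
)


def make_scored(rows):
    """rows: (participant, group, timepoint, surprisal, correct)."""
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "timepoint", "surprisal_mean",
                       "correct"]
    )


def trials(participant, group, values_by_tp, accuracy_by_tp=None):
    rows = []
    for tp, values in values_by_tp.items():
        acc = (accuracy_by_tp or {}).get(tp, 1)
        rows.extend((participant, group, tp, v, acc) for v in values)
    return rows


class TestTimepointComparisons:
    def test_identical_sessions_are_degenerate_with_p_one(self):
        rows = []
        for i in range(4):
            rows += trials(f"p{i}", "PWA", {"pre": [5.0], "post1": [5.0], "post2": [5.0]})
        comps = timepoint_comparisons(make_scored(rows), "PWA")
        assert all(c.degenerate and c.p_adjusted == 1.0 for c in comps)

    def test_matches_exact_signed_rank_null_on_four_pairs(self):
        # participant means pre (10,9,8,7) vs post1 (8,7.5,5,6): all four
        # differences positive and distinct, W- = 0, exact two-sided
        # p = 2/16 = 0.125
        rows = []
        for i, (a, b) in enumerate(zip((10, 9, 8, 7), (8, 7.5, 5, 6))):
            rows += trials(f"p{i}", "PWA",
                           {"pre": [a], "post1": [b], "post2": [b]})
        comps = {c.pair: c for c in timepoint_comparisons(make_scored(rows), "PWA")}
        c = comps[("pre", "post1")]
        assert c.statistic == 0.0
        assert c.p_raw == pytest.approx(0.125)
        assert c.p_adjusted == pytest.approx(min(1.0, 3 * 0.125))

    def test_bonferroni_family_of_three(self):
        # raw p of 0.125 in the fixture above adjusts to 0.375; the formula
        # min(1, 3p) is asserted there. Here: adjustment saturates at 1.
        rows = []
        rng = np.random.default_rng(0)
        for i in range(8):
            vals = rng.normal(5, 1, size=3)
            rows += trials(f"p{i}", "AEM",
                           {"pre": [vals[0]], "post1": [vals[1]], "post2": [vals[2]]})
        comps = timepoint_comparisons(make_scored(rows), "AEM")
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_too_few_participants_is_error(self):
        rows = trials("p0", "PWA", {"pre": [1.0], "post1": [2.0], "post2": [3.0]})
        with pytest.raises(ValueError):
            timepoint_comparisons(make_scored(rows), "PWA")


class TestParticipantSlopes:
    def test_binary_predictor_slope_equals_mean_difference(self):
        rows = trials("p0", "PWA", {"pre": [10.0, 10.0], "post1": [8.0, 8.0]})
        slopes = participant_slopes(make_scored(rows), ("pre", "post1"))
        assert slopes["p0"] == pytest.approx(-2.0)

    def test_constant_surprisal_gives_zero_slope(self):
        rows = trials("p0", "PWA", {"pre": [3.0, 3.0], "post1": [3.0, 3.0, 3.0]})
        slopes = participant_slopes(make_scored(rows), ("pre", "post1"))
        assert slopes["p0"] == pytest.approx(0.0)

    def test_unbalanced_counts_match_normal_equations(self):
        pre, post = [4.0, 6.0, 5.0], [3.0, 2.0]
        rows = trials("p0", "PWA", {"pre": pre, "post1": post})
        slopes = participant_slopes(make_scored(rows), ("pre", "post1"))
        x = np.array([0, 0, 0, 1, 1], dtype=float)
        y = np.array(pre + post)
        beta = sm.OLS(y, sm.add_constant(x)).fit().params[1]  # independent fit
        assert slopes["p0"] == pytest.approx(beta)
        assert slopes["p0"] == pytest.approx(np.mean(post) - np.mean(pre))

    def test_missing_session_excluded(self):
        rows = trials("p0", "PWA", {"pre": [1.0]}) + trials(
            "p1", "PWA", {"pre": [1.0], "post1": [0.5]}
        )
        slopes = participant_slopes(make_scored(rows), ("pre", "post1"))
        assert set(slopes) == {"p1"}


class TestInversePreferenceRegression:
    def test_exact_linear_relation_recovered(self):
        pre = {f"p{i}": float(i) for i in range(1, 9)}
        drop = {p: 0.5 * v for p, v in pre.items()}
        res = inverse_preference_regression(pre, drop)
        assert res.coefficient == pytest.approx(0.5, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_slope_within_three_standard_errors(self, rng):
        pre = {f"p{i}": float(v) for i, v in enumerate(rng.normal(5, 1, 200))}
        drop = {f"p{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 200))}
        res = inverse_preference_regression(pre, drop)
        assert abs(res.coefficient) < 3 * res.std_error

    def test_zero_variance_predictor_is_error(self):
        pre = {"a": 1.0, "b": 1.0, "c": 1.0}
        drop = {"a": 0.1, "b": 0.2, "c": 0.3}
        with pytest.raises(ValueError):
            inverse_preference_regression(pre, drop)

    def test_nominal_type_one_error_under_the_null(self):
        """Rejection rate 0.05 +/- 0.02 over 1,000 seeded null replicates
        (independent pre-test predictor and drop, n = 24 participants)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        for _ in range(1000):
            pre = {f"p{i}": float(v) for i, v in enumerate(rng.normal(3, 0.5, 24))}
            drop = {f"p{i}": float(v) for i, v in enumerate(rng.normal(0.2, 0.3, 24))}
            rejections += inverse_preference_regression(pre, drop).p_value < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_positive_coupling_detected_on_synthetic_cohort(self, scored_large):
        regs = {r.label: r for r in inverse_preference_by_group(scored_large)}
        res = regs["PWA:pre-post1"]
        assert res.coefficient > 0
        assert res.p_value < 0.05


class TestGroupTimepointContrasts:
    def test_identical_groups_give_zero_estimates(self):
        rows = []
        for g, prefix in (("PWA", "p"), ("AEM", "a")):
            for i in range(3):
                rows += trials(f"{prefix}{i}", g,
                               {"pre": [2.0], "post1": [2.0], "post2": [2.0]})
        for c in group_timepoint_contrasts(make_scored(rows)):
            assert c.estimate == pytest.approx(0.0)

    def test_constant_shift_recovered_exactly(self):
        # AEM = PWA - 1 everywhere, balanced: two-stage means give -1
        rows = []
        for i in range(3):
            base = 2.0 + i
            rows += trials(f"p{i}", "PWA",
                           {"pre": [base], "post1": [base], "post2": [base]})
            rows += trials(f"a{i}", "AEM",
                           {"pre": [base - 1], "post1": [base - 1], "post2": [base - 1]})
        for c in group_timepoint_contrasts(make_scored(rows)):
            assert c.estimate == pytest.approx(-1.0)

    def test_sign_antisymmetric_under_group_swap(self, scored_default):
        swapped = scored_default.copy()
        swapped["group"] = swapped["group"].map({"PWA": "AEM", "AEM": "PWA"})
        for c, cs in zip(
            group_timepoint_contrasts(scored_default), group_timepoint_contrasts(swapped)
        ):
            assert cs.estimate == pytest.approx(-c.estimate)
            assert cs.p_value == pytest.approx(c.p_value)

    def test_severity_penalty_makes_all_contrasts_negative(self, scored_large):
        contrasts = group_timepoint_contrasts(scored_large)
        assert len(contrasts) == 3
        assert all(c.estimate < 0 for c in contrasts)


class TestChangeScoreCorrelation:
    @staticmethod
    def _df_from_points(points):
        # points: participant -> (surp_pre, surp_post1, surp_post2,
        #                         acc_pre, acc_post1, acc_post2)
        rows = []
        for pid, (s0, s1, s2, a0, a1, a2) in points.items():
            rows += trials(pid, "PWA",
                           {"pre": [s0], "post1": [s1], "post2": [s2]},
                           {"pre": a0, "post1": a1, "post2": a2})
        return make_scored(rows)

    def test_gain_proportional_to_reduction_gives_r_one(self):
        points = {
            f"p{i}": (5.0 + i, 5.0 + i - d, 5.0 + i - d, 0.2, 0.2 + 0.1 * d,
                      0.2 + 0.1 * d)
            for i, d in enumerate((1.0, 2.0, 3.0, 4.0))
        }
        out = change_score_correlation(self._df_from_points(points))
        assert out["pre->post1"]["r"] == pytest.approx(1.0)

    def test_matches_textbook_formula_on_five_participants(self):
        reductions = [1.0, 2.0, 3.0, 4.0, 5.0]
        gains = [0.10, 0.30, 0.20, 0.50, 0.40]
        points = {
            f"p{i}": (6.0, 6.0 - red, 6.0 - red, 0.1, 0.1 + g, 0.1 + g)
            for i, (red, g) in enumerate(zip(reductions, gains))
        }
        out = change_score_correlation(self._df_from_points(points))
        x, y = np.array(reductions), np.array(gains)
        xc, yc = x - x.mean(), y - y.mean()
        r_manual = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert out["pre->post1"]["r"] == pytest.approx(r_manual, abs=1e-12)

    def test_independent_scores_stay_in_null_band(self, rng):
        points = {
            f"p{i}": tuple(rng.normal(3, 0.5, 3)) + tuple(rng.uniform(0, 1, 3))
            for i in range(200)
        }
        out = change_score_correlation(self._df_from_points(points))
        # null sampling band for r at n=200: |r| < ~3/sqrt(n)
        assert abs(out["pre->post1"]["r"]) < 3 / math.sqrt(200)

    def test_cohort_reduction_tracks_accuracy_gain(self, scored_large):
        out = change_score_correlation(scored_large, "PWA")
        assert out["pre->post1"]["r"] > 0
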