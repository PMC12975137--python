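"""Tests for the evaluation battery: ROC/AUC, operating points, risk
stratification, correlation structure and the sport comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wase.validate import (
    auc_mannwhitney,
    factor_correlation_analysis,
    operating_point,
    risk_stratification_summary,
    roc_analysis,
    sport_comparison,
)


def brute_force_auc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_pair_counting_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert auc_mannwhitney(scores, labels) == pytest.approx(0.75)
        assert brute_force_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert auc_mannwhitney(scores, labels) == 1.0

    def test_null_concordance(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert auc_mannwhitney(scores, labels) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 400))
        scores = rng.choice(np.linspace(0, 2, 25), size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc_mannwhitney(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([0.1, 0.2], [1, 1])

    def test_ci_brackets_auc_and_curve_monotone(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 400)
        scores = labels + rng.normal(0, 0.8, 400)
        res = roc_analysis(scores, labels, n_boot=200, seed=0)
        assert res.ci_low <= res.auc <= res.ci_high
        assert (np.diff(res.tpr) >= 0).all() and (np.diff(res.fpr) >= 0).all()

    def test_delong_matches_bootstrap_roughly(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 500)
        scores = labels + rng.normal(0, 1.0, 500)
        boot = roc_analysis(scores, labels, n_boot=500, seed=0)
        dl = roc_analysis(scores, labels, method="delong")
        assert dl.auc == pytest.approx(boot.auc, abs=1e-12)
        assert dl.ci_low == pytest.approx(boot.ci_low, abs=0.03)
        assert dl.ci_high == pytest.approx(boot.ci_high, abs=0.03)


class TestOperatingPoint:
    def test_two_by_two_arithmetic(self):
        # TP=3, FN=1, TN=4, FP=2 at cutoff 0.5
        scores = [0.6, 0.7, 0.9, 0.4,   0.1, 0.2, 0.3, 0.45, 0.8, 0.55]
        labels = [1, 1, 1, 1,   0, 0, 0, 0, 0, 0]
        op = operating_point(scores, labels, 0.5)
        assert (op.tp, op.fn, op.tn, op.fp) == (3, 1, 4, 2)
        assert op.sensitivity_pct == pytest.approx(75.0)
        assert op.specificity_pct == pytest.approx(200 / 3)
        assert op.ppv_pct == pytest.approx(60.0)
        assert op.npv_pct == pytest.approx(80.0)
        assert op.sensitivity_ci[0] < 75.0 < op.sensitivity_ci[1]

    def test_cutoff_below_min_all_positive(self):
        op = operating_point([0.5, 0.9], [1, 0], 0.1)
        assert op.sensitivity_pct == 100.0
        assert op.specificity_pct == 0.0

    def test_cutoff_above_max_all_negative(self):
        op = operating_point([0.5, 0.9], [1, 0], 1.5)
        assert op.sensitivity_pct == 0.0
        assert op.specificity_pct == 100.0

    def test_undefined_cells_not_available(self):
        op = operating_point([0.5, 0.9], [1, 1], 0.7)   # no negatives
        assert math.isnan(op.specificity_pct)
        op2 = operating_point([0.1, 0.2], [1, 0], 0.9)  # no predicted positives
        assert math.isnan(op2.ppv_pct)

    def test_consistent_with_roc_curve(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 300)
        scores = labels + rng.normal(0, 1, 300)
        res = roc_analysis(scores, labels, n_boot=0)
        cutoff = 0.75
        op = operating_point(scores, labels, cutoff)
        # roc_curve thresholds predict positive iff score >= threshold
        idx = np.argmin(np.abs(res.thresholds - cutoff))
        # find exact matching threshold by recomputation instead
        tpr = np.sum((scores >= cutoff) & (labels == 1)) / np.sum(labels == 1)
        fpr = np.sum((scores >= cutoff) & (labels == 0)) / np.sum(labels == 0)
        assert op.sensitivity_pct == pytest.approx(100 * tpr)
        assert op.specificity_pct == pytest.approx(100 * (1 - fpr))


class TestRiskStratification:
    def test_all_low(self):
        s = risk_stratification_summary(np.full(10, 0.1))
        assert s["proportions_pct"]["low"] == 100.0

    def test_hand_counted_bands(self):
        s = risk_stratification_summary(np.array([0.2, 0.6, 0.6, 0.9, 1.5]))
        p = s["proportions_pct"]
        assert (p["low"], p["moderate"], p["high"], p["critical"]) == \
            (20.0, 40.0, 20.0, 20.0)
        assert s["median"] == 0.6

    def test_proportions_sum_to_100(self, low_intensity_cohort):
        p = risk_stratification_summary(low_intensity_cohort.scores)["proportions_pct"]
        assert sum(p.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            risk_stratification_summary(np.array([]))


class TestFactorCorrelations:
    def _frame(self, x, y):
        n = len(x)
        return pd.DataFrame({"E_pct": x, "dI_ms": y, "wase_score": y})

    def test_self_correlation_and_sign_flip(self):
        x = np.array([1.0, 2, 3, 4, 5])
        out = factor_correlation_analysis(self._frame(x, -x))
        assert out["r"].loc["E_pct", "E_pct"] == 1.0
        assert out["r"].loc["E_pct", "dI_ms"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # devs x=(-2,-1,0,1,2), y=(-1,-2,1,0,2): r = 8/sqrt(10*10) = 0.8
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        out = factor_correlation_analysis(self._frame(x, y))
        assert out["r"].loc["E_pct", "dI_ms"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_column_not_available(self):
        x = np.array([1.0, 2, 3, 4, 5])
        out = factor_correlation_analysis(self._frame(x, np.full(5, 2.0)))
        assert math.isnan(out["r"].loc["E_pct", "dI_ms"])

    def test_sign_pattern_on_simulated_cohort(self, low_intensity_cohort):
        out = factor_correlation_analysis(low_intensity_cohort.frame)
        r = out["r"]["wase_score"]
        for col in ("E_pct", "dI_ms", "phi", "e_env", "T"):
            assert r[col] > 0, f"{col} should load positively"
        for col in ("C_pct", "S_hours"):
            assert r[col] < 0, f"{col} should be protective"

    def test_vif_reported(self, low_intensity_cohort):
        out = factor_correlation_analysis(low_intensity_cohort.frame)
        assert all(v >= 1.0 or math.isnan(v) for v in out["vif"].values())


def _toy_sport_frame(groups):
    rows = []
    aid = 0
    for sport, values in groups.items():
        for v in values:
            rows.append({"athlete_id": aid, "sport": sport,
                         "timestamp_ms": 0, "wase_score": v})
            aid += 1
    return pd.DataFrame(rows)


class TestSportComparison:
    def test_identical_groups_give_zero_f(self):
        frame = _toy_sport_frame({s: [1.0, 1.0, 1.0] for s in
                                  ("running", "cycling", "swimming", "team")})
        res = sport_comparison(frame, aggregation="none")
        assert res.f_stat == 0.0 and res.eta2 == 0.0

    def test_hand_worked_anova(self):
        # SSB=42, SSW=6, df=(2,6): F=21, eta2=0.875
        frame = _toy_sport_frame({"running": [1, 2, 3], "cycling": [2, 3, 4],
                                  "swimming": [6, 7, 8]})
        res = sport_comparison(frame, aggregation="none")
        assert res.f_stat == pytest.approx(21.0, abs=1e-10)
        assert res.eta2 == pytest.approx(0.875, abs=1e-10)
        assert res.df == (2, 6)

    def test_eta2_identity_on_random_data(self):
        rng = np.random.default_rng(4)
        groups = {s: rng.normal(i, 1, 12).tolist()
                  for i, s in enumerate(("running", "cycling", "swimming", "team"))}
        frame = _toy_sport_frame(groups)
        res = sport_comparison(frame, aggregation="none")
        values = [np.asarray(v) for v in groups.values()]
        allv = np.concatenate(values)
        ssb = sum(len(v) * (v.mean() - allv.mean()) ** 2 for v in values)
        sst = ((allv - allv.mean()) ** 2).sum()
        assert res.eta2 == pytest.approx(ssb / sst, abs=1e-10)
        assert 0.0 <= res.eta2 <= 1.0
        assert res.eta2_ci[0] <= res.eta2 <= res.eta2_ci[1] + 1e-9

    def test_bonferroni_never_below_unadjusted(self):
        rng = np.random.default_rng(5)
        frame = _toy_sport_frame({s: rng.normal(0, 1, 10).tolist()
                                  for s in ("running", "cycling", "swimming", "team")})
        res = sport_comparison(frame, aggregation="none")
        assert (res.bonferroni["p_bonferroni"]
                >= res.bonferroni["p_unadjusted"] - 1e-15).all()
        assert (res.bonferroni["p_bonferroni"] <= 1.0).all()

    def test_aggregation_unit_count(self, low_intensity_cohort):
        res = sport_comparison(low_intensity_cohort.frame, block_s=15.0)
        ds = low_intensity_cohort
        n_blocks = math.ceil(ds.config.duration_s / 3600 * 3600 / 15)
        # 8 athletes x blocks spanned by the session grid
        frame = ds.frame
        expected = frame.assign(b=(frame["timestamp_ms"] / 1000 // 15)) \
                        .groupby(["athlete_id", "b"]).ngroups
        assert res.n_units == expected
        assert res.diagnostics["levene_p"] >= 0.0

    def test_fewer_than_two_groups_rejected(self):
        frame = _toy_sport_frame({"running": [1, 2, 3]})
        with pytest.raises(ValueError):
            sport_comparison(frame, aggregation="none")
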