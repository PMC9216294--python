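"""Metric battery: AUC, FPR-anchored threshold, F-beta/MCC, bins, CI, summary."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventwatch.cohort import PatientStay
from ventwatch.evaluate import (
    CIResult,
    ConfusionMatrix,
    EvaluationConfig,
    cohort_summary,
    confusion,
    evaluate_predictions,
    f_beta,
    mcc,
    percent,
    pr_curve,
    precision_by_bin,
    roc_auc,
    sensitivity_auc_ci,
    threshold_at_fpr,
)
from ventwatch.model import SingleClassError

from conftest import pairwise_auc


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_chance_level(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        p = rng.uniform(size=10_000)
        assert abs(roc_auc(y, p) - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_equals_pairwise_oracle_including_ties(self):
        rng = np.random.default_rng(1)
        for n in (20, 57, 200):
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            p = rng.choice(np.linspace(0, 1, 7), size=n)  # heavy ties
            assert roc_auc(y, p) == pytest.approx(pairwise_auc(y, p), abs=1e-12)


class TestThreshold:
    def test_separable_case_achieves_zero_fpr(self):
        # with 4 negatives no negative score satisfies FPR <= 0.2, so mu
        # lands on the smallest positive score and FPR 0 is achieved
        y = [0] * 4 + [1] * 5
        p = [0.1, 0.2, 0.3, 0.4] + list(np.linspace(0.6, 1.0, 5))
        mu, fpr = threshold_at_fpr(y, p, 0.2)
        assert fpr == 0.0
        assert mu == 0.6

    def test_mu_is_smallest_score_meeting_target(self):
        y = [0] * 10 + [1] * 5
        p = list(np.linspace(0.0, 0.4, 10)) + list(np.linspace(0.6, 1.0, 5))
        mu, fpr = threshold_at_fpr(y, p, 0.2)
        # exactly two of ten negatives sit at or above mu
        assert fpr == pytest.approx(0.2)
        assert mu == pytest.approx(np.linspace(0.0, 0.4, 10)[8])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.9))
    def test_achieved_fpr_never_exceeds_target(self, seed, target):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        p = rng.uniform(size=60).round(2)
        mu, fpr = threshold_at_fpr(y, p, target)
        assert fpr <= target
        neg = p[np.asarray(y) == 0]
        assert (neg >= mu).mean() == pytest.approx(fpr)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.uniform(size=50).round(2)
        mu, _ = threshold_at_fpr(y, p, 0.2)
        neg = p[y == 0]
        feasible = [c for c in sorted(set(p)) if (neg >= c).mean() <= 0.2]
        assert mu == min(feasible)


class TestConfusion:
    def test_mu_zero_predicts_everything_positive(self):
        cm = confusion([0, 1, 1], [0.2, 0.5, 0.9], 0.0)
        assert cm.fn == 0 and cm.tn == 0
        assert cm.tp == 2 and cm.fp == 1

    def test_mu_above_one_predicts_everything_negative(self):
        cm = confusion([0, 1, 1], [0.2, 0.5, 0.9], 1.01)
        assert cm.tp == 0 and cm.fp == 0
        assert cm.fn == 2 and cm.tn == 1

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30)
        p = rng.uniform(size=30)
        mu = 0.4
        cm = confusion(y, p, mu)
        tp = sum(1 for yi, pi in zip(y, p) if pi >= mu and yi == 1)
        fp = sum(1 for yi, pi in zip(y, p) if pi >= mu and yi == 0)
        fn = sum(1 for yi, pi in zip(y, p) if pi < mu and yi == 1)
        tn = sum(1 for yi, pi in zip(y, p) if pi < mu and yi == 0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        assert cm.tp + cm.fn == int(y.sum())


class TestFBetaMcc:
    def test_perfect_prediction(self):
        cm = ConfusionMatrix(tp=10, fp=0, tn=10, fn=0, threshold=0.5)
        assert f_beta(cm, 0.5) == 1.0
        assert f_beta(cm, 2.0) == 1.0
        assert mcc(cm) == 1.0

    def test_inverted_prediction(self):
        cm = ConfusionMatrix(tp=0, fp=10, tn=0, fn=10, threshold=0.5)
        assert mcc(cm) == -1.0
        assert f_beta(cm, 0.5) == 0.0

    def test_harmonic_mean_case(self):
        # P = R = 0.5 with beta = 1
        cm = ConfusionMatrix(tp=5, fp=5, tn=5, fn=5, threshold=0.5)
        assert f_beta(cm, 1.0) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 50)] * 4), st.floats(0.1, 3.0))
    def test_closed_forms_on_random_confusion_matrices(self, counts, beta):
        tp, fp, tn, fn = counts
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, threshold=0.5)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        expect_f = (
            (1 + beta**2) * p * r / (beta**2 * p + r) if (p or r) and (beta**2 * p + r) else 0.0
        )
        assert f_beta(cm, beta) == pytest.approx(expect_f)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        expect_m = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
        assert mcc(cm) == pytest.approx(expect_m)


class TestPrCurve:
    def test_separable_scores_precision_one_at_every_recall(self):
        out = pr_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        # at every achieved recall some threshold delivers precision 1
        assert (out.groupby("recall")["precision"].max() == 1.0).all()

    def test_all_scores_equal_single_point(self):
        out = pr_curve([0, 1, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert len(out) == 1
        assert out.iloc[0]["recall"] == 1.0
        assert out.iloc[0]["precision"] == 0.5  # prevalence

    def test_matches_threshold_scan(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        p = rng.uniform(size=20).round(1)
        out = pr_curve(y, p)
        for _, row in out.iterrows():
            c = row["threshold"]
            pred = p >= c
            assert row["precision"] == pytest.approx(y[pred].mean())
            assert row["recall"] == pytest.approx(y[pred].sum() / y.sum())


class TestPrecisionByBin:
    def test_single_bin_equals_overall_precision(self):
        y = [0, 1, 1, 0, 1]
        p = [0.91, 0.93, 0.95, 0.97, 0.99]
        out = precision_by_bin(y, p, 0.9)
        filled = out.dropna(subset=["precision"])
        assert len(filled) == 1
        assert filled.iloc[0]["precision"] == pytest.approx(3 / 5)

    def test_aggregation_identity_on_random_data(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 500)
        p = rng.uniform(size=500)
        mu = 0.17
        out = precision_by_bin(y, p, mu)
        above = p >= mu
        overall = y[above].mean()
        weighted = (out["precision"].fillna(0) * out["count"]).sum() / out["count"].sum()
        assert weighted == pytest.approx(overall)
        assert out["count"].sum() == int(above.sum())

    def test_calibrated_scores_give_monotone_bin_precision(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50_000)
        y = (rng.uniform(size=50_000) < p).astype(int)  # probability = true risk
        out = precision_by_bin(y, p, 0.05)
        prec = out["precision"].dropna().to_numpy()
        assert (np.diff(prec) > 0).all()

    def test_first_interval_honors_mu_above_first_edge(self):
        out = precision_by_bin([0, 1], [0.2, 0.9], 0.35)
        assert out.iloc[0]["lo"] == 0.35
        assert out.iloc[0]["hi"] == 0.4

    def test_empty_bin_reports_nan_not_zero(self):
        out = precision_by_bin([1, 1], [0.95, 0.97], 0.05)
        empty = out[out["count"] == 0]
        assert empty["precision"].isna().all()


class TestSensitivityCI:
    def test_degenerate_identical_aucs_zero_width(self):
        ci = sensitivity_auc_ci(lambda stays, seed: 0.9, [None], n_splits=5)
        assert ci.mean == 0.9
        assert ci.width == pytest.approx(0.0)

    def test_ci_contains_mean_and_resamples_bad_splits(self):
        calls = []

        def proc(stays, seed):
            calls.append(seed)
            if seed == 1:  # simulate one single-class split
                raise SingleClassError("bad split")
            return 0.8 + 0.01 * (seed % 3)

        ci = sensitivity_auc_ci(proc, [None], n_splits=6, seed=0)
        assert ci.low <= ci.mean <= ci.high
        assert len(ci.aucs) == 6
        assert 1 in calls  # the bad seed was attempted then replaced


class TestCohortSummary:
    def test_printed_percentages(self):
        assert percent(6281, 11816, 0) == 53
        assert percent(6281, 11816, 1) == 53.2
        assert percent(160, 1061, 1) == 15.1

    def test_empty_cohort_no_division_error(self):
        out = cohort_summary([])
        assert len(out) == 0

    def test_counts_and_means(self):
        stays = [
            PatientStay(stay_id=1, los_hours=48.0, age=70.0, sex="male",
                        weight=80.0, height=160.0, vent=np.array([[5, 20]])),
            PatientStay(stay_id=2, los_hours=24.0, age=60.0, sex="female",
                        weight=60.0, height=160.0),
        ]
        out = cohort_summary(stays).set_index("characteristic")
        assert out.loc["total", "n"] == 2
        assert out.loc["male sex", "n"] == 1
        assert out.loc["male sex", "pct"] == 50.0
        assert out.loc["age (years)", "mean"] == pytest.approx(65.0)
        assert out.loc["invasive mechanical ventilation", "n"] == 1


class TestEvalReport:
    def test_metrics_consistent_with_confusion_matrix(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 300)
        p = np.clip(rng.normal(0.3 + 0.3 * y, 0.2), 0, 1)
        rep = evaluate_predictions(y, p, EvaluationConfig())
        cm = rep.cm
        assert rep.precision == pytest.approx(cm.tp / (cm.tp + cm.fp))
        assert rep.recall == pytest.approx(cm.tp / (cm.tp + cm.fn))
        assert rep.f_beta == pytest.approx(f_beta(cm, rep.beta))
        assert rep.mcc == pytest.approx(mcc(cm))
        assert rep.achieved_fpr <= 0.2
        assert cm.tp + cm.fn == int(y.sum())

    def test_report_serializes(self, tmp_path):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        p = rng.uniform(size=100)
        rep = evaluate_predictions(y, p)
        rep.to_json(tmp_path / "r.json")
        import json

        back = json.loads((tmp_path / "r.json").read_text())
        assert back["auc"] == pytest.approx(rep.auc)
        assert back["confusion"]["tp"] == rep.cm.tp
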