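"""Threshold calibration, metrics, bootstrap CIs and paired comparison."""

import numpy as np
import pytest

from fairsite.evaluation import (
    auroc,
    bootstrap_ci,
    calibrate_threshold,
    classification_metrics,
    metric_report,
    paired_bootstrap_pvalue,
    per_site_eval,
)


def pairwise_auroc(scores, labels):
    """Exhaustive positive-negative pair count, ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestCalibration:
    def test_ten_distinct_positives_hit_nine_tenths(self):
        rng = np.random.default_rng(0)
        pos_scores = np.linspace(0.1, 0.95, 10)
        neg_scores = rng.uniform(0, 0.5, 200)
        scores = np.r_[pos_scores, neg_scores]
        labels = np.r_[np.ones(10), np.zeros(200)]
        choice = calibrate_threshold(scores, labels, target_sens=0.9, tol=0.05)
        assert choice.feasible
        assert choice.sensitivity == pytest.approx(0.9)

    def test_perfect_scorer_marks_infeasible_when_target_unreachable(self):
        labels = np.r_[np.ones(20), np.zeros(20)]
        scores = labels.astype(float)
        choice = calibrate_threshold(scores, labels, target_sens=0.9, tol=0.05)
        # only achievable sensitivities are 0 and 1; 1.0 > 0.95
        assert not choice.feasible
        assert choice.sensitivity == 1.0

    def test_tolerance_one_returns_max_specificity(self):
        labels = np.r_[np.ones(5), np.zeros(5)]
        scores = np.r_[np.linspace(0.5, 0.9, 5), np.linspace(0.1, 0.45, 5)]
        choice = calibrate_threshold(scores, labels, target_sens=0.9, tol=1.0)
        assert choice.specificity == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([0.5, 0.6], [0, 0])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        labels = np.r_[np.ones(10), np.zeros(10)]
        scores = np.r_[np.full(10, 0.9), np.full(10, 0.1)]
        rep = classification_metrics(scores, labels, 0.5)
        assert rep.auroc == 1.0 and rep.auprc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_worked_auroc_three_quarters(self):
        rep = classification_metrics([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0], 0.5)
        assert rep.auroc == pytest.approx(0.75)

    def test_all_negative_predictions(self):
        labels = np.r_[np.ones(3), np.zeros(7)]
        rep = classification_metrics(np.full(10, 0.2), labels, 0.9)
        assert rep.sensitivity == 0.0
        assert rep.npv == pytest.approx(1 - 0.3)
        assert rep.ppv is None  # no positive predictions

    def test_auroc_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            rep = classification_metrics(scores, labels, 0.5)
            assert rep.auroc == pytest.approx(pairwise_auroc(scores, labels), abs=1e-12)

    def test_ppv_npv_identities_from_confusion_counts(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        t = 0.4
        rep = classification_metrics(scores, labels, t)
        pred = scores >= t
        tp = np.sum(pred & (labels == 1)); fp = np.sum(pred & (labels == 0))
        tn = np.sum(~pred & (labels == 0)); fn = np.sum(~pred & (labels == 1))
        assert rep.ppv == pytest.approx(tp / (tp + fp))
        assert rep.npv == pytest.approx(tn / (tn + fn))

    def test_threshold_monotonicity_of_sens_and_spec(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 400)
        scores = rng.random(400)
        sens, spec = [], []
        for t in np.linspace(0, 1, 21):
            rep = classification_metrics(scores, labels, t)
            sens.append(rep.sensitivity)
            spec.append(rep.specificity)
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))


class TestBootstrap:
    def test_constant_metric_gives_degenerate_ci(self):
        labels = np.r_[np.ones(20), np.zeros(20)]
        scores = labels.astype(float)
        lo, hi = bootstrap_ci(scores, labels, auroc, B=200, seed=0, stratified=True)
        assert lo == hi == 1.0

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)

        def width(n, seed):
            labels = rng.integers(0, 2, n)
            scores = np.clip(labels * 0.3 + rng.random(n) * 0.7, 0, 1)
            lo, hi = bootstrap_ci(scores, labels, auroc, B=300, seed=seed)
            return hi - lo

        widths_small = np.median([width(200, s) for s in range(5)])
        widths_large = np.median([width(2000, s) for s in range(5)])
        assert widths_large < widths_small

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        ci1 = bootstrap_ci(scores, labels, auroc, B=100, seed=9)
        ci2 = bootstrap_ci(scores, labels, auroc, B=100, seed=9)
        assert ci1 == ci2

    def test_metric_report_ci_brackets_point(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 300)
        scores = np.clip(labels * 0.4 + rng.random(300) * 0.6, 0, 1)
        rep = metric_report(scores, labels, 0.5, B=200, seed=0)
        for name, (lo, hi) in rep.ci.items():
            assert lo <= hi
            # percentile CIs bracket the point estimate up to resampling noise
            assert lo - 0.1 <= getattr(rep, name) <= hi + 0.1


class TestPairedBootstrap:
    def test_model_against_itself_is_a_coin_flip(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        p = paired_bootstrap_pvalue(scores, scores, labels, auroc, B=1000, seed=0)
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / 1000) + 1e-9

    def test_perfect_model_beats_random(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 500)
        perfect = labels.astype(float)
        random_scores = rng.random(500)
        p = paired_bootstrap_pvalue(perfect, random_scores, labels, auroc, B=1000, seed=1)
        assert p < 0.001

    def test_single_iteration_p_is_zero_or_one(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 100)
        p = paired_bootstrap_pvalue(rng.random(100), rng.random(100), labels, auroc, B=1, seed=2)
        assert p in (0.0, 1.0)


class TestPerSite:
    def test_single_site_equals_global(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        global_rep = classification_metrics(scores, labels, 0.5)
        by_site = per_site_eval(scores, labels, np.full(100, "only"), 0.5)
        assert by_site["only"].auroc == pytest.approx(global_rep.auroc)
        assert by_site["only"].ppv == pytest.approx(global_rep.ppv)

    def test_site_without_negatives_reports_absent_specificity(self):
        scores = [0.9, 0.8, 0.2, 0.7]
        labels = [1, 1, 0, 1]
        sites = ["P", "P", "Q", "P"]
        reps = per_site_eval(scores, labels, sites, 0.5)
        assert reps["P"].specificity is None
        assert reps["Q"].sensitivity is None

    def test_two_site_table_matches_manual_computation(self):
        scores = [0.9, 0.1, 0.8, 0.3, 0.6, 0.2]
        labels = [1, 0, 0, 1, 1, 0]
        sites = ["A", "A", "A", "B", "B", "B"]
        reps = per_site_eval(scores, labels, sites, 0.5)
        # site A: tp=1 fp=1 tn=1 fn=0; site B: tp=1 fp=0 tn=2 fn=1
        assert reps["A"].sensitivity == pytest.approx(1.0)
        assert reps["A"].specificity == pytest.approx(0.5)
        assert reps["B"].sensitivity == pytest.approx(0.5)
        assert reps["B"].prevalence == pytest.approx(2 / 3)
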