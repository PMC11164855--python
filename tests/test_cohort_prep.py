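"""Matching, splitting, harmonisation, missingness filtering, preprocessing."""

import numpy as np
import pandas as pd
import pytest

from fairsite.cohort_prep import (
    SplitPlan,
    apply_preprocess,
    filter_missingness,
    fit_preprocess,
    harmonize_features,
    impute_median,
    match_controls,
    split_extract,
)

from conftest import make_table


def _aged(table, ages):
    table = table.copy()
    table["age"] = ages
    return table


class TestMatchControls:
    def _pools(self, n_pos=10, n_ctrl=500, seed=0):
        rng = np.random.default_rng(seed)
        pos = make_table(rng.standard_normal((n_pos, 2)), np.ones(n_pos))
        ctrl = make_table(rng.standard_normal((n_ctrl, 2)), np.zeros(n_ctrl))
        return _aged(pos, rng.uniform(40, 60, n_pos)), _aged(ctrl, rng.uniform(30, 70, n_ctrl))

    def test_20_to_1_matching_prevalence_is_one_over_21(self):
        pos, ctrl = self._pools()
        out = match_controls(pos, ctrl, ratio=20, age_window=10)
        assert len(out) == 210
        assert out["label"].mean() == pytest.approx(10 / 210)

    def test_ratio_zero_returns_positives_only(self):
        pos, ctrl = self._pools()
        out = match_controls(pos, ctrl, ratio=0, age_window=10)
        assert len(out) == len(pos)
        assert out["label"].mean() == 1.0

    def test_insufficient_controls_is_an_error(self):
        pos, ctrl = self._pools(n_pos=1, n_ctrl=19)
        with pytest.raises(ValueError, match="insufficient"):
            match_controls(pos, ctrl, ratio=20, age_window=100)

    def test_controls_never_reused_and_within_window(self):
        pos, ctrl = self._pools(n_pos=5, n_ctrl=300)
        out = match_controls(pos, ctrl, ratio=20, age_window=5, seed=3)
        matched = out[out["label"] == 0]
        assert len(matched) == 100
        # no duplicated control rows (feature vectors are continuous draws)
        assert not matched.duplicated(subset=["f0", "f1", "age"]).any()
        # every matched control within the window of at least one case
        case_ages = out[out["label"] == 1]["age"].to_numpy()
        dists = np.abs(matched["age"].to_numpy()[:, None] - case_ages[None, :])
        assert (dists.min(axis=1) <= 5).all()

    def test_missing_age_column_is_an_error(self):
        pos, ctrl = self._pools()
        with pytest.raises(ValueError, match="age"):
            match_controls(pos.drop(columns="age"), ctrl, ratio=2, age_window=5)


class TestSplitExtract:
    def test_exact_divisibility_gives_exact_counts(self):
        y = np.r_[np.ones(100), np.zeros(900)]
        table = make_table(np.zeros((1000, 2)), y)
        out = split_extract(table, SplitPlan(seed=0))
        counts = out.groupby(["split", "label"]).size()
        assert counts[("train", 1)] == 60
        assert counts[("continuous_validation", 1)] == 20
        assert counts[("test", 1)] == 20
        assert counts[("train", 0)] == 540

    def test_deterministic_given_seed(self):
        table = make_table(np.zeros((50, 1)), np.r_[np.ones(10), np.zeros(40)])
        a = split_extract(table, SplitPlan(seed=5))
        b = split_extract(table, SplitPlan(seed=5))
        assert (a["split"] == b["split"]).all()

    def test_largest_remainder_on_five_rows(self):
        # one class of 5 rows at 0.6/0.2/0.2: quotas 3/1/1 exactly
        table = make_table(np.zeros((7, 1)), np.r_[np.ones(2), np.zeros(5)])
        out = split_extract(table, SplitPlan(seed=1))
        neg = out[out["label"] == 0]["split"].value_counts()
        assert neg["train"] == 3 and neg["continuous_validation"] == 1 and neg["test"] == 1
        # 2 positives: quotas 1.2/0.4/0.4 -> largest remainder tie broken in
        # split order, so validation gets the second row
        pos = out[out["label"] == 1]["split"].value_counts()
        assert pos["train"] == 1 and pos["continuous_validation"] == 1

    def test_single_class_input_rejected(self):
        table = make_table(np.zeros((10, 1)), np.zeros(10))
        with pytest.raises(ValueError):
            split_extract(table, SplitPlan())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitPlan(fractions=(0.5, 0.2, 0.2)).validate()


class TestHarmonize:
    def test_identical_schemas_drop_nothing(self):
        t = make_table(np.zeros((4, 3)), [0, 1, 0, 1])
        merged, dropped = harmonize_features([t, t.copy()])
        assert dropped == {0: [], 1: []}
        assert len(merged) == 8

    def test_feature_missing_in_one_table_dropped_everywhere(self):
        t1 = make_table(np.zeros((4, 3)), [0, 1, 0, 1])
        t2 = t1.drop(columns="f1")
        merged, dropped = harmonize_features([t1, t2])
        assert "f1" not in merged.columns
        assert dropped[0] == ["f1"]

    def test_disjoint_schemas_error(self):
        t1 = make_table(np.zeros((2, 2)), [0, 1], feature_names=["a", "b"])
        t2 = make_table(np.zeros((2, 2)), [0, 1], feature_names=["c", "d"])
        with pytest.raises(ValueError, match="no common features"):
            harmonize_features([t1, t2])


class TestFilterMissingness:
    def _with_missing(self, frac, n=100):
        X = np.zeros((n, 2))
        X[: int(round(frac * n)), 1] = np.nan
        t = make_table(X, np.tile([0, 1], n // 2))
        t["f0"] = np.arange(n, dtype=float)
        return t

    def test_boundary_is_strictly_greater(self):
        dropped_31 = filter_missingness(self._with_missing(0.31), scope="pooled")[1]
        dropped_30 = filter_missingness(self._with_missing(0.30), scope="pooled")[1]
        assert dropped_31 == ["f1"]
        assert dropped_30 == []

    def test_complete_table_unchanged(self):
        t = make_table(np.random.default_rng(0).standard_normal((20, 3)), np.tile([0, 1], 10))
        out, dropped = filter_missingness(t)
        assert dropped == []
        pd.testing.assert_frame_equal(out, t)

    def test_fully_missing_feature_dropped(self):
        t = self._with_missing(1.0)
        assert filter_missingness(t, scope="pooled")[1] == ["f1"]

    def test_train_scope_uses_training_rows_only(self):
        t = self._with_missing(0.0, n=100)
        t["split"] = ["train"] * 50 + ["test"] * 50
        t.loc[t["split"] == "test", "f1"] = np.nan  # 50% missing overall, 0% on train
        assert filter_missingness(t, scope="train")[1] == []
        assert filter_missingness(t, scope="pooled")[1] == ["f1"]


class TestPreprocess:
    def test_standardization_arithmetic_population_sd(self):
        train = make_table(np.array([[1.0], [2.0], [3.0]]), [0, 1, 0])
        state = fit_preprocess(train)
        assert state.means["f0"] == pytest.approx(2.0)
        assert state.sds["f0"] == pytest.approx(np.sqrt(2.0 / 3.0))
        out = apply_preprocess(train, state)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out["f0"].to_numpy(), expected, atol=1e-12)

    def test_observed_entries_standardized_to_mean0_sd1(self):
        rng = np.random.default_rng(1)
        X = rng.normal(50, 7, size=(500, 2))
        X[rng.random(500) < 0.2, 1] = np.nan
        train = make_table(X, rng.integers(0, 2, 500))
        state = fit_preprocess(train)
        out = apply_preprocess(train, state)
        observed = out.loc[train["f1"].notna(), "f1"]
        assert abs(observed.mean()) < 1e-9
        assert abs(observed.std(ddof=0) - 1.0) < 1e-9

    def test_missing_entry_maps_to_standardized_median(self):
        train = make_table(np.array([[1.0], [2.0], [3.0]]), [0, 1, 0])
        state = fit_preprocess(train)
        test = make_table(np.array([[np.nan]]), [0])
        out = apply_preprocess(test, state)
        assert out["f0"].iloc[0] == pytest.approx(0.0)  # median 2 == mean 2

    def test_apply_uses_training_statistics_not_own(self):
        train = make_table(np.array([[0.0], [1.0]]), [0, 1])
        test = make_table(np.array([[100.0], [200.0]]), [0, 1])
        state = fit_preprocess(train)
        out = apply_preprocess(test, state)
        assert out["f0"].iloc[0] == pytest.approx((100 - 0.5) / 0.5)

    def test_state_identical_across_applications(self):
        rng = np.random.default_rng(2)
        train = make_table(rng.standard_normal((100, 2)), rng.integers(0, 2, 100))
        state = fit_preprocess(train)
        before = state.to_json()
        apply_preprocess(train, state)
        apply_preprocess(train.iloc[:10], state)
        assert state.to_json() == before

    def test_imputation_idempotent(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2))
        X[:10, 0] = np.nan
        table = make_table(X, rng.integers(0, 2, 50))
        state = fit_preprocess(table)
        once = impute_median(table, state)
        twice = impute_median(once, state)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_variance_feature_named_in_error(self):
        train = make_table(np.ones((10, 1)), np.tile([0, 1], 5))
        with pytest.raises(ValueError, match="f0"):
            fit_preprocess(train)

    def test_state_json_roundtrip(self):
        from fairsite.cohort_prep import PreprocessState

        train = make_table(np.array([[1.0], [2.0], [4.0]]), [0, 1, 0])
        state = fit_preprocess(train)
        restored = PreprocessState.from_json(state.to_json())
        assert restored.means == state.means and restored.sds == state.sds
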