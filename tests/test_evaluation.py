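"""Metric suite, t-test confidence intervals, fairness gaps and criteria."""

import numpy as np
import pandas as pd
import pytest

from bayesboost.evaluation import (
    _t_ci,
    classification_metrics,
    evaluate,
    fairness_metrics,
    fairness_uncertainty_criterion,
)
from bayesboost.uncertainty import train_nb


class TestClassificationMetrics:
    def test_perfect_scores_give_ones(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.9, 0.8])
        m = classification_metrics(labels, scores)
        for key in ("accuracy", "precision", "recall", "f1", "roc_auc", "pr_auc"):
            assert m[key] == pytest.approx(1.0)

    def test_contingency_arithmetic(self):
        # TP=30, FP=70, FN=0, TN=900 -> precision 0.3, recall 1.0, F1 = 6/13
        labels = np.array([1] * 30 + [0] * 70 + [0] * 900)
        scores = np.array([0.9] * 100 + [0.1] * 900)
        m = classification_metrics(labels, scores)
        assert m["precision"] == pytest.approx(0.3)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(6 / 13)
        assert m["accuracy"] == pytest.approx(930 / 1000)

    def test_random_scores_sit_at_chance(self):
        rng = np.random.default_rng(0)
        labels = np.tile([0, 1], 5000)
        scores = rng.random(10_000)
        m = classification_metrics(labels, scores)
        assert abs(m["roc_auc"] - 0.5) < 0.02
        assert abs(m["pr_auc"] - 0.5) < 0.02

    def test_single_class_labels_warn_and_nan_aucs(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = classification_metrics(np.zeros(10, dtype=int), np.full(10, 0.2))
        assert np.isnan(m["roc_auc"]) and np.isnan(m["pr_auc"])


def test_t_interval_matches_hand_computation():
    from scipy import stats

    lo, mean, hi = _t_ci(np.array([0.8, 0.82, 0.84]))
    assert mean == pytest.approx(0.82)
    half = stats.t.ppf(0.975, 2) * np.std([0.8, 0.82, 0.84], ddof=1) / np.sqrt(3)
    assert hi - mean == pytest.approx(half)
    assert mean - lo == pytest.approx(half)
    lo0, mean0, hi0 = _t_ci(np.full(5, 0.7))
    assert lo0 == mean0 == hi0 == pytest.approx(0.7)  # zero variance -> width 0


class TestFairnessMetrics:
    def test_identical_rates_have_zero_gaps(self):
        labels = np.tile([0, 1], 50)
        preds = np.tile([0, 1], 50)
        groups = np.repeat(["a", "b"], 50)
        m = fairness_metrics(labels, preds, groups)
        assert m["demographic_parity_gap"] == pytest.approx(0.0)
        assert m["equalized_odds_gap"] == pytest.approx(0.0)

    def test_dp_gap_is_rate_difference(self):
        # group a positive-prediction rate 0.6, group b 0.2 -> gap 0.4
        preds = np.concatenate([np.repeat([1, 0], [6, 4]), np.repeat([1, 0], [2, 8])])
        labels = np.tile([0, 1], 10)
        groups = np.repeat(["a", "b"], 10)
        m = fairness_metrics(labels, preds, groups)
        assert m["demographic_parity_gap"] == pytest.approx(0.4)

    def test_gaps_invariant_to_relabeling(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 200)
        preds = rng.integers(0, 2, 200)
        groups = rng.choice(["a", "b", "c"], 200)
        m1 = fairness_metrics(labels, preds, groups)
        renamed = pd.Series(groups).map({"a": "z", "b": "y", "c": "x"}).to_numpy()
        m2 = fairness_metrics(labels, preds, renamed)
        assert m1 == pytest.approx(m2)

    def test_group_without_positives_warns(self):
        labels = np.array([0, 0, 0, 0, 1, 0, 1, 0])
        preds = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.warns(UserWarning, match="no positives"):
            fairness_metrics(labels, preds, groups)


class TestEvaluate:
    def test_reproducible_and_zero_width_for_fixed_candidates(self, cvd_small):
        from bayesboost.core_data import stratified_split

        train, test = stratified_split(cvd_small, "stroke_heart_attack", 0.7, 5)
        report = evaluate({"D": train}, test, n_runs=3, seed=9)
        report2 = evaluate({"D": train}, test, n_runs=3, seed=9)
        pd.testing.assert_frame_equal(report.table, report2.table)
        # deterministic training -> identical runs -> zero-width CIs
        row = report.table.loc[("D", "accuracy")]
        assert row["ci_low"] == row["mean"] == row["ci_high"]
        assert 0.0 <= row["mean"] <= 1.0

    def test_callable_candidates_receive_run_and_seed(self, cvd_small):
        from bayesboost.core_data import stratified_split

        train, test = stratified_split(cvd_small, "stroke_heart_attack", 0.7, 5)
        calls = []

        def factory(run, seed):
            calls.append((run, seed))
            return train

        evaluate({"D": factory}, test, n_runs=2, seed=3)
        assert len(calls) == 2 and calls[0] != calls[1]


class TestFairnessUncertaintyCriterion:
    def test_disadvantaged_group_is_selected(self, cvd_small):
        from bayesboost.core_data import stratified_split

        val, train = stratified_split(cvd_small, "ethnicity", 0.3, 7)
        model = train_nb(train)
        d_unc = fairness_uncertainty_criterion(model, val, "equalized_odds")
        if d_unc is not None:  # gap can be zero on a lucky draw
            assert d_unc.role == "uncertain"
            assert d_unc.frame["ethnicity"].nunique() == 1

    def test_cap_matches_interval_filter_count(self, cvd_small):
        from bayesboost.core_data import stratified_split
        from bayesboost.uncertainty import predict_proba

        val, train = stratified_split(cvd_small, "ethnicity", 0.3, 7)
        model = train_nb(train)
        probs = predict_proba(model, val)
        cap = int(((probs >= 0.4) & (probs <= 0.7)).sum())
        d_unc = fairness_uncertainty_criterion(model, val, "demographic_parity")
        assert d_unc is None or d_unc.n_rows <= cap

    def test_zero_gap_returns_none(self, tiny_dataset, monkeypatch):
        import bayesboost.evaluation as ev

        monkeypatch.setattr(
            ev, "predict_proba", lambda model, rows: np.zeros(rows.n_rows)
        )
        model = train_nb(tiny_dataset)
        with pytest.warns(UserWarning, match="zero fairness gap"):
            out = fairness_uncertainty_criterion(model, tiny_dataset, "demographic_parity")
        assert out is None

    def test_unknown_metric_rejected(self, tiny_dataset):
        model = train_nb(tiny_dataset)
        with pytest.raises(ValueError):
            fairness_uncertainty_criterion(model, tiny_dataset, "parity_of_odds")
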