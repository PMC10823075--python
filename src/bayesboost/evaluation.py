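"""Candidate-dataset comparison on a fixed held-out test set.

Every candidate training set (ground truth, biased, boosted, baseline
outputs) trains a Naive Bayes classifier which is scored on the SAME test
set; the procedure repeats over reseeded runs and reports per-metric means
with Student-t confidence intervals, mirroring the usual
``CI low / mean / CI up`` presentation. The metric suite is accuracy,
ROC-AUC, PR-AUC (step interpolation), precision, recall, F1 at the 0.5
threshold, plus two group-fairness gaps: demographic parity (max-min
positive-prediction rate across protected groups) and equalized odds (worst
across-group disparity of TPR and FPR).

An experimental alternative uncertain-set criterion is also provided: select
validation rows from the group on the disadvantaged side of a fairness gap
instead of by predicted-probability interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .core_data import TabularDataset
from .uncertainty import NaiveBayesModel, predict_proba, train_nb

logger = logging.getLogger("bayesboost")

METRICS = (
    "accuracy", "roc_auc", "pr_auc", "precision", "recall", "f1",
    "equalized_odds_gap", "demographic_parity_gap",
)

CandidateLike = TabularDataset | Callable[[int, int], TabularDataset]


def classification_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Thresholded accuracy/precision/recall/F1 plus ROC-AUC and PR-AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    out = {
        "accuracy": float((pred == labels).mean()),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
    }
    denom = 2 * tp + fp + fn
    out["f1"] = 2 * tp / denom if denom else 0.0
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels; AUC metrics undefined")
        out["roc_auc"] = float("nan")
        out["pr_auc"] = float("nan")
    else:
        out["roc_auc"] = float(roc_auc_score(labels, scores))
        out["pr_auc"] = float(average_precision_score(labels, scores))
    return out


def fairness_metrics(
    labels: np.ndarray, predictions: np.ndarray, groups: np.ndarray
) -> dict[str, float]:
    """Demographic-parity and equalized-odds gaps across protected groups."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two protected groups")
    pos_rates, tprs, fprs = [], [], []
    for g in uniq:
        m = groups == g
        pos_rates.append(predictions[m].mean())
        if (labels[m] == 1).any():
            tprs.append(predictions[m][labels[m] == 1].mean())
        else:
            warnings.warn(f"group {g!r} has no positives; TPR omitted from equalized odds")
        if (labels[m] == 0).any():
            fprs.append(predictions[m][labels[m] == 0].mean())
    dp = float(max(pos_rates) - min(pos_rates))
    spans = []
    if len(tprs) >= 2:
        spans.append(max(tprs) - min(tprs))
    if len(fprs) >= 2:
        spans.append(max(fprs) - min(fprs))
    eo = float(max(spans)) if spans else float("nan")
    return {"demographic_parity_gap": dp, "equalized_odds_gap": eo}


@dataclass
class EvalReport:
    """Mean and t-test CI per (dataset, metric), plus the raw per-run values."""

    table: pd.DataFrame  # index (dataset, metric); columns ci_low, mean, ci_high
    per_run: dict[str, pd.DataFrame]  # dataset -> runs x metrics

    def mean(self, dataset: str, metric: str) -> float:
        return float(self.table.loc[(dataset, metric), "mean"])


def _t_ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.nanmean(values))
    n = int(np.sum(~np.isnan(values)))
    if n < 2:
        return float("nan"), m, float("nan")
    sd = float(np.nanstd(values, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return m - half, m, m + half


def evaluate(
    candidates: Mapping[str, CandidateLike],
    test: TabularDataset,
    n_runs: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Train-on-candidate / test-on-fixed-set comparison over repeated runs.

    A candidate may be a fixed dataset or a callable ``(run, seed) ->
    dataset`` regenerating its training data per run (so resampling noise is
    part of the reported uncertainty). The test set never changes.
    """
    if n_runs < 2:
        warnings.warn("single run requested; means reported without CIs")
    rng = np.random.default_rng(seed)
    y_test = test.labels()
    groups = test.frame[test.schema.protected_name].to_numpy(dtype=object)
    per_run: dict[str, list[dict[str, float]]] = {name: [] for name in candidates}
    for run in range(n_runs):
        run_seed = int(rng.integers(2**31))
        for name, cand in candidates.items():
            dataset = cand(run, run_seed) if callable(cand) else cand
            model = train_nb(dataset)
            scores = predict_proba(model, test)
            row = classification_metrics(y_test, scores, threshold)
            row.update(fairness_metrics(y_test, (scores >= threshold).astype(int), groups))
            per_run[name].append(row)
    frames = {name: pd.DataFrame(rows) for name, rows in per_run.items()}
    records = []
    for name, frame in frames.items():
        for metric in METRICS:
            lo, m, hi = _t_ci(frame[metric].to_numpy())
            records.append({"dataset": name, "metric": metric, "ci_low": lo, "mean": m, "ci_high": hi})
    table = pd.DataFrame(records).set_index(["dataset", "metric"])
    return EvalReport(table=table, per_run=frames)


def fairness_uncertainty_criterion(
    model: NaiveBayesModel,
    validation: TabularDataset,
    metric: str,
    p1: float = 0.4,
    p2: float = 0.7,
    threshold: float = 0.5,
) -> TabularDataset | None:
    """EXPERIMENTAL: select uncertain rows by fairness gap instead of interval.

    Picks validation rows from the protected group on the disadvantaged side
    of the chosen gap — lowest TPR for equalized odds, lowest
    positive-prediction rate for demographic parity — capped at the number
    the probability-interval filter would have selected (rows nearest the
    decision threshold first). Returns ``None`` on a zero-gap input.

    This selection rule is a reconstruction of an only loosely described
    procedure; treat its outputs as exploratory.
    """
    if metric not in ("equalized_odds", "demographic_parity"):
        raise ValueError("metric must be 'equalized_odds' or 'demographic_parity'")
    probs = predict_proba(model, validation)
    pred = (probs >= threshold).astype(int)
    y = validation.labels()
    groups = validation.frame[validation.schema.protected_name].to_numpy(dtype=object)
    cap = int(((probs >= p1) & (probs <= p2)).sum())
    rates: dict[object, float] = {}
    for g in pd.unique(groups):
        m = groups == g
        if metric == "demographic_parity":
            rates[g] = float(pred[m].mean())
        elif (y[m] == 1).any():
            rates[g] = float(pred[m][y[m] == 1].mean())
    if not rates or max(rates.values()) - min(rates.values()) <= 0 or cap == 0:
        warnings.warn("zero fairness gap (or zero cap); empty uncertain selection")
        return None
    worst = min(sorted(rates), key=lambda g: rates[g])
    members = np.flatnonzero(groups == worst)
    order = members[np.argsort(np.abs(probs[members] - threshold), kind="stable")]
    return validation.subset(order[:cap], role="uncertain")
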