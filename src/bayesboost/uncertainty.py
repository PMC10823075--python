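"""Bias detection through classifier uncertainty.

A mixed-data Naive Bayes classifier (Laplace-smoothed categorical
likelihoods, per-class Gaussian likelihoods for numerics) is trained to
predict the binary disease target; validation rows whose predicted
positive-class probability falls in the closed interval ``[p1, p2]``
(defaults 0.4 and 0.7) form the *uncertain set*. Comparing the protected
attribute's distribution in the uncertain set against the audited dataset
flags the groups the data under-represents: a group over-represented among
hard-to-classify rows is a group the data needs more of.

The thresholds can be recalibrated by the quartile procedure: over repeated
stratified splits, ``p1`` is the mean predicted probability over validation
cases in the (0.25, 0.5] band and ``p2`` the mean over (0.5, 0.75].

Any probabilistic binary classifier implementing ``train``/``predict_proba``
can be plugged in; Naive Bayes is the bundled default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CATEGORICAL, NUMERIC, Schema, TabularDataset, stratified_split

logger = logging.getLogger("bayesboost")

_VAR_FLOOR = 1e-9


@dataclass(frozen=True)
class UncertaintyConfig:
    """Thresholds and calibration settings for the uncertain-set extraction."""

    p1: float = 0.4
    p2: float = 0.7
    calibrate: bool = False
    n_calibration_repeats: int = 10
    p1_band: tuple[float, float] = (0.25, 0.5)
    p2_band: tuple[float, float] = (0.5, 0.75)
    validation_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.p1 < self.p2 < 1:
            raise ValueError("thresholds must satisfy 0 < p1 < p2 < 1")


@dataclass
class NaiveBayesModel:
    """Class prior + per-feature likelihoods (categorical tables / Gaussians)."""

    schema: Schema
    prior: np.ndarray  # P(class 0), P(class 1)
    cat_likelihood: dict[str, np.ndarray]  # name -> (2, n_levels), rows sum to 1
    gauss_moments: dict[str, np.ndarray]  # name -> (2, 2) mean/var per class
    alpha: float = 1.0


def train_nb(train: TabularDataset, alpha: float = 1.0) -> NaiveBayesModel:
    """Fit the mixed Naive Bayes model on the dataset's target."""
    y = train.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single target class")
    prior = np.array([(y == 0).mean(), (y == 1).mean()])
    cat_likelihood: dict[str, np.ndarray] = {}
    gauss_moments: dict[str, np.ndarray] = {}
    for v in train.schema.variables:
        if v.name == train.schema.target_name:
            continue
        col = train.frame[v.name]
        if v.kind == CATEGORICAL:
            table = np.empty((2, len(v.levels)))
            for c in (0, 1):
                counts = col[y == c].value_counts()
                raw = np.array([counts.get(lv, 0) for lv in v.levels], dtype=float)
                table[c] = (raw + alpha) / (raw.sum() + alpha * len(v.levels))
            cat_likelihood[v.name] = table
        else:
            vals = col.to_numpy(dtype=float)
            moments = np.empty((2, 2))
            for c in (0, 1):
                sub = vals[y == c]
                moments[c] = [sub.mean(), max(sub.var(), _VAR_FLOOR)]
            gauss_moments[v.name] = moments
    return NaiveBayesModel(train.schema, prior, cat_likelihood, gauss_moments, alpha)


def predict_proba(model: NaiveBayesModel, rows: TabularDataset | pd.DataFrame) -> np.ndarray:
    """Per-row probability of the positive class, accumulated in log space."""
    frame = rows.frame if isinstance(rows, TabularDataset) else rows
    n = len(frame)
    log_post = np.tile(np.log(model.prior), (n, 1))
    for name, table in model.cat_likelihood.items():
        levels = model.schema.var(name).levels
        lookup = {lv: i for i, lv in enumerate(levels)}
        idx = frame[name].astype(str).map(lookup)
        if idx.isna().any():
            logger.warning("unseen level(s) in %r at prediction; using pure-alpha likelihood", name)
        idx_arr = idx.to_numpy()
        for c in (0, 1):
            probs = np.where(
                pd.isna(idx_arr),
                model.alpha / (model.alpha * len(levels) + 1.0),
                table[c][np.where(pd.isna(idx_arr), 0, idx_arr).astype(int)],
            )
            log_post[:, c] += np.log(probs)
    for name, moments in model.gauss_moments.items():
        vals = frame[name].to_numpy(dtype=float)
        for c in (0, 1):
            mean, var = moments[c]
            log_post[:, c] += -0.5 * (np.log(2 * np.pi * var) + (vals - mean) ** 2 / var)
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    return post[:, 1] / post.sum(axis=1)


def calibrate_thresholds(
    dataset: TabularDataset,
    config: UncertaintyConfig,
    seed: int,
) -> tuple[float, float]:
    """Quartile-based recalibration of (p1, p2) over repeated splits.

    Each repeat: stratified validation split on the protected attribute, train
    Naive Bayes on the remainder, predict on validation; the repeat's p1 is
    the mean predicted positive probability over cases in the (0.25, 0.5]
    band and p2 the mean over (0.5, 0.75]. Bands empty in every repeat fall
    back to the defaults (0.4, 0.7) with a warning.
    """
    rng = np.random.default_rng(seed)
    p1_vals: list[float] = []
    p2_vals: list[float] = []
    for _ in range(config.n_calibration_repeats):
        validation, train = stratified_split(
            dataset,
            dataset.schema.protected_name,
            config.validation_fraction,
            int(rng.integers(2**31)),
        )
        model = train_nb(train)
        probs = predict_proba(model, validation)
        lo1, hi1 = config.p1_band
        lo2, hi2 = config.p2_band
        band1 = probs[(probs > lo1) & (probs <= hi1)]
        band2 = probs[(probs > lo2) & (probs <= hi2)]
        if band1.size:
            p1_vals.append(float(band1.mean()))
        if band2.size:
            p2_vals.append(float(band2.mean()))
    fallback = False
    if not p1_vals:
        warnings.warn("p1 calibration band empty in every repeat; falling back to 0.4")
        p1, fallback = 0.4, True
    else:
        p1 = float(np.mean(p1_vals))
    if not p2_vals:
        warnings.warn("p2 calibration band empty in every repeat; falling back to 0.7")
        p2, fallback = 0.7, True
    else:
        p2 = float(np.mean(p2_vals))
    if p1 >= p2:
        warnings.warn(f"calibrated thresholds inverted (p1={p1:.3f} >= p2={p2:.3f}); using defaults")
        return 0.4, 0.7
    if fallback:
        logger.info("calibration fell back for one threshold: p1=%.3f p2=%.3f", p1, p2)
    return p1, p2


def extract_uncertain(
    model: NaiveBayesModel,
    validation: TabularDataset,
    p1: float = 0.4,
    p2: float = 0.7,
) -> tuple[TabularDataset, np.ndarray]:
    """Rows whose predicted positive probability lies in the CLOSED [p1, p2].

    Returns the uncertain subset (original, undiscretized feature values) and
    the per-row probabilities over the whole validation set.
    """
    if not p1 < p2:
        raise ValueError("p1 must be < p2")
    probs = predict_proba(model, validation)
    mask = (probs >= p1) & (probs <= p2)
    if not mask.any():
        raise ValueError(
            f"no validation rows fall in [{p1}, {p2}]; widen the thresholds"
        )
    return validation.subset(np.flatnonzero(mask), role="uncertain"), probs


def representation_report(
    reference: TabularDataset,
    uncertain: TabularDataset,
    protected: str | None = None,
) -> pd.DataFrame:
    """Per-level shares in the reference data vs the uncertain set.

    A level is flagged ``under_represented`` iff its share among uncertain
    (hard-to-classify) rows exceeds its share in the reference data. Levels
    absent from both datasets are omitted.
    """
    protected = protected or reference.schema.protected_name
    ref_col = reference.frame[protected]
    unc_col = uncertain.frame[protected]
    ref_shares = ref_col.value_counts(normalize=True)
    unc_shares = unc_col.value_counts(normalize=True)
    rows = []
    for level in reference.schema.var(protected).levels:
        r = float(ref_shares.get(level, 0.0))
        u = float(unc_shares.get(level, 0.0))
        if r == 0.0 and u == 0.0:
            continue
        rows.append(
            {
                "level": level,
                "reference_share": r,
                "uncertain_share": u,
                "under_represented": u > r,
            }
        )
    return pd.DataFrame(rows)
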