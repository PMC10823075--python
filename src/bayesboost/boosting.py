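"""Evidence-conditioned oversampling of under-represented strata.

The correction half of the method: rank the attributes by how much their
distributions differ between the audited dataset and the uncertain set (the
ordered set ``O``), decide how many synthetic rows each uncertain row should
spawn (the per-row counts ``m``, summing to 50/100/200% of the audited
dataset's size), train a Bayesian network on the audited dataset, and for
every uncertain row draw its ``m`` offspring with the row's protected value
and its values on the top-k attributes of ``O`` clamped as evidence. The
synthetic rows are merged with the audited dataset to form the boosted
dataset ``BB``.

The target variable is never used as evidence, so synthetic rows carry
sampled — not copied — labels, and the uncertain rows themselves are not
merged into ``BB``; only their synthetic offspring are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayesnet
from .core_data import (
    CATEGORICAL,
    TabularDataset,
    discretize,
    distribution_distance,
    stratified_split,
    undiscretize,
)
from .uncertainty import (
    UncertaintyConfig,
    calibrate_thresholds,
    extract_uncertain,
    representation_report,
    train_nb,
)

logger = logging.getLogger("bayesboost")


@dataclass(frozen=True)
class AttributeOrdering:
    """Non-target variables with their distribution-distance scores, descending."""

    entries: tuple[tuple[str, float], ...]

    def top(self, k: int, exclude: tuple[str, ...] = ()) -> list[str]:
        out = [name for name, _ in self.entries if name not in exclude]
        return out[:k]


@dataclass
class BoostPlan:
    """Per-uncertain-row synthetic counts for one boosting fraction."""

    fraction: float
    counts: np.ndarray
    evidence_depth: int = 3

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def order_attributes(d_bias: TabularDataset, d_unc: TabularDataset) -> AttributeOrdering:
    """Rank non-target variables by distribution difference (audited vs uncertain).

    Categorical columns use total variation, numeric ones the KS statistic;
    ties are broken by schema order, and the sort is stable under row order.
    """
    schema = d_bias.schema
    scores = []
    for v in schema.variables:
        if v.name == schema.target_name:
            continue
        d = distribution_distance(d_bias.frame[v.name], d_unc.frame[v.name], v.kind)
        scores.append((v.name, d))
    scores.sort(key=lambda t: -t[1])  # stable: ties keep schema order
    return AttributeOrdering(tuple(scores))


def compute_m(n_bias: int, n_unc: int, fraction: float, evidence_depth: int = 3) -> BoostPlan:
    """Split round(fraction * n_bias) synthetic rows as evenly as possible.

    The first ``total mod n_unc`` uncertain rows receive one extra row, so all
    counts differ by at most 1 and their sum is exact.
    """
    if n_unc < 1:
        raise ValueError("need at least one uncertain row")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    total = int(np.floor(fraction * n_bias + 0.5))
    if total == 0:
        raise ValueError("fraction * n_bias rounds to zero synthetic rows")
    base, rem = divmod(total, n_unc)
    counts = np.full(n_unc, base, dtype=int)
    counts[:rem] += 1
    return BoostPlan(fraction=fraction, counts=counts, evidence_depth=evidence_depth)


def _row_evidence(
    disc_row: pd.Series, protected: str, top_vars: list[str]
) -> tuple[tuple[str, str], ...]:
    ev = [(protected, str(disc_row[protected]))]
    ev += [(v, str(disc_row[v])) for v in top_vars]
    return tuple(ev)


def boost(
    d_bias: TabularDataset,
    d_unc: TabularDataset,
    plan: BoostPlan,
    ordering: AttributeOrdering,
    seed: int,
    network: bayesnet.BayesianNetwork | None = None,
    binning=None,
) -> TabularDataset:
    """Generate the boosted dataset ``BB`` for one fraction.

    A network is learned and fitted on the discretized audited dataset (or
    passed in, so the three fractions can share one fit); each uncertain row's
    offspring are drawn by likelihood weighting with the row's protected value
    plus its values on the top-k ordered attributes clamped. Rows whose
    evidence has zero likelihood fall back to protected-only evidence; rows
    still contradictory are skipped and their counts redistributed.
    """
    if len(plan.counts) != d_unc.n_rows:
        raise ValueError("plan is inconsistent with the uncertain set size")
    schema = d_bias.schema
    rng = np.random.default_rng(seed)
    if network is None:
        disc, binning = discretize(d_bias)
        dag = bayesnet.learn_structure(disc, seed=int(rng.integers(2**31)))
        network = bayesnet.fit_parameters(disc, dag)
    assert binning is not None

    # discretize the uncertain rows with the SAME binning as the audited data
    unc_frame = d_unc.frame.copy()
    for name in binning.bins:
        unc_frame[name] = binning.assign(name, unc_frame[name].to_numpy(dtype=float))

    top_vars = ordering.top(
        plan.evidence_depth, exclude=(schema.protected_name, schema.target_name)
    )
    groups: dict[tuple, int] = {}
    group_order: list[tuple] = []
    for i in range(len(unc_frame)):
        key = _row_evidence(unc_frame.iloc[i], schema.protected_name, top_vars)
        if key not in groups:
            groups[key] = 0
            group_order.append(key)
        groups[key] += int(plan.counts[i])

    # resolve each group's workable evidence up front so skipped mass can be
    # redistributed before sampling
    resolved: list[tuple[tuple, int]] = []
    skipped = 0
    for key in group_order:
        m = groups[key]
        if m == 0:
            continue
        ev = dict(key)
        try:
            bayesnet.sample_with_evidence(network, ev, 1, seed=0, n_proposals=64)
            resolved.append((key, m))
            continue
        except bayesnet.NetworkError:
            pass
        ev_fallback = {schema.protected_name: ev[schema.protected_name]}
        try:
            bayesnet.sample_with_evidence(network, ev_fallback, 1, seed=0, n_proposals=64)
            logger.info("evidence fell back to protected-only for %r", key)
            resolved.append((tuple(ev_fallback.items()), m))
        except bayesnet.NetworkError:
            warnings.warn(f"contradictory evidence skipped: {key!r}")
            skipped += m
    if not resolved:
        raise RuntimeError("every uncertain row's evidence was contradictory")
    for j in range(skipped):
        key, m = resolved[j % len(resolved)]
        resolved[j % len(resolved)] = (key, m + 1)

    chunks = []
    for key, m in resolved:
        frame = bayesnet.sample_with_evidence(
            network, dict(key), m, seed=int(rng.integers(2**31))
        )
        chunks.append(frame)
    synth_disc = TabularDataset(
        _discrete_schema(network, schema),
        pd.concat(chunks, ignore_index=True),
        role="boosted",
    )
    synth = undiscretize(synth_disc, binning, seed=int(rng.integers(2**31)), numeric_schema=schema)

    merged = pd.concat([d_bias.frame, synth.frame], ignore_index=True)
    provenance = np.concatenate(
        [np.full(d_bias.n_rows, "original", dtype=object),
         np.full(synth.n_rows, "synthetic", dtype=object)]
    )
    return TabularDataset(schema, merged, role="boosted", provenance=provenance)


def _discrete_schema(network: bayesnet.BayesianNetwork, schema) -> "TabularDataset.schema":
    from .core_data import Schema, Variable

    variables = tuple(
        Variable(v.name, CATEGORICAL, network.level_index[v.name])
        if v.kind != CATEGORICAL
        else v
        for v in schema.variables
    )
    return Schema(variables, schema.target_name, schema.protected_name)


@dataclass
class PipelineResult:
    boosted: dict[float, TabularDataset]
    d_unc: TabularDataset
    report: pd.DataFrame
    ordering: AttributeOrdering
    thresholds: tuple[float, float]
    manifest: dict


def bayesboost_pipeline(
    d_bias: TabularDataset,
    config: UncertaintyConfig | None = None,
    fractions: tuple[float, ...] = (0.5, 1.0, 2.0),
    evidence_depth: int = 3,
    seed: int = 0,
) -> PipelineResult:
    """Detection + correction end to end on one audited dataset.

    Stratified validation split on the protected attribute, Naive Bayes
    training, optional threshold calibration, uncertain-set extraction,
    attribute ordering, then one boosted dataset per requested fraction. The
    manifest records every seed and parameter of the run.
    """
    config = config or UncertaintyConfig()
    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(2**31))
    validation, train = stratified_split(
        d_bias, d_bias.schema.protected_name, config.validation_fraction, split_seed
    )
    model = train_nb(train)
    if config.calibrate:
        p1, p2 = calibrate_thresholds(d_bias, config, seed=int(rng.integers(2**31)))
    else:
        p1, p2 = config.p1, config.p2
    d_unc, _ = extract_uncertain(model, validation, p1, p2)
    report = representation_report(d_bias, d_unc)
    ordering = order_attributes(d_bias, d_unc)
    logger.info(
        "pipeline: |D_Bias|=%d |D_Unc|=%d thresholds=(%.3f, %.3f) O=%s",
        d_bias.n_rows, d_unc.n_rows, p1, p2,
        [n for n, _ in ordering.entries[:5]],
    )

    disc, binning = discretize(d_bias)
    dag = bayesnet.learn_structure(disc, seed=int(rng.integers(2**31)))
    network = bayesnet.fit_parameters(disc, dag)

    boosted = {}
    boost_seeds = {}
    for fraction in fractions:
        plan = compute_m(d_bias.n_rows, d_unc.n_rows, fraction, evidence_depth)
        s = int(rng.integers(2**31))
        boost_seeds[fraction] = s
        boosted[fraction] = boost(
            d_bias, d_unc, plan, ordering, seed=s, network=network, binning=binning
        )
    manifest = {
        "seed": seed,
        "split_seed": split_seed,
        "boost_seeds": {str(k): v for k, v in boost_seeds.items()},
        "thresholds": [p1, p2],
        "fractions": list(fractions),
        "evidence_depth": evidence_depth,
        "n_bias": d_bias.n_rows,
        "n_unc": d_unc.n_rows,
        "ordering": [[n, float(s)] for n, s in ordering.entries],
    }
    return PipelineResult(boosted, d_unc, report, ordering, (p1, p2), manifest)
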