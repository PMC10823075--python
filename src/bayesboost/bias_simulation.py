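"""Controlled injection of representation bias via a two-network pipeline.

The simulation experiments need datasets with a *known* under-representation:
a Bayesian network is learned from the source data, the protected attribute's
distribution is overridden to the desired post-bias marginal, an intermediate
sample is drawn by logic sampling, a SECOND network is learned from that
sample (fully separating the biased data from the original rows), and the
final biased dataset is drawn from it. Numeric variables travel through the
pipeline discretized and are inverted at the end.

An evidence-conditioned mechanism is also available: instead of overriding
the protected node's table, per-level quotas are drawn with the level clamped
as evidence.
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
    undiscretize,
)

logger = logging.getLogger("bayesboost")


class BiasInjectionError(RuntimeError):
    """The injected marginal drifted or the spec is inconsistent with the data."""


@dataclass(frozen=True)
class BiasSpec:
    """Desired post-bias protected marginal and pipeline sample sizes."""

    protected_name: str
    target_distribution: dict[str, float]
    n_out: int
    n_intermediate: int | None = None  # defaults to n_out
    mechanism: str = "cpt"  # or "evidence"
    #: constrain the protected attribute to be a root of both learned networks.
    #: True preserves its influence on the outcomes while the marginal is
    #: rewritten (exogenous-demographic reading); False reproduces the naive
    #: override on a freely learned structure, which severs the protected
    #: attribute's dependencies whenever the learner orients it as a child —
    #: a harsher corruption that also degrades downstream classifiers.
    protected_as_root: bool = True

    def __post_init__(self) -> None:
        probs = np.array(list(self.target_distribution.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("target_distribution must be a valid probability vector")
        if self.n_out < 100 or (self.n_intermediate or self.n_out) < 100:
            raise ValueError("n_out and n_intermediate must be >= 100")
        if self.mechanism not in ("cpt", "evidence"):
            raise ValueError("mechanism must be 'cpt' or 'evidence'")
        if np.any(probs == 1.0):
            warnings.warn("degenerate (one-hot) target distribution requested")


def shrink_level(
    shares: dict[str, float], level: str, new_share: float
) -> dict[str, float]:
    """Move one level to ``new_share``, rescaling the others proportionally."""
    if level not in shares:
        raise KeyError(f"level {level!r} not present")
    rest = 1.0 - shares[level]
    scale = (1.0 - new_share) / rest
    out = {k: v * scale for k, v in shares.items()}
    out[level] = new_share
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def measure_representation(dataset: TabularDataset, variable: str) -> dict[str, float]:
    """Empirical level shares of a categorical variable (sum to 1)."""
    if dataset.n_rows == 0:  # pragma: no cover - dataset invariant forbids this
        raise ValueError("empty dataset")
    var = dataset.schema.var(variable)
    if var.kind != CATEGORICAL:
        raise ValueError(f"{variable!r} is not categorical")
    counts = dataset.frame[variable].value_counts()
    return {level: float(counts.get(level, 0)) / dataset.n_rows for level in var.levels}


def inject_bias(dataset: TabularDataset, spec: BiasSpec, seed: int) -> TabularDataset:
    """Produce a biased dataset whose protected marginal matches the spec.

    Deterministic under the seed. Fails loudly (:class:`BiasInjectionError`)
    if the realized protected marginal drifts more than 3 Monte-Carlo standard
    errors from the target on any level — the double-network pipeline must not
    move it.
    """
    schema = dataset.schema
    prot = schema.var(spec.protected_name)
    missing = [
        lv
        for lv, p in spec.target_distribution.items()
        if p > 0 and lv not in set(dataset.frame[spec.protected_name])
    ]
    if missing:
        raise BiasInjectionError(
            f"protected level(s) {missing!r} absent from the source data"
        )
    target_vec = np.array(
        [spec.target_distribution.get(lv, 0.0) for lv in prot.levels], dtype=float
    )
    n_mid = spec.n_intermediate or spec.n_out
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=5)

    # the protected attribute is constrained to be a root in both learned
    # networks: a demographic is exogenous, and a marginal override on a
    # parented node would sever its influence on the outcomes
    discrete, binning = discretize(dataset)
    roots = (spec.protected_name,) if spec.protected_as_root else ()
    dag1 = bayesnet.learn_structure(discrete, seed=int(seeds[0]), roots=roots)
    net1 = bayesnet.fit_parameters(discrete, dag1)

    if spec.mechanism == "cpt":
        net1 = bayesnet.override_cpt(net1, spec.protected_name, target_vec)
        mid_frame = bayesnet.logic_sample(net1, n_mid, seed=int(seeds[1]))
    else:
        chunks = []
        quotas = np.floor(target_vec * n_mid).astype(int)
        for i in np.argsort(-(target_vec * n_mid - quotas)):
            if quotas.sum() >= n_mid:
                break
            quotas[i] += 1
        for lv, quota in zip(prot.levels, quotas):
            if quota == 0:
                continue
            chunks.append(
                bayesnet.sample_with_evidence(
                    net1, {spec.protected_name: lv}, int(quota), seed=int(seeds[1]) + hash(lv) % 997
                )
            )
        mid_frame = (
            pd.concat(chunks, ignore_index=True)
            .sample(frac=1.0, random_state=int(seeds[1]) % (2**31))
            .reset_index(drop=True)
        )

    mid = TabularDataset(discrete.schema, mid_frame, role="biased")
    dag2 = bayesnet.learn_structure(mid, seed=int(seeds[2]), roots=roots)
    net2 = bayesnet.fit_parameters(mid, dag2)
    out_frame = bayesnet.logic_sample(net2, spec.n_out, seed=int(seeds[3]))
    out_discrete = TabularDataset(discrete.schema, out_frame, role="biased")
    out = undiscretize(out_discrete, binning, seed=int(seeds[4]), numeric_schema=schema)

    realized = measure_representation(out, spec.protected_name)
    for lv, p in zip(prot.levels, target_vec):
        se = float(np.sqrt(max(p * (1 - p), 1e-12) * (1.0 / n_mid + 1.0 / spec.n_out)))
        drift = abs(realized[lv] - p)
        if drift > 3 * se + 3.0 / spec.n_out:
            raise BiasInjectionError(
                f"injected marginal drifted on {lv!r}: target {p:.4f}, got "
                f"{realized[lv]:.4f} (3 SE = {3 * se:.4f})"
            )
    logger.info(
        "inject_bias: protected=%s target=%s realized=%s",
        spec.protected_name,
        {k: round(v, 3) for k, v in spec.target_distribution.items()},
        {k: round(v, 3) for k, v in realized.items()},
    )
    return out
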