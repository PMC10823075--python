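"""Seeded CPRD-like synthetic datasets generated from pinned networks.

The real CPRD cardiovascular and Covid-19 synthetic datasets are
licence-restricted; these fixtures emulate their *shape* — a ~10-level
ethnicity and region, binary gender, numeric age/BMI/systolic blood pressure,
smoking, and minority-prevalence binary disease targets — from hand-authored
Bayesian networks committed as YAML, so every downstream detection or
correction experiment has exact ground truth to recover.

Disease nodes follow logistic risk formulas over age, smoking, BMI, gender
and ethnicity (South Asian groups carry elevated cardiovascular and diabetes
risk, mirroring the qualitative UK epidemiology the originals encode); the
numeric columns are emitted by drawing uniformly within each sampled band.
Exact CPTs live in ``bayesboost/data/*.yaml``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .bayesnet import BayesianNetwork, logic_sample, override_cpt
from .core_data import CATEGORICAL, NUMERIC, Schema, TabularDataset, Variable

_INTERVAL = re.compile(r"^\[([-\d.eE+]+),([-\d.eE+]+)\)$")

#: numeric age bands used to derive the Covid fixture's age_category column
AGE_CATEGORY_EDGES = (18.0, 35.0, 50.0, 65.0, 80.0, 95.0)
AGE_CATEGORY_LABELS = ("18-34", "35-49", "50-64", "65-79", "80+")


@dataclass(frozen=True)
class FixtureSpec:
    """Which fixture to build, at what size, under which seed."""

    name: str
    n_rows: int
    seed: int
    cpt_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("cvd_like", "covid_like", "toy"):
            raise ValueError(f"unknown fixture {self.name!r}")
        if self.name != "toy" and self.n_rows < 100:
            raise ValueError("cvd_like/covid_like fixtures require n_rows >= 100")


def _load_network(name: str) -> BayesianNetwork:
    path = resources.files("bayesboost.data") / f"{name}.yaml"
    return BayesianNetwork.from_dict(__import__("yaml").safe_load(path.read_text()))


def _parse_interval(label: str) -> tuple[float, float]:
    m = _INTERVAL.match(label)
    if not m:
        raise ValueError(f"band label {label!r} is not an interval")
    return float(m.group(1)), float(m.group(2))


def _bands_to_numeric(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(len(labels))
    for label in pd.unique(labels):
        lo, hi = _parse_interval(label)
        mask = labels == label
        out[mask] = lo + rng.random(mask.sum()) * (hi - lo)
    return out


def age_to_category(age: np.ndarray) -> np.ndarray:
    """Pure derivation of the Covid fixture's age_category from numeric age."""
    idx = np.searchsorted(np.asarray(AGE_CATEGORY_EDGES[1:-1]), age, side="right")
    return np.asarray(AGE_CATEGORY_LABELS, dtype=object)[idx]


def make_toy_bn() -> BayesianNetwork:
    """The pinned 2-node enumerable oracle network (P(A=1)=0.3, B depends on A)."""
    return _load_network("toy_ab")


def cvd_network() -> BayesianNetwork:
    return _load_network("cvd_like")


def covid_network() -> BayesianNetwork:
    return _load_network("covid_like")


def make_cvd_like(
    n: int,
    seed: int,
    target: str = "stroke_heart_attack",
    protected: str = "ethnicity",
    cpt_overrides: dict | None = None,
) -> TabularDataset:
    """CVD-like fixture: mixed demographics + risk factors + 3 binary targets.

    Positives are the minority class by construction (band-averaged prevalence
    around 8–15% per target). ``cpt_overrides`` replaces a root node's
    distribution before sampling, e.g. to pre-skew ethnicity.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for the cvd_like fixture")
    net = cvd_network()
    for var, dist in (cpt_overrides or {}).items():
        net = override_cpt(net, var, dist)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    frame = logic_sample(net, n, seed=int(rng.integers(2**31)))
    for col in ("age", "bmi", "sbp"):
        frame[col] = _bands_to_numeric(frame[col].to_numpy(dtype=object), rng)
    variables = (
        Variable("gender", CATEGORICAL, net.levels("gender")),
        Variable("ethnicity", CATEGORICAL, net.levels("ethnicity")),
        Variable("region", CATEGORICAL, net.levels("region")),
        Variable("age", NUMERIC, bounds=(25.0, 80.0)),
        Variable("smoking", CATEGORICAL, net.levels("smoking")),
        Variable("bmi", NUMERIC, bounds=(18.0, 45.0)),
        Variable("sbp", NUMERIC, bounds=(100.0, 190.0)),
        Variable("stroke_heart_attack", CATEGORICAL, ("0", "1")),
        Variable("atrial_fibrillation", CATEGORICAL, ("0", "1")),
        Variable("type2_diabetes", CATEGORICAL, ("0", "1")),
    )
    schema = Schema(variables, target_name=target, protected_name=protected)
    return TabularDataset(schema, frame, role="ground_truth")


def make_covid_like(
    n: int,
    seed: int,
    protected: str = "region",
) -> TabularDataset:
    """Covid-like fixture: demographics, numeric age with derived age bands,
    and a binary covid_diagnosis target."""
    if n < 100:
        raise ValueError("n must be >= 100 for the covid_like fixture")
    net = covid_network()
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    frame = logic_sample(net, n, seed=int(rng.integers(2**31)))
    frame["age"] = _bands_to_numeric(frame["age"].to_numpy(dtype=object), rng)
    frame["age_category"] = age_to_category(frame["age"].to_numpy(dtype=float))
    variables = (
        Variable("gender", CATEGORICAL, net.levels("gender")),
        Variable("region", CATEGORICAL, net.levels("region")),
        Variable("age", NUMERIC, bounds=(18.0, 95.0)),
        Variable("age_category", CATEGORICAL, AGE_CATEGORY_LABELS),
        Variable("covid_diagnosis", CATEGORICAL, ("0", "1")),
    )
    schema = Schema(variables, target_name="covid_diagnosis", protected_name=protected)
    return TabularDataset(schema, frame, role="ground_truth")


def make_fixture(spec: FixtureSpec) -> TabularDataset:
    if spec.name == "cvd_like":
        return make_cvd_like(spec.n_rows, spec.seed, cpt_overrides=spec.cpt_overrides)
    if spec.name == "covid_like":
        return make_covid_like(spec.n_rows, spec.seed)
    raise ValueError("the toy fixture is a network, not a dataset; use make_toy_bn()")
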