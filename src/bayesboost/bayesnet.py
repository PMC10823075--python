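"""Discrete Bayesian networks: learning, fitting, and sampling.

This is the generative engine used twice in the pipeline — once to inject a
controlled representation bias (override a node's distribution, then sample),
and once to oversample under-represented strata (sample conditioned on
evidence taken from uncertain rows).

Everything operates on fully discrete data: variables are categorical with an
explicit ordered level set, conditional probability tables (CPTs) are dense
arrays of shape ``(n_parent_configurations, n_levels)``, and parent
configurations are indexed in mixed radix (row-major over the ordered parent
list). Structure learning is greedy hill climbing over add/remove/reverse
edge moves scoring BIC, with deterministic lexicographic tie-breaking;
parameters are Laplace-smoothed relative frequencies. Forward ("logic")
sampling walks a topological order; evidence-conditioned sampling uses
likelihood weighting followed by weighted resampling. A brute-force joint
enumeration (:func:`exact_marginal`) serves as the inference oracle on small
networks.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("bayesboost")

Evidence = Mapping[str, str]


class NetworkError(ValueError):
    """Invalid network construction or impossible evidence."""


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for p, c in self.edges:
            if p not in node_set or c not in node_set:
                raise NetworkError(f"edge ({p!r}, {c!r}) references unknown node")
        self.topological_order()  # raises on a cycle

    def parents(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        ps = [p for p, c in self.edges if c == node]
        return tuple(sorted(ps, key=order.__getitem__))

    def topological_order(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in self.edges:
            indeg[c] += 1
            children[p].append(c)
        ready = [n for n in self.nodes if indeg[n] == 0]
        out: list[str] = []
        while ready:
            n = ready.pop(0)
            out.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(out) != len(self.nodes):
            raise NetworkError("graph contains a cycle")
        return out


@dataclass
class Cpt:
    """Conditional probability table of one node given its ordered parents.

    ``table[j, k]`` is P(child = level_k | parent configuration j), with j the
    row-major mixed-radix code over the parent level counts.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def validate(self) -> None:
        if np.any(self.table < 0):
            raise NetworkError(f"CPT for {self.child!r} has negative entries")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise NetworkError(f"CPT rows for {self.child!r} do not sum to 1")


@dataclass
class BayesianNetwork:
    """A DAG plus one CPT per node and an ordered level index per variable."""

    dag: Dag
    cpts: dict[str, Cpt]
    level_index: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise NetworkError(f"missing CPT for {node!r}")
            cpt = self.cpts[node]
            if cpt.parents != self.dag.parents(node):
                raise NetworkError(f"CPT parents for {node!r} do not match the DAG")
            q = int(np.prod([len(self.level_index[p]) for p in cpt.parents])) if cpt.parents else 1
            r = len(self.level_index[node])
            if cpt.table.shape != (q, r):
                raise NetworkError(f"CPT for {node!r} has shape {cpt.table.shape}, expected {(q, r)}")
            cpt.validate()

    def levels(self, node: str) -> tuple[str, ...]:
        return self.level_index[node]

    def n_joint_states(self) -> int:
        out = 1
        for node in self.dag.nodes:
            out *= len(self.level_index[node])
        return out

    def copy(self) -> "BayesianNetwork":
        return BayesianNetwork(
            dag=self.dag,
            cpts={n: Cpt(c.child, c.parents, c.table.copy()) for n, c in self.cpts.items()},
            level_index=dict(self.level_index),
        )

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for name in self.dag.nodes:
            cpt = self.cpts[name]
            nodes.append(
                {
                    "name": name,
                    "levels": list(self.level_index[name]),
                    "parents": list(cpt.parents),
                    "table": [[float(x) for x in row] for row in cpt.table],
                }
            )
        return {"nodes": nodes}

    @classmethod
    def from_dict(cls, d: Mapping) -> "BayesianNetwork":
        names = [n["name"] for n in d["nodes"]]
        level_index = {n["name"]: tuple(str(x) for x in n["levels"]) for n in d["nodes"]}
        edges = tuple(
            (p, n["name"]) for n in d["nodes"] for p in n.get("parents", [])
        )
        dag = Dag(tuple(names), edges)
        cpts = {
            n["name"]: Cpt(n["name"], tuple(n.get("parents", [])), np.asarray(n["table"], dtype=float))
            for n in d["nodes"]
        }
        return cls(dag=dag, cpts=cpts, level_index=level_index)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BayesianNetwork":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Data encoding helpers
# ---------------------------------------------------------------------------

def _as_frame(data) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Accept a plain DataFrame or a TabularDataset-like object."""
    if hasattr(data, "frame") and hasattr(data, "schema"):
        frame = data.frame
        levels = {
            v.name: tuple(v.levels) for v in data.schema.variables if v.levels is not None
        }
        non_cat = [v.name for v in data.schema.variables if v.levels is None]
        if non_cat:
            raise NetworkError(f"dataset must be discretized first (numeric: {non_cat})")
        return frame, levels
    frame = pd.DataFrame(data)
    levels = {c: tuple(sorted(frame[c].astype(str).unique())) for c in frame.columns}
    return frame, levels


def _encode(frame: pd.DataFrame, levels: Mapping[str, tuple[str, ...]]) -> dict[str, np.ndarray]:
    codes = {}
    for name, lv in levels.items():
        lookup = {l: i for i, l in enumerate(lv)}
        codes[name] = frame[name].astype(str).map(lookup).to_numpy(dtype=np.int64)
    return codes


def _config_codes(codes: Mapping[str, np.ndarray], parents: Sequence[str],
                  levels: Mapping[str, tuple[str, ...]]) -> np.ndarray:
    """Row-major mixed-radix code of each row's parent configuration."""
    n = len(next(iter(codes.values()))) if codes else 0
    if not parents:
        return np.zeros(n, dtype=np.int64)
    out = np.zeros_like(codes[parents[0]])
    for p in parents:
        out = out * len(levels[p]) + codes[p]
    return out


# ---------------------------------------------------------------------------
# Scoring and structure learning
# ---------------------------------------------------------------------------

def _family_score(child_codes: np.ndarray, cfg_codes: np.ndarray, r: int, q: int) -> float:
    """BIC contribution of one (child | parents) family."""
    n = len(child_codes)
    counts = np.bincount(cfg_codes * r + child_codes, minlength=q * r).reshape(q, r)
    row_tot = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / row_tot[:, None]), 0.0).sum()
    return float(ll - 0.5 * np.log(n) * q * (r - 1))


def bic_score(data, dag: Dag) -> float:
    """Total BIC of a DAG on a discrete dataset (higher is better)."""
    frame, levels = _as_frame(data)
    codes = _encode(frame, levels)
    total = 0.0
    for node in dag.nodes:
        parents = dag.parents(node)
        q = int(np.prod([len(levels[p]) for p in parents])) if parents else 1
        cfg = _config_codes(codes, parents, levels)
        total += _family_score(codes[node], cfg, len(levels[node]), q)
    return total


def learn_structure(
    data, max_parents: int = 3, seed: int = 0, roots: Sequence[str] = ()
) -> Dag:
    """Greedy hill climbing over add/remove/reverse moves maximizing BIC.

    Deterministic: candidate moves are scanned in a fixed lexicographic order
    and ties go to the first-scanned move, so the seed only matters for
    optional random restarts (none by default).

    ``roots`` names variables that may not receive parents (they can still be
    parents of others). Exogenous demographics are usually declared roots so
    that a later marginal override cannot sever their influence on outcomes.
    """
    frame, levels = _as_frame(data)
    nodes = list(frame.columns)
    if len(nodes) < 2:
        warnings.warn("fewer than 2 variables; returning an empty-edge DAG")
        return Dag(tuple(nodes), ())
    codes = _encode(frame, levels)

    parents: dict[str, list[str]] = {n: [] for n in nodes}
    cache: dict[tuple[str, tuple[str, ...]], float] = {}
    node_order = {n: i for i, n in enumerate(nodes)}
    root_set = set(roots)

    def family(child: str, ps: Sequence[str]) -> float:
        key = (child, tuple(sorted(ps, key=node_order.__getitem__)))
        if key not in cache:
            q = int(np.prod([len(levels[p]) for p in key[1]])) if key[1] else 1
            cfg = _config_codes(codes, key[1], levels)
            cache[key] = _family_score(codes[child], cfg, len(levels[child]), q)
        return cache[key]

    def creates_cycle(parent: str, child: str) -> bool:
        # would adding parent -> child close a cycle? i.e. is child an ancestor of parent
        stack, seen = [parent], set()
        while stack:
            cur = stack.pop()
            if cur == child:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(parents[cur])
        return False

    while True:
        best: tuple[float, tuple] | None = None
        for child in nodes:
            for parent in nodes:
                if parent == child:
                    continue
                if parent not in parents[child]:
                    if (
                        child not in root_set
                        and len(parents[child]) < max_parents
                        and not creates_cycle(parent, child)
                    ):
                        delta = family(child, parents[child] + [parent]) - family(child, parents[child])
                        move = ("add", parent, child)
                        if best is None or delta > best[0] + 1e-12:
                            best = (delta, move)
                else:
                    delta = family(child, [p for p in parents[child] if p != parent]) - family(
                        child, parents[child]
                    )
                    move = ("remove", parent, child)
                    if best is None or delta > best[0] + 1e-12:
                        best = (delta, move)
                    # reverse parent -> child into child -> parent
                    if parent not in root_set and len(parents[parent]) < max_parents:
                        parents[child].remove(parent)
                        cyclic = creates_cycle(child, parent)
                        parents[child].append(parent)
                        if not cyclic:
                            delta_r = (
                                family(child, [p for p in parents[child] if p != parent])
                                - family(child, parents[child])
                                + family(parent, parents[parent] + [child])
                                - family(parent, parents[parent])
                            )
                            move = ("reverse", parent, child)
                            if best is None or delta_r > best[0] + 1e-12:
                                best = (delta_r, move)
        if best is None or best[0] <= 1e-9:
            break
        _, (op, parent, child) = best
        if op == "add":
            parents[child].append(parent)
        elif op == "remove":
            parents[child].remove(parent)
        else:
            parents[child].remove(parent)
            parents[parent].append(child)

    edges = tuple(
        (p, c)
        for c in nodes
        for p in sorted(parents[c], key=node_order.__getitem__)
    )
    return Dag(tuple(nodes), edges)


# ---------------------------------------------------------------------------
# Parameter fitting
# ---------------------------------------------------------------------------

def fit_parameters(data, dag: Dag, laplace_alpha: float = 1.0) -> BayesianNetwork:
    """Laplace-smoothed CPT estimation: (count + alpha) / (total + alpha * r).

    A parent configuration never observed yields a uniform row (pure alpha, or
    explicit uniform when alpha == 0), logged at debug level.
    """
    frame, levels = _as_frame(data)
    codes = _encode(frame, levels)
    cpts = {}
    for node in dag.nodes:
        ps = dag.parents(node)
        r = len(levels[node])
        q = int(np.prod([len(levels[p]) for p in ps])) if ps else 1
        cfg = _config_codes(codes, ps, levels)
        counts = np.bincount(cfg * r + codes[node], minlength=q * r).reshape(q, r).astype(float)
        row_tot = counts.sum(axis=1)
        unseen = row_tot == 0
        if unseen.any():
            logger.debug("%d unseen parent configuration(s) for %r: uniform rows", unseen.sum(), node)
        if laplace_alpha > 0:
            table = (counts + laplace_alpha) / (row_tot + laplace_alpha * r)[:, None]
        else:
            with np.errstate(invalid="ignore"):
                table = counts / row_tot[:, None]
            table[unseen] = 1.0 / r
        cpts[node] = Cpt(node, ps, table)
    return BayesianNetwork(dag=dag, cpts=cpts, level_index={n: tuple(levels[n]) for n in dag.nodes})


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_node(table_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of one level per row from per-row probability vectors."""
    cum = np.cumsum(table_rows, axis=1)
    u = rng.random(len(table_rows))
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


def logic_sample(network: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Ancestral forward sampling of ``n`` rows in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for node in network.dag.topological_order():
        cpt = network.cpts[node]
        cfg = _config_codes(codes, cpt.parents, network.level_index) if cpt.parents else np.zeros(n, dtype=np.int64)
        codes[node] = _sample_node(cpt.table[cfg], rng)
    return _decode(codes, network)


def _decode(codes: Mapping[str, np.ndarray], network: BayesianNetwork) -> pd.DataFrame:
    out = {}
    for node in network.dag.nodes:
        lv = np.array(network.level_index[node], dtype=object)
        out[node] = lv[codes[node]]
    return pd.DataFrame(out)


def _validate_evidence(network: BayesianNetwork, evidence: Evidence) -> None:
    for var, val in evidence.items():
        if var not in network.level_index:
            raise NetworkError(f"evidence variable {var!r} not in network")
        if val not in network.level_index[var]:
            raise NetworkError(f"evidence value {val!r} is not a level of {var!r}")


def sample_with_evidence(
    network: BayesianNetwork,
    evidence: Evidence,
    n: int,
    seed: int,
    n_proposals: int | None = None,
) -> pd.DataFrame:
    """Likelihood weighting: clamp evidence, weight, resample with replacement.

    Evidence variables are fixed at their assigned values in every output row;
    the remaining variables are distributed as the conditional given the
    evidence (up to Monte-Carlo error). An effective sample size below
    ``n / 10`` triggers a logged warning; all-zero weights raise
    :class:`NetworkError` naming the contradictory assignment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _validate_evidence(network, evidence)
    rng = np.random.default_rng(seed)
    m = n_proposals or max(4 * n, 512)
    codes: dict[str, np.ndarray] = {}
    log_w = np.zeros(m)
    contrib: dict[str, np.ndarray] = {}
    for node in network.dag.topological_order():
        cpt = network.cpts[node]
        cfg = _config_codes(codes, cpt.parents, network.level_index) if cpt.parents else np.zeros(m, dtype=np.int64)
        if node in evidence:
            k = network.level_index[node].index(evidence[node])
            codes[node] = np.full(m, k, dtype=np.int64)
            p = cpt.table[cfg, k]
            contrib[node] = p
            with np.errstate(divide="ignore"):
                log_w += np.log(p)
        else:
            codes[node] = _sample_node(cpt.table[cfg], rng)
    w = np.exp(log_w - log_w[np.isfinite(log_w)].max()) if np.isfinite(log_w).any() else np.zeros(m)
    w[~np.isfinite(log_w)] = 0.0
    total = w.sum()
    if total <= 0:
        zero_vars = [v for v, p in contrib.items() if np.all(p == 0)]
        culprit = zero_vars[0] if zero_vars else min(contrib, key=lambda v: contrib[v].max())
        raise NetworkError(
            f"evidence {{{culprit!r}: {evidence[culprit]!r}}} has zero likelihood under the network"
        )
    ess = total ** 2 / np.square(w).sum()
    if ess < n / 10:
        logger.warning("likelihood weighting ESS %.1f < n/10 (n=%d); estimates may be noisy", ess, n)
    pick = rng.choice(m, size=n, replace=True, p=w / total)
    return _decode({k: v[pick] for k, v in codes.items()}, network)


# ---------------------------------------------------------------------------
# Exact inference oracle and CPT override
# ---------------------------------------------------------------------------

def exact_marginal(
    network: BayesianNetwork,
    variable: str,
    evidence: Evidence | None = None,
    max_states: int = 10 ** 6,
) -> np.ndarray:
    """Exact conditional marginal P(variable | evidence) via joint enumeration.

    Only for small networks (joint state space <= ``max_states``); larger ones
    raise with advice to sample instead.
    """
    evidence = evidence or {}
    _validate_evidence(network, evidence)
    total = network.n_joint_states()
    if total > max_states:
        raise NetworkError(
            f"joint state space ({total}) too large to enumerate; use sampling instead"
        )
    nodes = list(network.dag.nodes)
    dims = [len(network.level_index[nd]) for nd in nodes]
    grids = np.unravel_index(np.arange(total), dims)
    codes = {nd: g.astype(np.int64) for nd, g in zip(nodes, grids)}
    prob = np.ones(total)
    for node in nodes:
        cpt = network.cpts[node]
        cfg = _config_codes(codes, cpt.parents, network.level_index) if cpt.parents else np.zeros(total, dtype=np.int64)
        prob *= cpt.table[cfg, codes[node]]
    mask = np.ones(total, dtype=bool)
    for var, val in evidence.items():
        mask &= codes[var] == network.level_index[var].index(val)
    prob = np.where(mask, prob, 0.0)
    z = prob.sum()
    if z <= 0:
        raise NetworkError("evidence has zero probability under the network")
    r = len(network.level_index[variable])
    out = np.bincount(codes[variable], weights=prob, minlength=r)
    return out / z


def override_cpt(
    network: BayesianNetwork, variable: str, new_distribution: Sequence[float]
) -> BayesianNetwork:
    """Replace a node's CPT with one fixed distribution for EVERY parent row.

    This makes ``new_distribution`` the variable's marginal regardless of its
    parents — the mechanism used to force a target representation level.
    """
    vec = np.asarray(new_distribution, dtype=float)
    r = len(network.level_index[variable])
    if vec.shape != (r,):
        raise NetworkError(f"distribution must have {r} entries for {variable!r}")
    if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
        raise NetworkError("new_distribution is not a valid probability vector")
    out = network.copy()
    q = out.cpts[variable].table.shape[0]
    out.cpts[variable].table = np.tile(vec, (q, 1))
    return out


def enumerate_dags(nodes: Sequence[str]) -> list[Dag]:
    """All DAGs over a (tiny) node set — exhaustive-search oracle for tests."""
    nodes = tuple(nodes)
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    out = []
    for mask in itertools.product([False, True], repeat=len(pairs)):
        edges = tuple(p for p, keep in zip(pairs, mask) if keep)
        if any((b, a) in edges for a, b in edges):
            continue
        try:
            out.append(Dag(nodes, edges))
        except NetworkError:
            continue
    return out
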