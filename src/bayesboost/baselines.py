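"""Comparison resamplers: SMOTE, AdaSyn, and a simplified Fair-SMOTE.

All three follow the SMOTE-NC convention for mixed data: distances are
Euclidean over standardized numerics plus a constant penalty (the median of
the standardized numeric deviations) per categorical mismatch; synthetic rows
interpolate numerics uniformly along the segment to a sampled neighbor and
set categoricals by majority vote among the k nearest neighbors.

SMOTE oversamples the minority class to exact balance; AdaSyn allocates the
synthetic rows adaptively, proportional to how majority-dominated each
minority row's neighborhood is. The simplified Fair-SMOTE binarizes the
protected attribute through a privileged/unprivileged mapping and oversamples
each of the four (class x privilege) subgroups to the size of the largest;
it deliberately omits the situation-testing machinery of the full published
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_data import CATEGORICAL, TabularDataset

#: the privileged-group assumptions used when comparing against Fair-SMOTE
DEFAULT_PRIVILEGED = {
    "gender": ("M",),
    "ethnicity": ("White or not stated", "Other ethnic group"),
    "region": ("London", "South Central"),
}


@dataclass(frozen=True)
class PrivilegeMap:
    """Binary privileged/unprivileged partition of the protected levels."""

    protected_name: str
    privileged_levels: tuple[str, ...]

    def validate(self, dataset: TabularDataset) -> None:
        levels = set(dataset.schema.var(self.protected_name).levels)
        priv = set(self.privileged_levels)
        if not priv or not priv < levels:
            raise ValueError("privileged_levels must be a nonempty proper subset of the levels")


# ---------------------------------------------------------------------------
# Mixed-type SMOTE core
# ---------------------------------------------------------------------------

def _feature_arrays(dataset: TabularDataset):
    schema = dataset.schema
    num_names = [n for n in schema.numeric_names]
    cat_names = [n for n in schema.categorical_names if n != schema.target_name]
    num = dataset.frame[num_names].to_numpy(dtype=float) if num_names else np.empty((dataset.n_rows, 0))
    std = num.std(axis=0)
    std[std == 0] = 1.0
    num_z = num / std
    cat = np.empty((dataset.n_rows, len(cat_names)), dtype=object)
    for j, name in enumerate(cat_names):
        cat[:, j] = dataset.frame[name].to_numpy(dtype=object)
    med = float(np.median(num_z.std(axis=0))) if num_names else 1.0
    return num_names, cat_names, num, num_z, cat, med


def _sq_distances(num_z_a, cat_a, num_z_b, cat_b, med, chunk=2048):
    """Squared mixed distance between row sets A and B, chunked over A."""
    out = np.empty((len(num_z_a), len(num_z_b)))
    for start in range(0, len(num_z_a), chunk):
        sl = slice(start, start + chunk)
        d = cdist(num_z_a[sl], num_z_b, "sqeuclidean") if num_z_a.shape[1] else np.zeros(
            (len(num_z_a[sl]), len(num_z_b))
        )
        if cat_a.shape[1]:
            mism = (cat_a[sl, None, :] != cat_b[None, :, :]).sum(axis=2)
            d = d + (med ** 2) * mism
        out[sl] = d
    return out


def _knn(num_z_a, cat_a, num_z_b, cat_b, med, k, exclude_self: bool):
    d = _sq_distances(num_z_a, cat_a, num_z_b, cat_b, med)
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, :k]


def _vote(values: np.ndarray) -> object:
    levels, counts = np.unique(values.astype(str), return_counts=True)
    return sorted(levels[counts == counts.max()])[0]  # ties -> lexicographic


def _synthesize(
    dataset: TabularDataset,
    pool: np.ndarray,
    counts: np.ndarray,
    k: int,
    rng: np.random.Generator,
    label_value: str | None,
) -> pd.DataFrame:
    """Generate sum(counts) synthetic rows; counts are per pool row."""
    schema = dataset.schema
    num_names, cat_names, num, num_z, cat, med = _feature_arrays(dataset)
    k_eff = min(k, len(pool) - 1)
    if k_eff < k:
        warnings.warn(f"minority pool has only {len(pool)} rows; k reduced to {max(k_eff, 0)}")
    if k_eff < 1:
        rows = [dataset.frame.iloc[i].to_dict() for i, c in zip(pool, counts) for _ in range(int(c))]
        return pd.DataFrame(rows)
    nbrs = _knn(num_z[pool], cat[pool], num_z[pool], cat[pool], med, k_eff, exclude_self=True)
    # the categorical vote depends only on the source row's neighbor set
    votes = np.empty((len(pool), len(cat_names)), dtype=object)
    for local_i in range(len(pool)):
        nbr_rows = pool[nbrs[local_i]]
        for col_idx in range(len(cat_names)):
            votes[local_i, col_idx] = _vote(cat[nbr_rows, col_idx])
    src = np.repeat(np.arange(len(pool)), counts.astype(int))
    j_local = nbrs[src, rng.integers(k_eff, size=len(src))]
    u = rng.random(len(src))
    out = {}
    for col_idx, name in enumerate(num_names):
        a = num[pool[src], col_idx]
        b = num[pool[j_local], col_idx]
        out[name] = a + u * (b - a)
    for col_idx, name in enumerate(cat_names):
        out[name] = votes[src, col_idx]
    if label_value is not None:
        out[schema.target_name] = np.full(len(src), label_value, dtype=object)
    else:
        out[schema.target_name] = dataset.frame[schema.target_name].to_numpy(dtype=object)[pool[src]]
    return pd.DataFrame(out)


def _finish(dataset: TabularDataset, synth: pd.DataFrame) -> TabularDataset:
    if len(synth) == 0:
        return TabularDataset(
            dataset.schema,
            dataset.frame.copy(),
            role="baseline-output",
            provenance=np.full(dataset.n_rows, "original", dtype=object),
        )
    merged = pd.concat([dataset.frame, synth], ignore_index=True)
    provenance = np.concatenate(
        [np.full(dataset.n_rows, "original", dtype=object),
         np.full(len(synth), "synthetic", dtype=object)]
    )
    return TabularDataset(dataset.schema, merged, role="baseline-output", provenance=provenance)


# ---------------------------------------------------------------------------
# The three resamplers
# ---------------------------------------------------------------------------

def smote(dataset: TabularDataset, k_neighbors: int = 5, seed: int = 0) -> TabularDataset:
    """Oversample the minority class to exact 1:1 balance."""
    rng = np.random.default_rng(seed)
    y = dataset.labels()
    n1 = int(y.sum())
    minority = 1 if n1 <= len(y) - n1 else 0
    pool = np.flatnonzero(y == minority)
    n_new = len(y) - 2 * len(pool)
    if n_new <= 0:
        return _finish(dataset, pd.DataFrame())
    picks = rng.choice(len(pool), size=n_new, replace=True)
    counts = np.bincount(picks, minlength=len(pool))
    synth = _synthesize(dataset, pool, counts, k_neighbors, rng, str(minority))
    return _finish(dataset, synth)


def adasyn(dataset: TabularDataset, k_neighbors: int = 5, seed: int = 0) -> TabularDataset:
    """SMOTE with per-row counts proportional to majority-neighbor density."""
    rng = np.random.default_rng(seed)
    y = dataset.labels()
    n1 = int(y.sum())
    minority = 1 if n1 <= len(y) - n1 else 0
    pool = np.flatnonzero(y == minority)
    n_new = len(y) - 2 * len(pool)
    if n_new <= 0:
        return _finish(dataset, pd.DataFrame())
    num_names, cat_names, num, num_z, cat, med = _feature_arrays(dataset)
    k_eff = min(k_neighbors, dataset.n_rows - 1)
    all_nbrs = _knn(num_z[pool], cat[pool], num_z, cat, med, k_eff + 1, exclude_self=False)
    ratios = np.empty(len(pool))
    for local_i in range(len(pool)):
        nbr = [j for j in all_nbrs[local_i] if j != pool[local_i]][:k_eff]
        ratios[local_i] = (y[nbr] != minority).mean()
    if ratios.sum() == 0:
        warnings.warn("all minority neighborhoods are pure minority; uniform allocation")
        ratios[:] = 1.0
    weights = ratios / ratios.sum()
    counts = np.floor(weights * n_new).astype(int)
    remainder = n_new - counts.sum()
    order = np.argsort(-(weights * n_new - counts), kind="stable")
    counts[order[:remainder]] += 1
    synth = _synthesize(dataset, pool, counts, k_neighbors, rng, str(minority))
    return _finish(dataset, synth)


def fair_smote_simplified(
    dataset: TabularDataset,
    privilege_map: PrivilegeMap,
    k_neighbors: int = 5,
    seed: int = 0,
) -> TabularDataset:
    """Balance the four (class x privilege) subgroups to the largest's size.

    Original rows keep their protected levels; synthetic rows inherit levels
    by neighbor vote within their subgroup (so the privilege flag is stable).
    """
    privilege_map.validate(dataset)
    rng = np.random.default_rng(seed)
    y = dataset.labels()
    priv = dataset.frame[privilege_map.protected_name].isin(privilege_map.privileged_levels).to_numpy()
    subgroups = {}
    for cls in (0, 1):
        for flag in (True, False):
            idx = np.flatnonzero((y == cls) & (priv == flag))
            if idx.size == 0:
                name = f"class={cls}, {'privileged' if flag else 'unprivileged'}"
                raise ValueError(f"empty subgroup: {name}")
            subgroups[(cls, flag)] = idx
    target_size = max(len(v) for v in subgroups.values())
    chunks = []
    for (cls, flag), idx in subgroups.items():
        n_new = target_size - len(idx)
        if n_new == 0:
            continue
        picks = rng.choice(len(idx), size=n_new, replace=True)
        counts = np.bincount(picks, minlength=len(idx))
        chunks.append(_synthesize(dataset, idx, counts, k_neighbors, rng, str(cls)))
    synth = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame()
    return _finish(dataset, synth)
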