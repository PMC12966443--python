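"""Descriptor-table preprocessing and Borderline-SMOTE oversampling.

Three training-data-only transforms precede modelling:

* near-constant filtering — a feature whose modal value covers more than a
  threshold fraction (default 0.95, strict inequality) of records carries no
  signal and is dropped;
* two scaling strategies for the mixed continuous/ordinal/binary descriptor
  types: strategy A (standard scaling + one-hot encoding of discrete
  features) and strategy B (min-max scaling + equal-frequency coarse binning
  of high-cardinality discrete features);
* Borderline-SMOTE1 (Han et al.): synthesize minority examples only from
  "danger" points — minority points with at least half but not all of their
  m nearest neighbors in the majority class — by interpolating toward
  minority neighbors, until the classes balance 1:1.

All statistics are fitted on training data and reapplied frozen, so the test
partition never leaks into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import FeatureKind, FeatureMeta, SubstrateDataset

__all__ = [
    "near_constant_filter",
    "PreprocessPlan",
    "fit_plan",
    "apply_plan",
    "fit_transform",
    "classify_minority",
    "borderline_smote",
]

logger = logging.getLogger(__name__)

#: Distinct training values above which strategy B bins a discrete feature.
HIGH_CARDINALITY = 10
#: Equal-frequency bin count for strategy B coarse binning.
N_BINS = 5


def near_constant_filter(
    ds: SubstrateDataset, threshold: float = 0.95
) -> tuple[SubstrateDataset, list[str]]:
    """Drop features whose modal relative frequency strictly exceeds the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if ds.n == 0:
        return ds, []
    X = ds.X
    removed: list[str] = []
    kept_idx: list[int] = []
    for j, meta in enumerate(ds.features):
        _, counts = np.unique(X[:, j], return_counts=True)
        if counts.max() / ds.n > threshold:
            removed.append(meta.name)
        else:
            kept_idx.append(j)
    if not removed:
        return ds, []
    features = [ds.features[j] for j in kept_idx]
    records = []
    for r in ds.records:
        rec = type(r)(r.id, r.smiles, r.label, np.asarray(r.descriptors)[kept_idx])
        records.append(rec)
    return SubstrateDataset(records, features), removed


@dataclass
class PreprocessPlan:
    """Frozen per-feature statistics for reapplying a fitted transform."""

    strategy: str
    feature_names: list[str]
    params: dict[str, dict] = field(default_factory=dict)
    output_names: list[str] = field(default_factory=list)


def _is_discrete(meta: FeatureMeta) -> bool:
    return meta.kind in (FeatureKind.ORDINAL, FeatureKind.CATEGORICAL)


def fit_plan(ds_train: SubstrateDataset, strategy: str = "A") -> PreprocessPlan:
    """Fit transform statistics on training data only."""
    if strategy not in ("A", "B"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if ds_train.n == 0:
        raise ValueError("cannot fit a plan on empty training data")
    X = ds_train.X
    plan = PreprocessPlan(strategy=strategy, feature_names=ds_train.feature_names)
    for j, meta in enumerate(ds_train.features):
        col = X[:, j]
        if strategy == "A":
            if _is_discrete(meta):
                cats = sorted(set(col.tolist()))
                plan.params[meta.name] = {"mode": "onehot", "categories": cats}
                plan.output_names += [f"{meta.name}={c:g}" for c in cats]
            elif meta.kind == FeatureKind.BINARY:
                plan.params[meta.name] = {"mode": "passthrough"}
                plan.output_names.append(meta.name)
            else:
                sd = float(col.std(ddof=0))
                plan.params[meta.name] = {
                    "mode": "standard",
                    "mean": float(col.mean()),
                    "sd": sd,
                }
                plan.output_names.append(meta.name)
        else:  # strategy B
            if meta.kind == FeatureKind.CONTINUOUS:
                plan.params[meta.name] = {
                    "mode": "minmax",
                    "min": float(col.min()),
                    "max": float(col.max()),
                }
            else:
                distinct = np.unique(col)
                if distinct.size > HIGH_CARDINALITY:
                    edges = np.quantile(col, np.linspace(0, 1, N_BINS + 1)[1:-1])
                    plan.params[meta.name] = {
                        "mode": "bin",
                        "edges": np.unique(edges).tolist(),
                    }
                else:
                    codes = {v: i for i, v in enumerate(sorted(distinct.tolist()))}
                    plan.params[meta.name] = {"mode": "code", "codes": codes}
            plan.output_names.append(meta.name)
    return plan


def apply_plan(plan: PreprocessPlan, ds: SubstrateDataset) -> np.ndarray:
    """Apply a fitted plan to any table with the same features."""
    if ds.feature_names != plan.feature_names:
        raise ValueError("dataset features do not match the fitted plan")
    X = ds.X
    out_cols: list[np.ndarray] = []
    for j, name in enumerate(plan.feature_names):
        col = X[:, j]
        p = plan.params[name]
        mode = p["mode"]
        if mode == "onehot":
            for c in p["categories"]:
                out_cols.append((col == c).astype(float))
        elif mode == "passthrough":
            out_cols.append(col.astype(float))
        elif mode == "standard":
            if p["sd"] == 0.0:
                out_cols.append(np.zeros_like(col))
            else:
                out_cols.append((col - p["mean"]) / p["sd"])
        elif mode == "minmax":
            span = p["max"] - p["min"]
            if span == 0.0:
                out_cols.append(np.zeros_like(col))
            else:
                out_cols.append((col - p["min"]) / span)
        elif mode == "bin":
            out_cols.append(np.searchsorted(p["edges"], col, side="right").astype(float))
        elif mode == "code":
            codes = p["codes"]
            fallback = len(codes)  # unseen category -> extra code
            out_cols.append(
                np.array([codes.get(v, fallback) for v in col.tolist()], dtype=float)
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown mode {mode!r}")
    return np.column_stack(out_cols) if out_cols else np.empty((ds.n, 0))


def fit_transform(
    ds_train: SubstrateDataset, strategy: str = "A"
) -> tuple[PreprocessPlan, np.ndarray]:
    plan = fit_plan(ds_train, strategy)
    return plan, apply_plan(plan, ds_train)


def _nearest(dist_row: np.ndarray, exclude: int, count: int) -> np.ndarray:
    """Indices of the ``count`` nearest points; ties broken by lowest index."""
    d = dist_row.copy()
    d[exclude] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:count]


def classify_minority(
    X: np.ndarray, y: np.ndarray, m: int = 5
) -> dict[str, list[int]]:
    """Partition minority points into safe / danger / noise (Han et al.).

    With m' the number of majority points among a minority point's m nearest
    neighbors (any class): m' = m -> noise, m/2 <= m' < m -> danger, else
    safe.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    minority = int(np.argmin(counts))
    dist = cdist(X, X)
    result: dict[str, list[int]] = {"safe": [], "danger": [], "noise": []}
    m_eff = min(m, len(y) - 1)
    for i in np.flatnonzero(y == minority):
        nn = _nearest(dist[i], i, m_eff)
        n_majority = int(np.sum(y[nn] != minority))
        if n_majority == m_eff:
            result["noise"].append(int(i))
        elif n_majority >= m_eff / 2:
            result["danger"].append(int(i))
        else:
            result["safe"].append(int(i))
    return result


def borderline_smote(
    X: np.ndarray,
    y: np.ndarray,
    m: int = 5,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Borderline-SMOTE1: oversample the minority class to a 1:1 balance.

    New samples are ``danger + u * (minority neighbor - danger)`` with
    u ~ Uniform(0,1), originals retained unchanged.  If no danger points
    exist, plain interpolation over all minority points is used (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    minority = int(np.argmin(counts))
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X.copy(), y.copy()
    min_idx = np.flatnonzero(y == minority)
    if min_idx.size < 2:
        raise ValueError("need at least 2 minority samples to interpolate")

    groups = classify_minority(X, y, m=m)
    seeds_idx = groups["danger"]
    if not seeds_idx:
        logger.warning(
            "borderline_smote: no DANGER points; falling back to plain "
            "interpolation over all %d minority points", min_idx.size
        )
        seeds_idx = min_idx.tolist()

    dist_min = cdist(X[min_idx], X[min_idx])
    pos_in_min = {int(g): i for i, g in enumerate(min_idx)}
    k_eff = min(k, min_idx.size - 1)

    rng = np.random.default_rng(seed)
    new_X = np.empty((deficit, X.shape[1]))
    for t in range(deficit):
        p = int(seeds_idx[int(rng.integers(0, len(seeds_idx)))])
        row = dist_min[pos_in_min[p]]
        neighbors = _nearest(row, pos_in_min[p], k_eff)
        q = int(min_idx[neighbors[int(rng.integers(0, k_eff))]])
        u = rng.random()
        new_X[t] = X[p] + u * (X[q] - X[p])
    X_out = np.vstack([X, new_X])
    y_out = np.concatenate([y, np.full(deficit, minority)])
    return X_out, y_out
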