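"""Interpretability core: Gini importances and a discrete Bayesian network.

Two complementary views of which molecular descriptors drive the oxidation
outcome:

* mean-decrease-impurity (Gini) importances read directly off a fitted tree
  ensemble, normalized to sum to 1 — fast but model-specific and biased
  toward high-cardinality features;
* a probabilistic view: descriptors are discretized with the entropy/MDLP
  (Fayyad-Irani) criterion, a discrete Bayesian network is learned by greedy
  hill-climbing on the BIC score, conditional probability tables are fitted
  by maximum likelihood, and the Markov blanket of the target — parents,
  children and co-parents of children — is extracted as the minimal feature
  set that renders the target conditionally independent of everything else.

Entropy is measured in bits (the MDLP convention); the BIC log-likelihood
uses natural logs (the standard convention).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureKind, SubstrateDataset, binarize

__all__ = [
    "ImportanceReport",
    "DiscretizationScheme",
    "BayesNet",
    "gini_importance",
    "entropy",
    "mdlp_discretize",
    "discretize_dataset",
    "bic_score",
    "family_score",
    "hill_climb",
    "fit_cpts",
    "markov_blanket",
]

logger = logging.getLogger(__name__)

TARGET = "Oxd"


# ---------------------------------------------------------------------------
# Gini importance


@dataclass
class ImportanceReport:
    """Per-feature mean-decrease-impurity importances (sum to 1)."""

    importances: np.ndarray
    feature_names: list[str] | None = None
    sd: np.ndarray | None = None


def gini_importance(forest, n_features: int | None = None) -> ImportanceReport:
    """Mean-decrease-impurity importances from a fitted tree ensemble.

    ``forest`` must expose ``estimators_``, each with a sklearn-style
    ``tree_`` (arrays: feature, children_left/right, weighted_n_node_samples,
    impurity).  Per feature and node splitting on it the weighted impurity
    decrease (node samples / total) * impurity minus the children's weighted
    impurities is summed; per-tree importances are normalized and averaged
    over trees, then renormalized to sum to 1.
    """
    estimators = getattr(forest, "estimators_", None)
    if not estimators:
        raise ValueError("empty forest: no fitted estimators")
    if n_features is None:
        n_features = int(getattr(forest, "n_features_in_", estimators[0].tree_.n_features))
    total = np.zeros(n_features)
    for est in estimators:
        tree = est.tree_
        imp = np.zeros(n_features)
        root_w = tree.weighted_n_node_samples[0]
        left, right = tree.children_left, tree.children_right
        for node in range(tree.node_count):
            if left[node] < 0:  # leaf
                continue
            w = tree.weighted_n_node_samples[node]
            wl = tree.weighted_n_node_samples[left[node]]
            wr = tree.weighted_n_node_samples[right[node]]
            decrease = (
                w * tree.impurity[node]
                - wl * tree.impurity[left[node]]
                - wr * tree.impurity[right[node]]
            ) / root_w
            imp[tree.feature[node]] += decrease
        s = imp.sum()
        if s > 0:
            imp /= s
        total += imp
    total /= len(estimators)
    s = total.sum()
    if s > 0:
        total /= s
    return ImportanceReport(importances=total)


# ---------------------------------------------------------------------------
# Entropy and MDLP discretization


def entropy(labels) -> float:
    """Shannon entropy in bits; 0 log 0 = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _candidate_cuts(xs: np.ndarray, ys: np.ndarray) -> list[float]:
    """Midpoints between adjacent distinct x values at class boundaries.

    With tied x values "adjacent labels differ" is ambiguous, so the
    well-defined rule is: a boundary is a candidate unless the two adjacent
    value-groups are pure with the same single label.
    """
    cuts = []
    start = 0
    groups: list[tuple[float, set]] = []
    for i in range(1, len(xs) + 1):
        if i == len(xs) or xs[i] != xs[start]:
            groups.append((xs[start], set(ys[start:i].tolist())))
            start = i
    for (xa, la), (xb, lb) in zip(groups, groups[1:]):
        if len(la) == 1 and la == lb:
            continue
        cuts.append((xa + xb) / 2.0)
    return cuts


def _mdlp_accept(ys: np.ndarray, yl: np.ndarray, yr: np.ndarray, ig: float) -> bool:
    n = len(ys)
    c = len(np.unique(ys))
    cl = len(np.unique(yl))
    cr = len(np.unique(yr))
    delta = math.log2(3**c - 2) - (c * entropy(ys) - cl * entropy(yl) - cr * entropy(yr))
    return ig > math.log2(n - 1) / n + delta / n


def _mdlp_recurse(xs: np.ndarray, ys: np.ndarray, cuts: list[float]) -> None:
    n = len(xs)
    if n < 2 or len(np.unique(ys)) < 2:
        return
    h = entropy(ys)
    best_t, best_ig, best_i = None, -np.inf, None
    for t in _candidate_cuts(xs, ys):
        i = int(np.searchsorted(xs, t))
        yl, yr = ys[:i], ys[i:]
        ig = h - (len(yl) / n) * entropy(yl) - (len(yr) / n) * entropy(yr)
        if ig > best_ig + 1e-12:
            best_t, best_ig, best_i = t, ig, i
    if best_t is None:
        return
    yl, yr = ys[:best_i], ys[best_i:]
    if not _mdlp_accept(ys, yl, yr, best_ig):
        return
    cuts.append(best_t)
    _mdlp_recurse(xs[:best_i], yl, cuts)
    _mdlp_recurse(xs[best_i:], yr, cuts)


def mdlp_discretize(x, y) -> list[float]:
    """Recursive entropy-based cut selection with the Fayyad-Irani MDLP stop.

    Returns the sorted accepted cut points (empty for a feature that never
    clears the MDLP threshold; constant x has no candidates at all).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    order = np.argsort(x, kind="mergesort")
    cuts: list[float] = []
    _mdlp_recurse(x[order], y[order], cuts)
    return sorted(cuts)


@dataclass
class DiscretizationScheme:
    """Per-feature ordered MDLP cut points (empty list = single bin)."""

    cuts: dict[str, list[float]] = field(default_factory=dict)

    def apply(self, name: str, values) -> np.ndarray:
        return np.searchsorted(self.cuts.get(name, []), np.asarray(values, dtype=float))


def discretize_dataset(ds: SubstrateDataset) -> tuple[pd.DataFrame, DiscretizationScheme]:
    """MDLP-discretize all non-binary features against the oxidation label.

    Returns an integer-coded table (including the target column) ready for
    Bayesian-network structure learning.
    """
    ds = binarize(ds)
    y = ds.y
    X = ds.X
    scheme = DiscretizationScheme()
    cols: dict[str, np.ndarray] = {}
    for j, meta in enumerate(ds.features):
        if meta.kind == FeatureKind.BINARY:
            cols[meta.name] = X[:, j].astype(int)
            continue
        scheme.cuts[meta.name] = mdlp_discretize(X[:, j], y)
        cols[meta.name] = scheme.apply(meta.name, X[:, j])
    cols[TARGET] = y
    return pd.DataFrame(cols, index=ds.ids), scheme


# ---------------------------------------------------------------------------
# Bayesian network: BIC scoring, hill-climb structure search, MLE CPTs


@dataclass
class BayesNet:
    """A DAG over discretized variables, optionally with fitted CPTs.

    ``cpts[node]`` is a (parent-configuration x state) row-stochastic table;
    parent configurations are mixed-radix indices over ``parents(node)`` in
    stored order with per-variable state lists in ``states``.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    cpts: dict[str, np.ndarray] | None = None
    states: dict[str, list] | None = None

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for (u, v) in self.edges if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for (u, v) in self.edges if u == node))


def _states(data: pd.DataFrame) -> dict[str, list]:
    return {c: sorted(data[c].unique().tolist()) for c in data.columns}


def family_score(data: pd.DataFrame, node: str, parents: tuple[str, ...]) -> float:
    """BIC contribution of one family: MLE log-likelihood minus
    (ln n / 2) * (r-1) * q free parameters."""
    n = len(data)
    r = data[node].nunique()
    if parents:
        q = 1
        for p in parents:
            q *= data[p].nunique()
        counts = data.groupby(list(parents) + [node], observed=True).size()
        parent_totals = data.groupby(list(parents), observed=True).size()
        ll = 0.0
        for key, nijk in counts.items():
            pkey = key[:-1] if len(parents) > 1 else key[0]
            # single-parent groupby keys are scalars
            if len(parents) == 1:
                nij = parent_totals.loc[pkey]
            else:
                nij = parent_totals.loc[tuple(pkey)] if isinstance(pkey, tuple) else parent_totals.loc[pkey]
            ll += nijk * math.log(nijk / nij)
    else:
        q = 1
        counts = data[node].value_counts()
        ll = float(sum(c * math.log(c / n) for c in counts))
    return ll - (math.log(n) / 2.0) * (r - 1) * q


def bic_score(net: BayesNet | dict[str, tuple[str, ...]], data: pd.DataFrame) -> float:
    """Decomposable BIC of a structure: sum of per-family scores."""
    if isinstance(net, BayesNet):
        families = {v: net.parents(v) for v in net.nodes}
    else:
        families = dict(net)
    for node in families:
        if node not in data.columns:
            raise ValueError(f"node {node!r} missing from the data")
    return sum(family_score(data, v, tuple(ps)) for v, ps in families.items())


def _has_path(families: dict[str, tuple[str, ...]], src: str, dst: str) -> bool:
    """True if dst is reachable from src following child edges."""
    children: dict[str, list[str]] = {v: [] for v in families}
    for v, ps in families.items():
        for p in ps:
            children[p].append(v)
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


_OP_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def hill_climb(
    data: pd.DataFrame, max_iter: int = 200, seed: int = 0
) -> BayesNet:
    """Greedy best-first BIC hill-climbing over add/delete/reverse edge moves.

    Starts from the empty graph, preserves acyclicity, stops at a local
    optimum (no single-edge operation improves the BIC) or after
    ``max_iter`` moves.  Deterministic: ties break lexicographically on
    (operation add < delete < reverse, source, target); ``seed`` is accepted
    for interface uniformity but unused.
    """
    del seed
    variables = list(data.columns)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    families: dict[str, tuple[str, ...]] = {v: () for v in variables}
    fam_scores = {v: family_score(data, v, ()) for v in variables}

    for _ in range(max_iter):
        best = None  # (delta, op_rank, src, dst, changes)
        for u, v in itertools.permutations(variables, 2):
            if u in families[v]:
                # delete u -> v
                new_ps = tuple(p for p in families[v] if p != u)
                delta = family_score(data, v, new_ps) - fam_scores[v]
                best = _better(best, (delta, _OP_ORDER["delete"], u, v, {v: new_ps}))
                # reverse u -> v  (becomes v -> u)
                without = {**families, v: new_ps}
                if not _has_path(without, u, v):
                    new_pu = tuple(sorted(families[u] + (v,)))
                    delta_r = (
                        family_score(data, v, new_ps)
                        - fam_scores[v]
                        + family_score(data, u, new_pu)
                        - fam_scores[u]
                    )
                    best = _better(best, (delta_r, _OP_ORDER["reverse"], u, v, {v: new_ps, u: new_pu}))
            elif v not in families[u]:
                # add u -> v
                if _has_path(families, v, u):
                    continue  # would create a cycle
                new_ps = tuple(sorted(families[v] + (u,)))
                delta = family_score(data, v, new_ps) - fam_scores[v]
                best = _better(best, (delta, _OP_ORDER["add"], u, v, {v: new_ps}))
        if best is None or best[0] <= 1e-9:
            break
        for node, ps in best[4].items():
            families[node] = ps
            fam_scores[node] = family_score(data, node, ps)

    edges = frozenset((p, v) for v, ps in families.items() for p in ps)
    return BayesNet(nodes=tuple(variables), edges=edges)


def _better(best, cand):
    """Pick the larger-delta move; ties break lexicographically on
    (op rank, source, target)."""
    if cand[0] <= 1e-9:
        return best
    if best is None:
        return cand
    if cand[0] > best[0] + 1e-12:
        return cand
    if abs(cand[0] - best[0]) <= 1e-12 and (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3]):
        return cand
    return best


def fit_cpts(
    net: BayesNet, data: pd.DataFrame, pseudo: float = 0.0
) -> BayesNet:
    """Estimate CPTs by (optionally smoothed) maximum likelihood.

    Entry = (count + pseudo) / (parent-config count + pseudo * arity);
    pseudo=0 is pure MLE.  Parent configurations never observed get a uniform
    row (logged).
    """
    states = _states(data)
    cpts: dict[str, np.ndarray] = {}
    for node in net.nodes:
        parents = net.parents(node)
        r = len(states[node])
        state_pos = {s: i for i, s in enumerate(states[node])}
        if parents:
            cards = [len(states[p]) for p in parents]
            q = int(np.prod(cards))
            counts = np.zeros((q, r))
            pos = [{s: i for i, s in enumerate(states[p])} for p in parents]
            for _, row in data.iterrows():
                idx = 0
                for d, p in enumerate(parents):
                    idx = idx * cards[d] + pos[d][row[p]]
                counts[idx, state_pos[row[node]]] += 1
        else:
            counts = np.zeros((1, r))
            for v, c in data[node].value_counts().items():
                counts[0, state_pos[v]] = c
        table = np.empty_like(counts)
        for i in range(counts.shape[0]):
            rowsum = counts[i].sum()
            if rowsum + pseudo * r == 0:
                logger.info(
                    "fit_cpts: unseen parent configuration %d for %r; uniform row",
                    i, node,
                )
                table[i] = 1.0 / r
            else:
                table[i] = (counts[i] + pseudo) / (rowsum + pseudo * r)
        cpts[node] = table
    return BayesNet(net.nodes, net.edges, cpts=cpts, states=states)


def markov_blanket(net: BayesNet, target: str = TARGET) -> set[str]:
    """Parents, children and co-parents of children of the target."""
    if target not in net.nodes:
        raise ValueError(f"unknown target {target!r}")
    blanket = set(net.parents(target)) | set(net.children(target))
    for child in net.children(target):
        blanket |= set(net.parents(child))
    blanket.discard(target)
    return blanket
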