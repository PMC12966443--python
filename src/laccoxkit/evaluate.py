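"""Nested cross-validated evaluation of pluggable classifiers.

The protocol, not the solvers, is the substance here: per random seed a
stratified 80/20 outer split, an inner 5-fold grid search on the training
portion (selection criterion: F1), Borderline-SMOTE applied strictly inside
training data, refit with the best hyperparameters, evaluation on the
untouched outer test, and mean ± sd summaries over (by default) 10 seeds.
Learners are delegated to scikit-learn behind a named ClassifierSpec; the
averaged-probability ensemble and model comparison (paired Wilcoxon on
per-seed F1, AUROC rank aggregation) complete the engine.

Probability threshold is 0.5 with >= mapping to the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.svm import SVC

from .data import SubstrateDataset, binarize, split_train_test
from .preprocess import apply_plan, borderline_smote, fit_plan

__all__ = [
    "ClassWeights",
    "ClassifierSpec",
    "CVReport",
    "class_weights",
    "metrics",
    "auroc_score",
    "default_specs",
    "nested_cv",
    "ensemble_predict",
    "compare_models",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auroc")


@dataclass(frozen=True)
class ClassWeights:
    """Balanced class weights w1 = n/(2 n1), w0 = n/(2 n0) for weighted BCE."""

    w1: float
    w0: float
    n: int
    n1: int
    n0: int


def class_weights(y: Sequence[int]) -> ClassWeights:
    y = np.asarray(y, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n1 + n0
    return ClassWeights(w1=n / (2 * n1), w0=n / (2 * n0), n=n, n1=n1, n0=n0)


def auroc_score(y_true: np.ndarray, y_prob: np.ndarray) -> float | None:
    """Rank-based AUROC with ties averaged; None when y_true is single-class."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    n1 = int(np.sum(y_true == 1))
    n0 = int(np.sum(y_true == 0))
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(y_prob, method="average")
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def metrics(
    y_true: Sequence[int], y_prob: Sequence[float], threshold: float = 0.5
) -> dict[str, float | None]:
    """Accuracy/precision/recall/F1 at the threshold plus rank-based AUROC.

    Probabilities exactly at the threshold predict positive.  Precision is 0
    (logged) when no positive predictions exist; AUROC is None for a
    single-class y_true rather than 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    n = len(y_true)
    if tp + fp == 0:
        logger.info("metrics: no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "accuracy": (tp + tn) / n,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auroc": auroc_score(y_true, y_prob),
    }


@dataclass
class ClassifierSpec:
    """A named learner with a hyperparameter grid.

    ``name`` selects a built-in scikit-learn learner
    (logreg_elasticnet / svc / rfc / gradboost) or "custom", in which case
    ``builder(params, seed)`` must return an unfitted estimator with
    predict_proba.  ``scale`` controls whether the strategy-A preprocessing
    plan is applied (tree ensembles consume raw mixed-type descriptors).
    """

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    builder: Callable | None = None
    scale: bool = True


# Small default grids; the tuning protocol, not the grid content, is the
# contract under test.
def default_specs(
    names: Sequence[str] = ("logreg_elasticnet", "svc", "rfc", "gradboost"),
) -> list[ClassifierSpec]:
    registry = {
        "logreg_elasticnet": ClassifierSpec(
            "logreg_elasticnet",
            {"C": [0.1, 1.0], "l1_ratio": [0.2, 0.8]},
            scale=True,
        ),
        "svc": ClassifierSpec("svc", {"C": [1.0, 10.0], "kernel": ["rbf"]}, scale=True),
        "rfc": ClassifierSpec(
            "rfc", {"n_estimators": [100], "max_depth": [None, 8]}, scale=False
        ),
        "gradboost": ClassifierSpec(
            "gradboost",
            {"n_estimators": [100], "max_depth": [2, 3]},
            scale=False,
        ),
    }
    return [registry[n] for n in names]


def _build(spec: ClassifierSpec, params: dict, seed: int):
    if spec.name == "logreg_elasticnet":
        # float l1_ratio selects the elastic-net penalty
        return LogisticRegression(solver="saga", max_iter=5000, random_state=seed, **params)
    if spec.name == "svc":
        return SVC(probability=True, random_state=seed, **params)
    if spec.name == "rfc":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.name == "gradboost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if spec.builder is not None:
        return spec.builder(params, seed)
    raise ValueError(f"unknown classifier {spec.name!r} and no builder given")


@dataclass
class CVReport:
    """Per-(seed, model) metric rows plus mean ± sd summaries."""

    rows: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        """Mean and sample sd per model per metric over seeds."""
        ok = self.rows[~self.rows["failed"]]
        return ok.groupby("model")[list(METRIC_NAMES)].agg(["mean", "std"])

    def per_seed(self, model: str, metric: str) -> np.ndarray:
        sel = self.rows[(self.rows["model"] == model) & (~self.rows["failed"])]
        return sel.sort_values("seed")[metric].to_numpy()


def _fit_eval_once(
    spec: ClassifierSpec,
    params: dict,
    ds_fit: SubstrateDataset,
    ds_eval: SubstrateDataset,
    seed: int,
    smote: bool,
    strategy: str,
) -> dict[str, float | None]:
    if spec.scale:
        plan = fit_plan(ds_fit, strategy)
        X_fit, X_eval = apply_plan(plan, ds_fit), apply_plan(plan, ds_eval)
    else:
        X_fit, X_eval = ds_fit.X, ds_eval.X
    y_fit = ds_fit.y
    if smote and np.unique(y_fit).size == 2:
        X_fit, y_fit = borderline_smote(X_fit, y_fit, seed=seed)
    clf = _build(spec, params, seed)
    clf.fit(X_fit, y_fit)
    prob = clf.predict_proba(X_eval)[:, list(clf.classes_).index(1)]
    return metrics(ds_eval.y, prob)


def nested_cv(
    ds: SubstrateDataset,
    specs: Sequence[ClassifierSpec],
    n_seeds: int = 10,
    outer_test: float = 0.2,
    inner_folds: int = 5,
    base_seed: int = 0,
    smote: bool = True,
    strategy: str = "A",
) -> CVReport:
    """Nested cross-validation over repeated outer splits.

    Per seed: stratified outer split; inner stratified k-fold grid search on
    the training portion maximizing F1 (Borderline-SMOTE fitted inside each
    inner-training fold); refit on the full training portion with the best
    hyperparameters; evaluate on the untouched outer test.  A learner failure
    marks that (seed, model) cell failed and the run continues.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ds = binarize(ds)
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        tr, te = split_train_test(ds, outer_test, seed=seed)
        assert not set(tr.ids) & set(te.ids)
        y_tr = tr.y
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(tr.n), y_tr))
        for spec in specs:
            try:
                best_params, best_f1 = None, -np.inf
                for params in ParameterGrid(spec.grid) if spec.grid else [{}]:
                    f1s = []
                    for fit_idx, val_idx in folds:
                        res = _fit_eval_once(
                            spec, params, tr.subset(fit_idx), tr.subset(val_idx),
                            seed, smote, strategy,
                        )
                        f1s.append(res["f1"])
                    mean_f1 = float(np.mean(f1s))
                    if mean_f1 > best_f1 + 1e-12:
                        best_params, best_f1 = params, mean_f1
                res = _fit_eval_once(spec, best_params, tr, te, seed, smote, strategy)
                rows.append({"seed": seed, "model": spec.name, "failed": False, **res})
            except Exception as exc:  # noqa: BLE001 - per-cell failure tolerance
                logger.warning("seed %d model %s failed: %s", seed, spec.name, exc)
                rows.append(
                    {"seed": seed, "model": spec.name, "failed": True}
                    | {m: np.nan for m in METRIC_NAMES}
                )
    return CVReport(pd.DataFrame(rows))


def ensemble_predict(
    prob_vectors: Sequence[np.ndarray], threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-probability voting: elementwise mean, label 1 iff mean >= threshold."""
    if len(prob_vectors) == 0:
        raise ValueError("need at least one model's probabilities")
    P = np.vstack([np.asarray(p, dtype=float) for p in prob_vectors])
    mean = P.mean(axis=0)
    return mean, (mean >= threshold).astype(int)


@dataclass
class ModelComparison:
    wilcoxon_p: pd.DataFrame
    auroc_ranks: pd.DataFrame
    summed_ranks: pd.Series


def compare_models(
    reports: CVReport | Sequence[CVReport], metric: str = "f1"
) -> ModelComparison:
    """Paired Wilcoxon on per-seed scores plus AUROC rank aggregation.

    Wilcoxon: two-sided signed-rank on per-seed F1 with zero differences
    dropped and the exact distribution for <= 25 pairs; all-zero differences
    report p = 1.  Ranks: per report, models ranked by mean AUROC (rank 1 =
    highest, average-rank ties), then summed across reports.
    """
    if isinstance(reports, CVReport):
        reports = [reports]
    models = sorted(reports[0].rows["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")

    first = reports[0]
    pmat = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            xa, xb = first.per_seed(a, metric), first.per_seed(b, metric)
            if len(xa) < 2 or len(xa) != len(xb):
                p = np.nan
            elif np.allclose(xa, xb):
                p = 1.0
            else:
                method = "exact" if len(xa) <= 25 else "auto"
                p = float(
                    wilcoxon(
                        xa, xb, zero_method="wilcox", alternative="two-sided",
                        method=method,
                    ).pvalue
                )
            pmat.loc[a, b] = pmat.loc[b, a] = p

    rank_rows = {}
    for r, rep in enumerate(reports):
        means = rep.summary[("auroc", "mean")].reindex(models)
        rank_rows[f"dataset_{r}"] = rankdata(-means.to_numpy(), method="average")
    ranks = pd.DataFrame(rank_rows, index=models)
    return ModelComparison(
        wilcoxon_p=pmat, auroc_ranks=ranks, summed_ranks=ranks.sum(axis=1)
    )
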