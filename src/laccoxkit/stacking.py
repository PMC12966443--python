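"""Stacked generalization via confidence regions in a 2-D Isomap embedding.

Base classifiers are trained once; on a dedicated validation set each model's
probability of the true class is rescaled to a signed confidence
s = 2 (p - 0.5) in [-1, 1].  The descriptor space is embedded in 2-D with
Isomap (k-NN graph -> geodesic distances -> classical MDS); each validation
point stores the locally most confident base model and that model's
predicted class.  A new sample is projected into the same plane with the
standard Nystrom out-of-sample extension and inherits the stored class of
its nearest validation point — so the meta-model's decision regions are
exactly the Voronoi cells of the embedded validation set, which this module
also exports for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "confidence_scores",
    "IsomapReference",
    "isomap_embed",
    "project_new",
    "StackedMeta",
    "fit_meta",
    "predict_meta",
    "voronoi_regions",
    "SplitTriple",
    "split_triple",
]

#: Validation-split proportions back-computed from a 180/49/21 triple.
DEFAULT_TRIPLE_FRACTIONS = (0.72, 0.196, 0.084)


def confidence_scores(prob_true_class: np.ndarray) -> np.ndarray:
    """Signed confidence s = 2 (p - 0.5), mapping [0, 1] onto [-1, 1]."""
    P = np.asarray(prob_true_class, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return 2.0 * (P - 0.5)


@dataclass
class IsomapReference:
    """Everything needed to project new points into a fitted embedding."""

    X: np.ndarray
    geodesics: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    embedding: np.ndarray
    k_neighbors: int
    col_mean_sq: np.ndarray  # per-reference mean squared geodesic distance


def isomap_embed(
    X: np.ndarray, k_neighbors: int = 10, dims: int = 2
) -> tuple[np.ndarray, IsomapReference]:
    """Isomap: k-NN graph -> geodesics -> classical MDS.

    Deterministic up to sign (fixed here by making each axis's largest-
    magnitude loading positive).  A disconnected neighborhood graph raises an
    error naming the components.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n <= k_neighbors:
        raise ValueError(f"need n > k_neighbors, got n={n}, k={k_neighbors}")
    graph = kneighbors_graph(X, k_neighbors, mode="distance")
    sym = graph.maximum(graph.T)
    n_comp, labels = connected_components(sym, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"neighborhood graph is disconnected ({n_comp} components of sizes "
            f"{sizes.tolist()}); raise k_neighbors"
        )
    D = shortest_path(sym, directed=False)
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    eigvals = np.clip(w[order], 0.0, None)
    eigvecs = V[:, order]
    for d in range(dims):  # deterministic sign convention
        j = int(np.argmax(np.abs(eigvecs[:, d])))
        if eigvecs[j, d] < 0:
            eigvecs[:, d] *= -1
    embedding = eigvecs * np.sqrt(eigvals)
    ref = IsomapReference(
        X=X,
        geodesics=D,
        eigvals=eigvals,
        eigvecs=eigvecs,
        embedding=embedding,
        k_neighbors=k_neighbors,
        col_mean_sq=D2.mean(axis=1),
    )
    return embedding, ref


def project_new(x: np.ndarray, ref: IsomapReference) -> np.ndarray:
    """Nystrom out-of-sample projection into a fitted Isomap plane.

    Geodesic distances from the new point are approximated through its
    k nearest reference points; a point equal to a reference lands exactly on
    that reference's embedding.
    """
    if ref.X.size == 0:
        raise ValueError("empty reference")
    x = np.asarray(x, dtype=float)
    direct = np.linalg.norm(ref.X - x, axis=1)
    j0 = int(np.argmin(direct))
    if direct[j0] < 1e-12:
        # exact self-consistency for (duplicates of) reference points
        d = ref.geodesics[j0]
    else:
        anchors = np.argsort(direct, kind="stable")[: ref.k_neighbors]
        d = np.min(direct[anchors, None] + ref.geodesics[anchors, :], axis=0)
    b = -0.5 * (d**2 - ref.col_mean_sq)
    out = np.empty(len(ref.eigvals))
    for k in range(len(ref.eigvals)):
        lam = ref.eigvals[k]
        out[k] = (ref.eigvecs[:, k] @ b) / np.sqrt(lam) if lam > 0 else 0.0
    return out


@dataclass
class StackedMeta:
    """Embedded validation points with per-point best base model and class."""

    embedding: np.ndarray
    best_model_index: np.ndarray
    best_confidence: np.ndarray
    predicted_label_at_point: np.ndarray
    tree: cKDTree


def fit_meta(
    embedding: np.ndarray,
    confidences: np.ndarray,
    base_predictions: np.ndarray,
) -> StackedMeta:
    """Store, per validation point, the most confident base model's class.

    Confidence ties break toward the lowest model index.
    """
    embedding = np.asarray(embedding, dtype=float)
    confidences = np.asarray(confidences, dtype=float)
    base_predictions = np.asarray(base_predictions, dtype=int)
    if confidences.shape != base_predictions.shape or len(embedding) != len(confidences):
        raise ValueError("inconsistent shapes")
    best_idx = np.argmax(confidences, axis=1)  # argmax returns lowest tied index
    rows = np.arange(len(embedding))
    return StackedMeta(
        embedding=embedding,
        best_model_index=best_idx,
        best_confidence=confidences[rows, best_idx],
        predicted_label_at_point=base_predictions[rows, best_idx],
        tree=cKDTree(embedding),
    )


def predict_meta(x: np.ndarray, meta: StackedMeta, ref: IsomapReference) -> int:
    """Project, find the nearest embedded validation point (ties -> lowest
    id), return its stored class."""
    z = project_new(x, ref)
    d = np.linalg.norm(meta.embedding - z, axis=1)
    return int(meta.predicted_label_at_point[int(np.argmin(d))])


def voronoi_regions(meta: StackedMeta, pad: float = 0.05):
    """Voronoi cells of the embedded validation points, clipped to the
    (padded) bounding box, annotated with best model and confidence.

    Fewer than 3 points or collinear points are degenerate: a half-plane
    description is returned instead of polygons.
    """
    pts = meta.embedding
    n = len(pts)
    # coincident points share one Voronoi site (GEOS rejects duplicates)
    sites, site_of = np.unique(pts.round(12), axis=0, return_inverse=True)
    span = pts.max(axis=0) - pts.min(axis=0) if n else np.zeros(2)
    degenerate = (
        len(sites) < 3 or np.linalg.matrix_rank(sites - sites.mean(axis=0)) < 2
    )
    if degenerate:
        return {
            "degenerate": True,
            "description": [
                {
                    "point_index": i,
                    "site": pts[i].tolist(),
                    "best_model": int(meta.best_model_index[i]),
                    "confidence": float(meta.best_confidence[i]),
                    "region": "half-plane of points nearest this site",
                }
                for i in range(n)
            ],
        }
    margin = pad * float(max(span.max(), 1e-9))
    bbox = box(
        pts[:, 0].min() - margin,
        pts[:, 1].min() - margin,
        pts[:, 0].max() + margin,
        pts[:, 1].max() + margin,
    )
    cells = voronoi_diagram(MultiPoint(sites.tolist()), envelope=bbox)
    regions = []
    site_cell = [None] * len(sites)
    for cell in cells.geoms:
        clipped = cell.intersection(bbox)
        for s in range(len(sites)):
            if site_cell[s] is None and clipped.covers(Point(sites[s])):
                site_cell[s] = clipped
                break
    for i in range(n):
        poly = site_cell[site_of[i]]
        regions.append(
            {
                "point_index": i,
                "site": pts[i].tolist(),
                "polygon": list(poly.exterior.coords) if poly is not None else None,
                "best_model": int(meta.best_model_index[i]),
                "confidence": float(meta.best_confidence[i]),
                "label": int(meta.predicted_label_at_point[i]),
            }
        )
    return {"degenerate": False, "regions": regions}


@dataclass
class SplitTriple:
    """Disjoint train/validation/test id lists covering the dataset."""

    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]


def split_triple(
    ds,
    fractions: tuple[float, float, float] = DEFAULT_TRIPLE_FRACTIONS,
    seed: int = 0,
):
    """Stratified train/validation/test partition in the given proportions."""
    from .data import split_train_test

    f_train, f_val, f_test = fractions
    total = f_train + f_val + f_test
    rest, test = split_train_test(ds, f_test / total, seed=seed)
    train, val = split_train_test(rest, f_val / (f_train + f_val), seed=seed + 1)
    triple = SplitTriple(train.ids, val.ids, test.ids)
    assert set(triple.train_ids) | set(triple.validation_ids) | set(triple.test_ids) == set(ds.ids)
    return (train, val, test, triple)
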