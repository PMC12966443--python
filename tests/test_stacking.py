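"""Confidence scores, Isomap embedding/projection, meta-model, Voronoi export."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from laccoxkit.stacking import (
    confidence_scores,
    fit_meta,
    isomap_embed,
    predict_meta,
    project_new,
    split_triple,
    voronoi_regions,
)


def _plane_data(n=30, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(2, 5))
    Z = rng.uniform(size=(n, 2))
    return Z @ A


class TestConfidenceScores:
    @pytest.mark.parametrize("p,s", [(0.5, 0.0), (1.0, 1.0), (0.0, -1.0), (0.75, 0.5)])
    def test_linear_map(self, p, s):
        assert confidence_scores(np.array([[p]]))[0, 0] == pytest.approx(s)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            confidence_scores(np.array([[1.2]]))

    def test_affine_order_preserving(self):
        p = np.linspace(0, 1, 11)
        s = confidence_scores(p)
        assert np.all(np.diff(s) > 0)
        assert s.min() == -1.0 and s.max() == 1.0


class TestIsomap:
    def test_flat_manifold_isometry(self):
        X = _plane_data()
        emb, _ = isomap_embed(X, k_neighbors=10)
        r = np.corrcoef(pdist(emb), pdist(X))[0, 1]
        assert r > 0.99

    def test_equilateral_triangle(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        emb, _ = isomap_embed(X, k_neighbors=2)
        d = pdist(emb)
        assert np.all(np.abs(d - d[0]) < 1e-6)

    def test_duplicated_points_identical_coords(self):
        X = _plane_data(20, seed=1)
        X = np.vstack([X, X[3]])
        emb, _ = isomap_embed(X, k_neighbors=6)
        np.testing.assert_allclose(emb[3], emb[-1], atol=1e-9)

    def test_disconnected_graph_error_names_components(self):
        X = np.vstack(
            [np.random.default_rng(2).normal(0, 0.1, (8, 2)),
             np.random.default_rng(3).normal(100, 0.1, (8, 2))]
        )
        with pytest.raises(ValueError, match="disconnected"):
            isomap_embed(X, k_neighbors=3)

    def test_matches_sklearn_isomap_geometry(self):
        # independent cross-check: same pairwise geometry as sklearn's Isomap
        from sklearn.manifold import Isomap

        X = _plane_data(40, seed=4)
        ours, _ = isomap_embed(X, k_neighbors=8)
        theirs = Isomap(n_neighbors=8, n_components=2).fit_transform(X)
        r = np.corrcoef(pdist(ours), pdist(theirs))[0, 1]
        assert r > 0.999


class TestProjection:
    def test_reference_point_projects_onto_itself(self):
        X = _plane_data(25, seed=5)
        emb, ref = isomap_embed(X, k_neighbors=8)
        for i in (0, 7, 24):
            np.testing.assert_allclose(project_new(X[i], ref), emb[i], atol=1e-8)

    def test_midpoint_of_duplicates(self):
        X = _plane_data(20, seed=6)
        X = np.vstack([X, X[5]])
        emb, ref = isomap_embed(X, k_neighbors=6)
        z = project_new(X[5], ref)
        np.testing.assert_allclose(z, emb[5], atol=1e-8)

    def test_held_out_geometry(self):
        X = _plane_data(60, seed=7)
        train, test = X[:45], X[45:]
        emb, ref = isomap_embed(train, k_neighbors=10)
        proj = np.array([project_new(x, ref) for x in test])
        all_true = np.vstack([train, test])
        all_emb = np.vstack([emb, proj])
        r = np.corrcoef(pdist(all_emb), pdist(all_true))[0, 1]
        assert r > 0.95


class TestMeta:
    def _meta(self, n=6, k=3, seed=8):
        rng = np.random.default_rng(seed)
        emb = rng.normal(size=(n, 2))
        conf = rng.uniform(-1, 1, (n, k))
        preds = rng.integers(0, 2, (n, k))
        return emb, conf, preds

    def test_single_model_all_zero_index(self):
        emb, conf, preds = self._meta(k=1)
        meta = fit_meta(emb, conf, preds)
        assert np.all(meta.best_model_index == 0)

    def test_tie_breaks_to_lowest_index(self):
        meta = fit_meta(
            np.zeros((1, 2)),
            np.array([[0.2, 0.9, 0.9]]),
            np.array([[0, 1, 0]]),
        )
        assert meta.best_model_index[0] == 1
        assert meta.predicted_label_at_point[0] == 1

    def test_best_confidence_is_row_max(self):
        emb, conf, preds = self._meta()
        meta = fit_meta(emb, conf, preds)
        np.testing.assert_allclose(meta.best_confidence, conf.max(axis=1))

    def test_predict_nearest_point_class(self):
        X = _plane_data(30, seed=9)
        emb, ref = isomap_embed(X[:20], k_neighbors=8)
        preds = np.arange(20) % 2
        meta = fit_meta(emb, np.ones((20, 1)), preds.reshape(-1, 1))
        for i in (0, 5, 11):
            assert predict_meta(X[i], meta, ref) == preds[i]

    def test_all_points_one_class(self):
        X = _plane_data(25, seed=10)
        emb, ref = isomap_embed(X[:15], k_neighbors=6)
        meta = fit_meta(emb, np.ones((15, 2)), np.ones((15, 2), dtype=int))
        assert predict_meta(X[20], meta, ref) == 1


class TestVoronoi:
    def test_unit_square_four_congruent_cells(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        meta = fit_meta(emb, np.ones((4, 1)), np.zeros((4, 1), dtype=int))
        out = voronoi_regions(meta, pad=0.5)
        assert not out["degenerate"]
        from shapely.geometry import Polygon

        areas = [Polygon(r["polygon"]).area for r in out["regions"]]
        assert np.allclose(areas, areas[0])

    def test_collinear_degenerate_no_crash(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        meta = fit_meta(emb, np.ones((3, 1)), np.zeros((3, 1), dtype=int))
        out = voronoi_regions(meta)
        assert out["degenerate"]
        assert len(out["description"]) == 3

    def test_cells_agree_with_nearest_neighbor_rule(self):
        rng = np.random.default_rng(11)
        emb = rng.uniform(size=(7, 2))
        labels = rng.integers(0, 2, (7, 1))
        meta = fit_meta(emb, np.ones((7, 1)), labels)
        out = voronoi_regions(meta)
        from shapely.geometry import Point, Polygon

        polys = [(r["point_index"], Polygon(r["polygon"])) for r in out["regions"]]
        for q in rng.uniform(0.05, 0.95, size=(40, 2)):
            nearest = int(np.argmin(np.linalg.norm(emb - q, axis=1)))
            inside = [i for i, poly in polys if poly.covers(Point(q))]
            if len(inside) == 1:  # skip points on cell borders
                assert inside[0] == nearest


def test_split_triple_partition(medium_panel):
    train, val, test, triple = split_triple(medium_panel, seed=3)
    ids = [set(triple.train_ids), set(triple.validation_ids), set(triple.test_ids)]
    assert not ids[0] & ids[1] and not ids[0] & ids[2] and not ids[1] & ids[2]
    assert ids[0] | ids[1] | ids[2] == set(medium_panel.ids)
    # proportions close to 72 / 19.6 / 8.4
    assert abs(train.n / medium_panel.n - 0.72) < 0.03
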