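"""Gini importances, MDLP discretization and Bayesian-network machinery."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from laccoxkit.features import (
    BayesNet,
    bic_score,
    entropy,
    family_score,
    fit_cpts,
    gini_importance,
    hill_climb,
    markov_blanket,
    mdlp_discretize,
)


class TestEntropy:
    def test_fifty_fifty(self):
        assert entropy([0, 1, 0, 1]) == pytest.approx(1.0)

    def test_pure(self):
        assert entropy([1, 1, 1]) == 0.0

    def test_three_one_split(self):
        assert entropy([0, 0, 0, 1]) == pytest.approx(0.8112781244591328)


class _FakeTree:
    """Minimal sklearn-like tree_ structure for hand-computed examples."""

    def __init__(self, feature, left, right, weights, impurity):
        self.feature = np.asarray(feature)
        self.children_left = np.asarray(left)
        self.children_right = np.asarray(right)
        self.weighted_n_node_samples = np.asarray(weights, dtype=float)
        self.impurity = np.asarray(impurity, dtype=float)
        self.node_count = len(feature)
        self.n_features = int(self.feature.max()) + 1


def _forest(trees):
    return SimpleNamespace(
        estimators_=[SimpleNamespace(tree_=t) for t in trees],
        n_features_in_=max(t.n_features for t in trees),
    )


class TestGiniImportance:
    def test_perfect_stump(self):
        stump = _FakeTree(
            feature=[3, -2, -2],
            left=[1, -1, -1],
            right=[2, -1, -1],
            weights=[100, 50, 50],
            impurity=[0.5, 0.0, 0.0],
        )
        rep = gini_importance(_forest([stump]), n_features=5)
        np.testing.assert_allclose(rep.importances, [0, 0, 0, 1.0, 0])

    def test_depth_two_hand_arithmetic(self):
        # root splits on f0 (100 samples, G=0.48 -> 60/40 children with
        # G=0.3 and 0.2), left child splits on f1 into two pure leaves.
        tree = _FakeTree(
            feature=[0, 1, -2, -2, -2],
            left=[1, 3, -1, -1, -1],
            right=[2, 4, -1, -1, -1],
            weights=[100, 60, 40, 30, 30],
            impurity=[0.48, 0.3, 0.2, 0.0, 0.0],
        )
        d0 = (100 * 0.48 - 60 * 0.3 - 40 * 0.2) / 100
        d1 = (60 * 0.3 - 0 - 0) / 100
        rep = gini_importance(_forest([tree]), n_features=2)
        np.testing.assert_allclose(
            rep.importances, np.array([d0, d1]) / (d0 + d1), atol=1e-12
        )

    def test_matches_sklearn_mean_decrease_impurity(self, medium_panel):
        rf = RandomForestClassifier(n_estimators=30, random_state=0)
        rf.fit(medium_panel.X, medium_panel.y)
        rep = gini_importance(rf)
        np.testing.assert_allclose(rep.importances, rf.feature_importances_, atol=1e-10)
        assert rep.importances.sum() == pytest.approx(1.0)
        assert np.all(rep.importances >= 0)

    def test_empty_forest_errors(self):
        with pytest.raises(ValueError):
            gini_importance(SimpleNamespace(estimators_=[]))


class TestMdlp:
    def test_constant_y_no_cuts(self):
        x = np.arange(20, dtype=float)
        assert mdlp_discretize(x, np.zeros(20, dtype=int)) == []

    def test_perfect_separation_single_cut(self):
        x = np.concatenate([np.linspace(-5, -1, 10), np.linspace(1, 5, 10)])
        y = np.array([0] * 10 + [1] * 10)
        cuts = mdlp_discretize(x, y)
        assert len(cuts) == 1
        assert -1 < cuts[0] < 1

    def test_independent_feature_rarely_cut(self):
        rng = np.random.default_rng(0)
        n_cut = sum(
            bool(mdlp_discretize(rng.normal(size=30), rng.integers(0, 2, 30)))
            for _ in range(50)
        )
        assert n_cut <= 5  # the MDLP threshold suppresses spurious cuts


class TestBicScore:
    def test_closed_form_empty_graph(self):
        data = pd.DataFrame({"X": [0, 0, 1, 1]})
        score = bic_score({"X": ()}, data)
        assert score == pytest.approx(4 * math.log(0.5) - math.log(4) / 2)

    def test_additivity_over_families(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"A": rng.integers(0, 2, 50), "B": rng.integers(0, 3, 50)}
        )
        total = bic_score({"A": (), "B": ("A",)}, data)
        assert total == pytest.approx(
            family_score(data, "A", ()) + family_score(data, "B", ("A",))
        )

    def test_deterministic_dependence_favors_edge(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 100)
        data = pd.DataFrame({"X1": x, "X2": x})
        assert bic_score({"X1": (), "X2": ("X1",)}, data) > bic_score(
            {"X1": (), "X2": ()}, data
        )

    def test_missing_node_errors(self):
        with pytest.raises(ValueError):
            bic_score({"Z": ()}, pd.DataFrame({"X": [0, 1]}))


def _neighborhood_is_local_optimum(net: BayesNet, data: pd.DataFrame) -> bool:
    """Scan every single-edge operation; none may improve the BIC."""
    import itertools

    import networkx as nx

    base = bic_score(net, data)
    edges = set(net.edges)
    for u, v in itertools.permutations(net.nodes, 2):
        candidates = []
        if (u, v) in edges:
            candidates.append(edges - {(u, v)})
            candidates.append((edges - {(u, v)}) | {(v, u)})
        elif (v, u) not in edges:
            candidates.append(edges | {(u, v)})
        for cand in candidates:
            g = nx.DiGraph(list(cand))
            g.add_nodes_from(net.nodes)
            if not nx.is_directed_acyclic_graph(g):
                continue
            fams = {n: tuple(sorted(g.predecessors(n))) for n in net.nodes}
            if bic_score(fams, data) > base + 1e-9:
                return False
    return True


class TestHillClimb:
    def test_independent_uniform_gives_empty_graph(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            {f"V{i}": rng.integers(0, 2, 500) for i in range(4)}
        )
        net = hill_climb(data)
        assert net.edges == frozenset()

    def test_result_is_local_optimum(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 300)
        b = rng.integers(0, 2, 300)
        y = (a ^ b) | (rng.random(300) < 0.1)
        data = pd.DataFrame({"A": a, "B": b, "Y": y.astype(int)})
        net = hill_climb(data)
        assert _neighborhood_is_local_optimum(net, data)

    def test_v_structure_skeleton_recovered(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        noise = rng.random(1000) < 0.05
        y = ((a & b) ^ noise).astype(int)
        data = pd.DataFrame({"A": a, "B": b, "Y": y})
        net = hill_climb(data)
        skeleton = {frozenset(e) for e in net.edges}
        assert frozenset({"A", "Y"}) in skeleton
        assert frozenset({"B", "Y"}) in skeleton


class TestFitCpts:
    def test_single_node_frequency(self):
        data = pd.DataFrame({"X": [1] * 7 + [0] * 3})
        net = fit_cpts(BayesNet(("X",), frozenset()), data)
        np.testing.assert_allclose(net.cpts["X"][0], [0.3, 0.7])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(
            {"A": rng.integers(0, 3, 60), "B": rng.integers(0, 2, 60)}
        )
        net = fit_cpts(BayesNet(("A", "B"), frozenset({("A", "B")})), data)
        np.testing.assert_allclose(net.cpts["B"].sum(axis=1), 1.0, atol=1e-9)

    def test_chain_counts_row_normalized(self):
        # P(B|A) from a printed 2x2 count table: A=0 -> (3,1), A=1 -> (2,4)
        data = pd.DataFrame(
            {"A": [0] * 4 + [1] * 6, "B": [0, 0, 0, 1, 0, 0, 1, 1, 1, 1]}
        )
        net = fit_cpts(BayesNet(("A", "B"), frozenset({("A", "B")})), data)
        np.testing.assert_allclose(net.cpts["B"], [[0.75, 0.25], [2 / 6, 4 / 6]])

    def test_unseen_parent_config_uniform(self):
        data = pd.DataFrame({"A": [0, 0, 1], "B": [0, 1, 0], "C": [2, 0, 1]})
        net = fit_cpts(
            BayesNet(("A", "B", "C"), frozenset({("A", "C"), ("B", "C")})), data
        )
        # parent config (A=1, B=1) never observed -> uniform row over C's states
        rows = net.cpts["C"]
        assert any(np.allclose(r, 1 / 3) for r in rows)


class TestMarkovBlanket:
    def _net(self, edges):
        nodes = tuple(sorted({n for e in edges for n in e} | {"Y"}))
        return BayesNet(nodes, frozenset(edges))

    def test_isolated_target(self):
        net = BayesNet(("A", "Y"), frozenset())
        assert markov_blanket(net, "Y") == set()

    def test_parent_child_coparent(self):
        net = self._net([("A", "Y"), ("Y", "C"), ("B", "C")])
        assert markov_blanket(net, "Y") == {"A", "B", "C"}

    def test_chain(self):
        net = self._net([("A", "Y"), ("Y", "B")])
        assert markov_blanket(net, "Y") == {"A", "B"}

    def test_unknown_target(self):
        with pytest.raises(ValueError):
            markov_blanket(BayesNet(("A",), frozenset()), "Z")
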