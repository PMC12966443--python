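"""Class weights, metrics, nested CV protocol, ensembling and comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier

from laccoxkit.evaluate import (
    CVReport,
    ClassifierSpec,
    auroc_score,
    class_weights,
    compare_models,
    default_specs,
    ensemble_predict,
    metrics,
    nested_cv,
)

from conftest import make_descriptor_dataset


class TestClassWeights:
    def test_balanced_symmetry(self):
        w = class_weights([0, 1] * 10)
        assert w.w1 == w.w0 == 1.0

    def test_imbalanced_panel_weights(self):
        # the 74%-positive regime: w1 = 100/148, w0 = 100/52
        y = [1] * 74 + [0] * 26
        w = class_weights(y)
        assert w.w1 == pytest.approx(100 / 148)
        assert w.w0 == pytest.approx(100 / 52)
        assert (w.n, w.n1, w.n0) == (100, 74, 26)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestMetrics:
    def test_perfect_probabilities(self):
        y = [1, 0, 1, 0, 1]
        p = [1.0, 0.0, 1.0, 0.0, 1.0]
        m = metrics(y, p)
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1", "auroc"))

    def test_constant_probability_closed_form(self):
        y = [1, 0] * 10
        m = metrics(y, [0.6] * 20)
        assert m["accuracy"] == 0.5
        assert m["recall"] == 1.0
        assert m["precision"] == 0.5
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["auroc"] == 0.5

    def test_threshold_tie_predicts_positive(self):
        m = metrics([1], [0.5])
        assert m["recall"] == 1.0

    def test_single_class_auroc_missing(self):
        m = metrics([1, 1], [0.9, 0.8])
        assert m["auroc"] is None

    def test_auroc_monotone_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        p = rng.random(50)
        a1 = auroc_score(y, p)
        a2 = auroc_score(y, 1 / (1 + np.exp(-5 * (p - 0.3))))  # strictly monotone
        assert a1 == pytest.approx(a2)


class TestEnsemble:
    def test_single_model_identity(self):
        p = np.array([0.2, 0.8, 0.55])
        mean, labels = ensemble_predict([p])
        np.testing.assert_array_equal(mean, p)
        np.testing.assert_array_equal(labels, [0, 1, 1])

    def test_tie_rule(self):
        mean, labels = ensemble_predict([np.array([0.6]), np.array([0.4])])
        assert mean[0] == pytest.approx(0.5)
        assert labels[0] == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ensemble_predict([])


def _majority_spec():
    return ClassifierSpec(
        "majority",
        grid={},
        builder=lambda params, seed: DummyClassifier(strategy="prior"),
        scale=False,
    )


class TestNestedCV:
    def test_shape_contract_and_stub_stability(self):
        rng = np.random.default_rng(2)
        ds = make_descriptor_dataset(rng.normal(size=(100, 3)), [1] * 60 + [0] * 40)
        rep = nested_cv(ds, [_majority_spec()], n_seeds=4, smote=False)
        assert len(rep.rows) == 4
        # stratified splits give the stub identical metrics every seed
        assert rep.rows["accuracy"].std() == 0.0
        assert rep.summary[("auroc", "std")].iloc[0] == 0.0

    def test_report_rows_per_seed_and_model(self, medium_panel):
        specs = default_specs(["rfc"])
        specs[0].grid = {"n_estimators": [20], "max_depth": [4]}
        rep = nested_cv(medium_panel, specs, n_seeds=2)
        assert len(rep.rows) == 2 * 1
        assert set(rep.rows["model"]) == {"rfc"}
        assert not rep.rows["failed"].any()
        assert (rep.rows["auroc"] > 0.6).all()

    def test_learner_failure_marks_cell(self):
        def broken(params, seed):
            raise RuntimeError("boom")

        ds = make_descriptor_dataset(
            np.random.default_rng(0).normal(size=(40, 2)), [0, 1] * 20
        )
        rep = nested_cv(
            ds,
            [ClassifierSpec("broken", {}, builder=broken, scale=False), _majority_spec()],
            n_seeds=2,
            smote=False,
        )
        assert rep.rows[rep.rows["model"] == "broken"]["failed"].all()
        assert not rep.rows[rep.rows["model"] != "broken"]["failed"].any()

    def test_empty_specs_error(self, medium_panel):
        with pytest.raises(ValueError):
            nested_cv(medium_panel, [])


def _report_from(per_model: dict[str, list[float]]) -> CVReport:
    rows = []
    for model, values in per_model.items():
        for seed, v in enumerate(values):
            rows.append(
                {
                    "seed": seed,
                    "model": model,
                    "failed": False,
                    "accuracy": v,
                    "precision": v,
                    "recall": v,
                    "f1": v,
                    "auroc": v,
                }
            )
    return CVReport(pd.DataFrame(rows))


class TestCompareModels:
    def test_identical_models_p_one(self):
        rep = _report_from({"a": [0.8, 0.7, 0.9], "b": [0.8, 0.7, 0.9]})
        cmp = compare_models(rep)
        assert cmp.wilcoxon_p.loc["a", "b"] == 1.0

    def test_rank_ordering(self):
        rep = _report_from(
            {"a": [0.9] * 3, "b": [0.8] * 3, "c": [0.7] * 3}
        )
        cmp = compare_models(rep)
        assert cmp.auroc_ranks["dataset_0"].tolist() == [1.0, 2.0, 3.0]

    def test_average_rank_ties(self):
        rep = _report_from(
            {"a": [0.9] * 3, "b": [0.9] * 3, "c": [0.7] * 3}
        )
        cmp = compare_models(rep)
        assert cmp.auroc_ranks["dataset_0"].tolist() == [1.5, 1.5, 3.0]

    def test_summed_ranks_across_datasets(self):
        r1 = _report_from({"a": [0.9] * 3, "b": [0.8] * 3})
        r2 = _report_from({"a": [0.7] * 3, "b": [0.8] * 3})
        cmp = compare_models([r1, r2])
        assert cmp.summed_ranks["a"] == 3.0 and cmp.summed_ranks["b"] == 3.0
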