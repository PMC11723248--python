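import numpy as np
import pandas as pd
import pytest

from ifptml.models import (
    DeepANNClassifier,
    LDARFEClassifier,
    MLPCClassifier,
    ModelSpec,
    TreeClassifier,
    extract_tree_report,
    make_model,
)


def planted_matrix(n=300, p=20, n_signal=2, seed=0):
    """Gaussian design where only the first columns carry the outcome."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i:02d}" for i in range(p)]
    )
    score = sum(3.0 * X[f"f{i:02d}"] for i in range(n_signal))
    y = (score + rng.normal(0, 0.5, n) > 0).astype(int).to_numpy()
    return X, y


class TestModelSpec:
    def test_family_and_constraint_validation(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec(family="SVM")
        with pytest.raises(ValueError, match="max_leaf_nodes"):
            ModelSpec(family="DTC", hyperparameters={"max_leaf_nodes": 1})
        with pytest.raises(ValueError, match="epochs"):
            ModelSpec(family="DEEP_ANN", hyperparameters={"epochs": 0})

    def test_factory_dispatch(self):
        assert isinstance(make_model(ModelSpec("LDA")), LDARFEClassifier)
        assert isinstance(make_model(ModelSpec("DTC")), TreeClassifier)
        assert isinstance(make_model(ModelSpec("MLPC")), MLPCClassifier)
        assert isinstance(make_model(ModelSpec("DEEP_ANN")), DeepANNClassifier)


class TestLDARFE:
    def test_planted_columns_survive_elimination(self):
        X, y = planted_matrix()
        model = LDARFEClassifier(n_features=10, n_boot=10).fit(X, y)
        assert len(model.selected_features_) == 10
        assert {"f00", "f01"} <= set(model.selected_features_)

    def test_no_elimination_when_n_features_equals_columns(self):
        X, y = planted_matrix(p=5)
        model = LDARFEClassifier(n_features=5, n_boot=2).fit(X, y)
        assert model.selected_features_ == list(X.columns)

    def test_seeded_rerun_identical(self):
        X, y = planted_matrix()
        m1 = LDARFEClassifier(n_features=8, n_boot=5, random_state=3).fit(X, y)
        m2 = LDARFEClassifier(n_features=8, n_boot=5, random_state=3).fit(X, y)
        assert m1.selected_features_ == m2.selected_features_
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
        pd.testing.assert_frame_equal(m1.bootstrap_trace_, m2.bootstrap_trace_)

    def test_bootstrap_trace_length(self):
        X, y = planted_matrix(n=120)
        model = LDARFEClassifier(n_features=5, n_boot=7).fit(X, y)
        assert len(model.bootstrap_trace_) <= 7
        assert {"sn_train", "sp_train"} <= set(model.bootstrap_trace_.columns)

    def test_single_class_rejected(self):
        X, _ = planted_matrix(n=40)
        with pytest.raises(ValueError, match="single class"):
            LDARFEClassifier().fit(X, np.ones(40, dtype=int))


class TestTree:
    def test_separable_data_perfect_with_few_leaves(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        y = (X["a"] > 0).astype(int).to_numpy()
        model = TreeClassifier(n_features=2, max_leaf_nodes=3, n_iter=5).fit(X, y)
        assert (model.predict(X) == y).all()
        assert model.estimator_.get_n_leaves() <= 3

    def test_leaf_budget_honored(self):
        X, y = planted_matrix(n=500)
        model = TreeClassifier(max_leaf_nodes=40, n_iter=5).fit(X, y)
        assert model.estimator_.get_n_leaves() <= 40

    def test_planted_features_among_selected(self):
        X, y = planted_matrix(n=600, n_signal=3, seed=5)
        model = TreeClassifier(n_features=15, n_iter=20).fit(X, y)
        hits = {"f00", "f01", "f02"} & set(model.selected_features_)
        assert len(hits) >= 2

    def test_best_iteration_dominates_trace(self):
        X, y = planted_matrix(n=200)
        model = TreeClassifier(n_iter=15).fit(X, y)
        assert model.best_score_ == pytest.approx(
            model.iteration_trace_["balanced_accuracy"].max()
        )

    def test_probabilities_are_leaf_fractions(self):
        X, y = planted_matrix(n=200, seed=2)
        model = TreeClassifier(n_iter=3).fit(X, y)
        proba = model.predict_proba(X)[:, 1]
        tree = model.estimator_.tree_
        counts = tree.value[model.estimator_.apply(
            X[model.selected_features_].to_numpy())][:, 0, :]
        np.testing.assert_allclose(proba, counts[:, 1] / counts.sum(axis=1))

    def test_missing_feature_column_named_in_error(self):
        X, y = planted_matrix(n=100)
        model = TreeClassifier(n_iter=2).fit(X, y)
        gone = model.selected_features_[0]
        with pytest.raises(KeyError, match=gone):
            model.predict(X.drop(columns=[gone]))


class TestNetworks:
    def test_mlpc_overfits_separable_rows(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=list("abcd"))
        y = (X["a"] > 0).astype(int).to_numpy()
        model = MLPCClassifier(hidden_layers=(100, 100),
                               max_iter=600).fit(X, y)
        from ifptml.evaluate import auroc

        assert auroc(y, model.predict_proba(X)[:, 1]) >= 0.99

    def test_mlpc_seeded_loss_trajectory_identical(self):
        X, y = planted_matrix(n=100, p=5)
        m1 = MLPCClassifier(max_iter=30, random_state=4).fit(X, y)
        m2 = MLPCClassifier(max_iter=30, random_state=4).fit(X, y)
        assert m1.loss_history_ == m2.loss_history_

    def test_empty_hidden_layers_warns_and_fits(self):
        X, y = planted_matrix(n=80, p=4)
        with pytest.warns(UserWarning, match="logistic"):
            model = MLPCClassifier(hidden_layers=()).fit(X, y)
        assert model.predict_proba(X).shape == (80, 2)

    def test_deep_ann_loss_history_length_equals_epochs(self):
        X, y = planted_matrix(n=80, p=6)
        model = DeepANNClassifier(hidden=(16, 8), epochs=40,
                                  batch_size=16).fit(X, y)
        assert len(model.loss_history_) == 40

    def test_deep_ann_learns_planted_signal(self):
        from ifptml.evaluate import auroc

        X, y = planted_matrix(n=400, p=10, n_signal=3, seed=7)
        model = DeepANNClassifier(epochs=200, batch_size=32,
                                  random_state=7).fit(X.iloc[:300], y[:300])
        assert auroc(y[300:], model.predict_proba(X.iloc[300:])[:, 1]) > 0.8


class TestTreeReport:
    def test_single_split_tree(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = (X["a"] > 0.2).astype(int).to_numpy()
        model = TreeClassifier(n_features=1, max_leaf_nodes=2, n_iter=1).fit(X, y)
        report = extract_tree_report(model, depth=1)
        root = report[0]
        assert root["feature"] == "a"
        assert root["share"] == 1.0
        assert root["threshold"] == pytest.approx(0.2, abs=0.3)

    def test_shares_partition_at_any_depth(self, small_db):
        from ifptml.models import ModelSpec
        from ifptml.pipeline import run_pipeline

        res = run_pipeline(small_db.records, small_db.descriptors,
                           small_db.cutoffs,
                           ModelSpec("DTC", n_iterations=5, seed=2), seed=2)
        for depth in (1, 2, 3):
            report = extract_tree_report(res.model, depth=depth)
            leaves = [e for e in report if e["leaf"]]
            assert sum(e["share"] for e in leaves) == pytest.approx(1.0)
            assert all(0 <= e["p_good"] <= 1 for e in leaves)


def test_all_families_share_contract(small_db):
    """Pipeline code is family-agnostic: same fit/predict surface."""
    from ifptml.fusion import fuse_dataset
    from ifptml.featurize import build_design_matrix

    fused, _ = fuse_dataset(small_db.records[:200], small_db.cutoffs)
    X, y, _ = build_design_matrix(fused, small_db.descriptors)
    for spec in (ModelSpec("LDA", {"n_boot": 3}),
                 ModelSpec("DTC", {"n_iter": 3}),
                 ModelSpec("MLPC", {"max_iter": 40}),
                 ModelSpec("DEEP_ANN", {"epochs": 10})):
        model = make_model(spec).fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (len(y), 2)
        assert ((proba >= 0) & (proba <= 1)).all()
        np.testing.assert_array_equal(
            model.predict(X), (proba[:, 1] >= 0.5).astype(int)
        )
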