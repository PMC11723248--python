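"""The four model families trained on the PT design matrix.

All estimators follow the scikit-learn contract (``fit`` /
``predict_proba`` / ``predict`` / ``get_params``) and share a common
surface: after fitting, ``selected_features_`` names the design-matrix
columns the model actually uses, and ``predict_proba`` returns the
probability of a *good* print.  Class labels come from thresholding the
probability at 0.5.

Families
--------
``LDARFEClassifier``
    Linear discriminant analysis with recursive feature elimination down
    to 10 variables; model quality is profiled by bootstrap resampling
    (100 iterations) recording sensitivity/specificity per iteration.
``TreeClassifier``
    Decision tree (<= 40 leaf nodes) on the top-15 features by impurity
    importance; 100 resampled training repetitions, keeping the iteration
    with the best validation balanced accuracy.  Leaf class fractions are
    the predicted probabilities, and the top splits can be read out as
    family rules.
``MLPCClassifier``
    Multi-layer perceptron classifier with configurable dense hidden
    layers (e.g. 100-100).
``DeepANNClassifier``
    Deeper dense network (default hidden stack 64-32-32-32) with ReLU
    activations, sigmoid output, Adam optimizer and binary cross-entropy
    loss, trained for a fixed number of epochs with mini-batches; the
    per-epoch loss history is retained.  Built on scikit-learn's
    ``MLPClassifier``, whose log-loss objective is binary cross-entropy
    for binary targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelSpec",
    "LDARFEClassifier",
    "TreeClassifier",
    "MLPCClassifier",
    "DeepANNClassifier",
    "extract_tree_report",
    "make_model",
]

FAMILIES = ("LDA", "DTC", "MLPC", "DEEP_ANN")


@dataclass
class ModelSpec:
    """Declarative description of a model family + hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    n_iterations: int = 100

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        hp = self.hyperparameters
        if self.family == "DTC":
            if hp.get("max_leaf_nodes", 40) < 2:
                raise ValueError("DTC needs max_leaf_nodes >= 2")
            if hp.get("n_features", 15) < 1:
                raise ValueError("DTC needs n_features >= 1")
        if self.family == "DEEP_ANN":
            if hp.get("epochs", 1000) < 1 or hp.get("batch_size", 32) < 1:
                raise ValueError("DEEP_ANN needs epochs >= 1, batch_size >= 1")


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            "training outcomes contain a single class; cannot fit"
        )
    if not set(classes) <= {0, 1}:
        raise ValueError(f"outcomes must be binary 0/1, got {classes}")
    return y


def _sn_sp(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos, neg = y_true == 1, y_true == 0
    sn = float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    sp = float(np.mean(y_pred[neg] == 0)) if neg.any() else np.nan
    return sn, sp


class _PTModelBase(BaseEstimator, ClassifierMixin):
    """Shared feature-subset bookkeeping and prediction surface."""

    def _subset(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "selected_features_")
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from input: {missing}")
        return X[self.selected_features_].to_numpy(dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of a good print per row, columns [p(0), p(1)]."""
        return self.estimator_.predict_proba(self._subset(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous score used for ranking (probability of class 1)."""
        return self.predict_proba(X)[:, 1]


class LDARFEClassifier(_PTModelBase):
    """Linear discriminant model with recursive feature elimination.

    Each elimination round fits the discriminant on the surviving
    features and drops the ``step`` features with the smallest absolute
    standardized coefficient, until ``n_features`` remain.  The final
    model is refit on the full training set with the survivors.  A
    bootstrap profile (``n_boot`` resamples with replacement) records
    in-bag and out-of-bag sensitivity/specificity per iteration.
    """

    def __init__(self, n_features: int = 10, n_boot: int = 100, step: int = 1,
                 random_state: int = 0):
        self.n_features = n_features
        self.n_boot = n_boot
        self.step = step
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "LDARFEClassifier":
        y = _check_binary(y)
        if self.n_features > X.shape[1]:
            raise ValueError(
                f"n_features={self.n_features} exceeds column count "
                f"{X.shape[1]}"
            )
        rng = np.random.default_rng(self.random_state)
        survivors = list(X.columns)

        while len(survivors) > self.n_features:
            lda = LinearDiscriminantAnalysis().fit(
                X[survivors].to_numpy(dtype=float), y
            )
            # rank by |coef| on standardized columns so scale cannot mask
            # an informative feature
            scale = X[survivors].std(axis=0).to_numpy()
            scale[scale == 0] = 1.0
            importance = np.abs(lda.coef_[0]) * scale
            k = min(self.step, len(survivors) - self.n_features)
            for idx in sorted(np.argsort(importance)[:k], reverse=True):
                del survivors[idx]

        self.selected_features_ = list(survivors)
        Xs = X[survivors].to_numpy(dtype=float)
        self.estimator_ = LinearDiscriminantAnalysis().fit(Xs, y)
        self.classes_ = self.estimator_.classes_

        trace = []
        n = len(y)
        for it in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if np.unique(y[idx]).size < 2:
                continue
            m = LinearDiscriminantAnalysis().fit(Xs[idx], y[idx])
            sn_in, sp_in = _sn_sp(y[idx], m.predict(Xs[idx]))
            if oob.size and np.unique(y[oob]).size == 2:
                sn_out, sp_out = _sn_sp(y[oob], m.predict(Xs[oob]))
            else:
                sn_out = sp_out = np.nan
            trace.append(
                {"iteration": it, "sn_train": sn_in, "sp_train": sp_in,
                 "sn_oob": sn_out, "sp_oob": sp_out}
            )
        self.bootstrap_trace_ = pd.DataFrame(trace)
        return self


class TreeClassifier(_PTModelBase):
    """Decision-tree printability classifier with iteration selection.

    Feature reduction ranks columns by impurity importance *averaged
    over bootstrap-resampled preliminary trees* (``n_iter`` of them) and
    keeps the top ``n_features``.  Averaging matters because
    perturbation columns of one descriptor across different conditions
    are nearly collinear, and a single greedy tree attributes their
    shared importance to an arbitrary member of the group; bagging the
    ranking concentrates importance on the column that genuinely carries
    the signal.  ``n_iter`` trees are then trained on bootstrap
    resamples of the reduced training rows and the iteration with the
    best balanced accuracy ``(Sn + Sp) / 2`` on the validation split (or
    on the training rows when no validation data is supplied) is
    retained.  Probabilities are leaf class fractions.
    """

    def __init__(self, n_features: int = 15, max_leaf_nodes: int = 40,
                 n_iter: int = 100, random_state: int = 0):
        self.n_features = n_features
        self.max_leaf_nodes = max_leaf_nodes
        self.n_iter = n_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, X_val: pd.DataFrame | None = None,
            y_val=None) -> "TreeClassifier":
        y = _check_binary(y)
        Xf = X.to_numpy(dtype=float)
        n = len(y)
        rng = np.random.default_rng(self.random_state)
        importance = np.zeros(X.shape[1])
        for it in range(max(1, self.n_iter)):
            idx = rng.integers(0, n, size=n) if it else np.arange(n)
            if np.unique(y[idx]).size < 2:
                continue
            prelim = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(Xf[idx], y[idx])
            importance += prelim.feature_importances_
        order = np.argsort(importance)[::-1]
        n_keep = min(self.n_features, X.shape[1])
        self.selected_features_ = [X.columns[i] for i in sorted(order[:n_keep])]

        Xs = X[self.selected_features_].to_numpy(dtype=float)
        if X_val is not None:
            Xv = X_val[self.selected_features_].to_numpy(dtype=float)
            yv = np.asarray(y_val, dtype=int)
        else:
            Xv, yv = Xs, y

        best, best_score, trace = None, -np.inf, []
        for it in range(self.n_iter):
            idx = rng.integers(0, n, size=n) if it else np.arange(n)
            if np.unique(y[idx]).size < 2:
                continue
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(Xs[idx], y[idx])
            sn, sp = _sn_sp(yv, tree.predict(Xv))
            score = (sn + sp) / 2
            trace.append({"iteration": it, "sn_val": sn, "sp_val": sp,
                          "balanced_accuracy": score})
            if score > best_score:
                best, best_score = tree, score
        self.estimator_ = best
        self.classes_ = best.classes_
        self.best_score_ = best_score
        self.iteration_trace_ = pd.DataFrame(trace)
        return self


class MLPCClassifier(_PTModelBase):
    """Dense multi-layer perceptron classifier.

    ``hidden_layers=[100, 100]`` reproduces the two-hidden-layer,
    100-neuron architecture family; an empty list degrades to a plain
    logistic-type model (a warning is emitted).
    """

    def __init__(self, hidden_layers: Sequence[int] = (100, 100),
                 max_iter: int = 300, random_state: int = 0):
        self.hidden_layers = hidden_layers
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "MLPCClassifier":
        y = _check_binary(y)
        self.selected_features_ = list(X.columns)
        hidden = tuple(self.hidden_layers)
        if not hidden:
            import warnings

            from sklearn.linear_model import LogisticRegression

            warnings.warn(
                "empty hidden_layers: fitting a plain logistic model",
                stacklevel=2,
            )
            self.estimator_ = LogisticRegression(
                max_iter=self.max_iter, random_state=self.random_state
            ).fit(X.to_numpy(dtype=float), y)
            self.classes_ = self.estimator_.classes_
            self.loss_history_ = []
            return self
        self.estimator_ = MLPClassifier(
            hidden_layer_sizes=hidden,
            activation="relu",
            solver="adam",
            max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(X.to_numpy(dtype=float), y)
        self.classes_ = self.estimator_.classes_
        self.loss_history_ = list(self.estimator_.loss_curve_)
        return self


class DeepANNClassifier(_PTModelBase):
    """Deep dense network: ReLU hidden stack, sigmoid output, Adam
    optimizer, binary cross-entropy loss.

    The default hidden stack is ``[64, 32, 32, 32]``; the shallower
    ``[64, 32, 32]`` variant is a supported alternative.  Training runs
    for exactly ``epochs`` passes with the given mini-batch size (early
    stopping disabled so the loss history length equals ``epochs``).
    """

    EPOCH_GRID = (100, 200, 500, 1000, 2000)
    BATCH_GRID = (32, 64, 128)

    def __init__(self, hidden: Sequence[int] = (64, 32, 32, 32),
                 epochs: int = 1000, batch_size: int = 32,
                 random_state: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "DeepANNClassifier":
        y = _check_binary(y)
        self.selected_features_ = list(X.columns)
        self.estimator_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden),
            activation="relu",
            solver="adam",
            batch_size=min(self.batch_size, len(y)),
            max_iter=self.epochs,
            n_iter_no_change=self.epochs,  # run every epoch
            tol=0.0,
            random_state=self.random_state,
        ).fit(X.to_numpy(dtype=float), y)
        self.classes_ = self.estimator_.classes_
        self.loss_history_ = list(self.estimator_.loss_curve_)
        return self


def extract_tree_report(model: TreeClassifier, depth: int = 3) -> list[dict]:
    """Read out the top splits of a fitted tree as family rules.

    Returns one entry per node down to ``depth`` (root = depth 1):
    the split feature, threshold, and the fraction of training rows
    routed through the node.  Subtrees cut off at the depth limit appear
    as leaves, so the leaf/cut shares at any depth partition the data.
    """
    check_is_fitted(model, "estimator_")
    tree = model.estimator_.tree_
    names = model.selected_features_
    total = tree.n_node_samples[0]
    report: list[dict] = []

    def walk(node: int, level: int) -> None:
        share = tree.n_node_samples[node] / total
        is_leaf = tree.children_left[node] == -1
        if is_leaf or level > depth:
            counts = tree.value[node][0]
            report.append(
                {"node": int(node), "depth": level, "leaf": True,
                 "share": float(share),
                 "p_good": float(counts[-1] / counts.sum())}
            )
            return
        report.append(
            {"node": int(node), "depth": level, "leaf": False,
             "feature": names[tree.feature[node]],
             "threshold": float(tree.threshold[node]),
             "share": float(share)}
        )
        walk(tree.children_left[node], level + 1)
        walk(tree.children_right[node], level + 1)

    walk(0, 1)
    return report


def make_model(spec: ModelSpec):
    """Instantiate the estimator described by a :class:`ModelSpec`."""
    hp = dict(spec.hyperparameters)
    if spec.family == "LDA":
        return LDARFEClassifier(
            n_features=hp.pop("n_features", 10),
            n_boot=hp.pop("n_boot", spec.n_iterations),
            step=hp.pop("step", 1),
            random_state=spec.seed,
        )
    if spec.family == "DTC":
        return TreeClassifier(
            n_features=hp.pop("n_features", 15),
            max_leaf_nodes=hp.pop("max_leaf_nodes", 40),
            n_iter=hp.pop("n_iter", spec.n_iterations),
            random_state=spec.seed,
        )
    if spec.family == "MLPC":
        return MLPCClassifier(
            hidden_layers=hp.pop("hidden_layers", (100, 100)),
            max_iter=hp.pop("max_iter", 300),
            random_state=spec.seed,
        )
    return DeepANNClassifier(
        hidden=hp.pop("hidden", (64, 32, 32, 32)),
        epochs=hp.pop("epochs", 1000),
        batch_size=hp.pop("batch_size", 32),
        random_state=spec.seed,
    )
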