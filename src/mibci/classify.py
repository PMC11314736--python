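"""Classifier wrappers: LDA, RBF-kernel SVM, and a small MLP.

All three are trained on z-scored features (scaler fitted on the training
data only) and expose a real-valued decision score where larger means
stronger class-2 preference, which the evaluation harness feeds to AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable

KINDS = ("lda", "svm_rbf", "mlp")


@dataclass
class ClassifierSpec:
    """Which classifier to build and with what hyperparameters.

    Defaults: SVM uses C=1 with the RBF kernel and gamma='scale'; the MLP has
    a single hidden layer of ten units.
    """

    kind: str = "lda"
    hyper: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind '{self.kind}'; valid: {KINDS}")
        h = self.hyper
        if self.kind == "svm_rbf" and h.get("C", 1.0) <= 0:
            raise ValueError("C must be > 0")
        if self.kind == "mlp" and h.get("hidden_size", 10) < 1:
            raise ValueError("hidden_size must be >= 1")


def _build(spec: ClassifierSpec):
    h = spec.hyper
    if spec.kind == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=h.get("shrinkage"))
    elif spec.kind == "svm_rbf":
        clf = SVC(kernel="rbf", C=h.get("C", 1.0), gamma=h.get("gamma", "scale"))
    else:
        clf = MLPClassifier(
            hidden_layer_sizes=(h.get("hidden_size", 10),),
            max_iter=h.get("max_epochs", 500),
            random_state=h.get("seed", 0),
            early_stopping=False,
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class FittedModel:
    """A trained scaler+classifier pipeline with its input width."""

    pipeline: Pipeline
    spec: ClassifierSpec
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check(X)
        return self.pipeline.predict(X)

    def _check(self, X: np.ndarray) -> None:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} feature columns, got shape {X.shape}")


def train(spec: ClassifierSpec, X: FeatureTable | np.ndarray, y: np.ndarray | None = None) -> FittedModel:
    """Fit a classifier; deterministic for LDA/SVM, seeded for the MLP.

    Raises when only one class is present.  MLP non-convergence produces a
    warning from the underlying solver but still returns the model.
    """
    if isinstance(X, FeatureTable):
        y = X.labels if y is None else y
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    pipe = _build(spec)
    pipe.fit(X, y)
    return FittedModel(pipeline=pipe, spec=spec, n_features=X.shape[1])


def decision_scores(model: FittedModel, X: np.ndarray | FeatureTable) -> np.ndarray:
    """Real-valued scores: higher means stronger preference for the larger label.

    score > 0 iff the predicted label is class 2 (LDA/SVM use the signed
    distance to the decision boundary; the MLP uses the class-2 posterior
    minus one half).
    """
    if isinstance(X, FeatureTable):
        X = X.values
    X = np.asarray(X, dtype=float)
    model._check(X)
    pipe = model.pipeline
    clf = pipe.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return pipe.decision_function(X)
    proba = pipe.predict_proba(X)
    pos_col = int(np.argmax(clf.classes_))
    return proba[:, pos_col] - 0.5
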