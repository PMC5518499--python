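"""Classifier adapters (SVM, MLP) and stratified cross-validated evaluation.

The tunables exposed to the evolvers are the SVM soft-margin cost C and
the MLP learning rate / momentum, each bounded in [0, 1].  A value of 0
for C or the learning rate is mapped to a tiny positive floor so the
underlying solvers stay defined.  Evaluation pools TP/TN/FP/FN over the
stratified test folds, so the class-total identities hold exactly for
the whole dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .data import Dataset, one_hot_encode
from .errors import BoundViolationError, DegenerateFoldError
from .evolvers import ParameterSpec
from .objectives import ConfusionCounts, confusion_counts

__all__ = [
    "ClassifierSpec",
    "CVConfig",
    "svm_spec",
    "mlp_spec",
    "default_params",
    "hidden_layer_size",
    "train_classifier",
    "evaluate_params",
]

_PARAM_FLOOR = 1e-6  # smallest admissible positive value for C / learning rate


@dataclass(frozen=True)
class ClassifierSpec:
    """Contract for a tunable classifier: kind, tunables and fixed settings."""

    kind: str  # "svm" | "mlp"
    tunables: tuple  # of ParameterSpec
    fixed_settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("svm", "mlp"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        object.__setattr__(self, "tunables", tuple(self.tunables))


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    shuffle_seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def svm_spec(kernel: str = "linear", gamma: float = 1.0) -> ClassifierSpec:
    """SVM with evolvable cost C in [0, 1]; kernel fixed (linear default)."""
    return ClassifierSpec(
        kind="svm",
        tunables=(ParameterSpec("cost", 0.0, 1.0),),
        fixed_settings={"kernel": kernel, "gamma": gamma},
    )


def mlp_spec(epochs: int = 500) -> ClassifierSpec:
    """MLP with evolvable learning rate and momentum, both in [0, 1]."""
    return ClassifierSpec(
        kind="mlp",
        tunables=(
            ParameterSpec("learning_rate", 0.0, 1.0),
            ParameterSpec("momentum", 0.0, 1.0),
        ),
        fixed_settings={"epochs": epochs},
    )


def default_params(spec: ClassifierSpec) -> np.ndarray:
    """Out-of-the-box parameter vector (Weka defaults: C=1, eta=0.3, alpha=0.2)."""
    if spec.kind == "svm":
        return np.array([1.0])
    return np.array([0.3, 0.2])


def hidden_layer_size(n_inputs: int, n_outputs: int = 2) -> int:
    """Single hidden layer sized to the mean of input and output layer sizes."""
    return int(round((n_inputs + n_outputs) / 2.0))


def _check_bounds(spec: ClassifierSpec, params) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if params.shape != (len(spec.tunables),):
        raise BoundViolationError(
            f"expected {len(spec.tunables)} parameters, got shape {params.shape}"
        )
    for p, v in zip(spec.tunables, params):
        if not p.lower <= v <= p.upper:
            raise BoundViolationError(f"{p.name}={v} outside [{p.lower}, {p.upper}]")
    return params


def _build_estimator(spec: ClassifierSpec, params: np.ndarray, n_inputs: int, seed: int):
    if spec.kind == "svm":
        cost = max(float(params[0]), _PARAM_FLOOR)
        kernel = spec.fixed_settings.get("kernel", "linear")
        gamma = spec.fixed_settings.get("gamma", 1.0)
        return SVC(kernel=kernel, C=cost, gamma=gamma, random_state=seed)
    eta = max(float(params[0]), _PARAM_FLOOR)
    momentum = min(float(params[1]), 1.0 - 1e-9)
    return MLPClassifier(
        hidden_layer_sizes=(hidden_layer_size(n_inputs),),
        activation="logistic",
        solver="sgd",
        learning_rate_init=eta,
        momentum=momentum,
        nesterovs_momentum=False,
        max_iter=int(spec.fixed_settings.get("epochs", 500)),
        random_state=seed,
    )


def train_classifier(spec: ClassifierSpec, params, train: Dataset, seed: int = 0):
    """Fit one classifier on a dataset; deterministic for a fixed seed."""
    params = _check_bounds(spec, params)
    y = train.labels
    if len(np.unique(y)) < 2:
        raise DegenerateFoldError("training data contains a single class")
    X = one_hot_encode(train)
    est = _build_estimator(spec, params, X.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def evaluate_params(
    spec: ClassifierSpec,
    params,
    ds: Dataset,
    cv: CVConfig = CVConfig(),
    seed: int = 0,
) -> ConfusionCounts:
    """Stratified k-fold evaluation pooling confusion counts over test folds."""
    params = _check_bounds(spec, params)
    X = one_hot_encode(ds)
    y = ds.labels
    m1 = int(y.sum())
    m2 = len(y) - m1
    if cv.stratified and cv.n_folds > min(m1, m2):
        raise DegenerateFoldError(
            f"n_folds={cv.n_folds} exceeds minority class size {min(m1, m2)}"
        )
    splitter = StratifiedKFold(
        n_splits=cv.n_folds, shuffle=True, random_state=cv.shuffle_seed
    )
    total = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in splitter.split(X, y):
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            raise DegenerateFoldError("a training fold contains a single class")
        est = _build_estimator(spec, params, X.shape[1], seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X[train_idx], y_train)
        pred = est.predict(X[test_idx])
        total = total + confusion_counts(y[test_idx], pred)
    return total
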