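"""Static classification tasks and their cross-validated evaluation.

Ten binary tasks are defined on the normalised input square [0, 1]^2
(formaldehyde x NaOH).  A linear support-vector classifier is trained on
standardised steady-state reservoir features and evaluated with a
stratified leave-five-out cross-validation: 20 repeats of 26 random
disjoint test splits of five inputs each (520 train/test evaluations for
the default 132-point grid).  Performance is reported as the Phi
(Matthews correlation) score mapped to [0, 1] via (Phi + 1) / 2.

Because the tasks are published only as shaded regions, the boundary
definitions below are this package's canonical, explicitly stated
choices; all are configurable by registering a replacement
:class:`TaskDef`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

__all__ = [
    "TaskDef",
    "TASKS",
    "task_label",
    "ContingencyCounts",
    "phi_score",
    "phi_accuracy",
    "standardize",
    "Standardization",
    "ClassifierReadout",
    "train_linear_svc",
    "CVResult",
    "cross_validate",
    "ELMClassifier",
    "baseline_suite",
]


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# task definitions

@dataclass(frozen=True)
class TaskDef:
    """A binary task on the unit square: name, indicator, linearity flag."""

    name: str
    indicator: Callable[[np.ndarray, np.ndarray], np.ndarray]
    linear: bool = False


def _xor(u1, u2):
    return ((u1 > 0.5) ^ (u2 > 0.5)).astype(int)


def _in_triangle(u1, u2):
    # interior of the triangle (0,0), (1,0), (0.5,1)
    return ((u2 <= 2.0 * u1) & (u2 <= 2.0 * (1.0 - u1))).astype(int)


def _checkers(u1, u2):
    i = np.clip((np.asarray(u1) * 3).astype(int), 0, 2)
    j = np.clip((np.asarray(u2) * 3).astype(int), 0, 2)
    return ((i + j) % 2).astype(int)


def _dots(u1, u2):
    centres = [(0.25, 0.25), (0.75, 0.25), (0.5, 0.75)]
    u1, u2 = np.asarray(u1), np.asarray(u2)
    inside = np.zeros(np.broadcast(u1, u2).shape, dtype=bool)
    for cx, cy in centres:
        inside |= (u1 - cx) ** 2 + (u2 - cy) ** 2 <= 0.15**2
    return inside.astype(int)


TASKS: dict[str, TaskDef] = {
    t.name: t
    for t in [
        TaskDef("and", lambda u1, u2: ((np.asarray(u1) > 0.5) & (np.asarray(u2) > 0.5)).astype(int), linear=True),
        TaskDef("or", lambda u1, u2: ((np.asarray(u1) > 0.5) | (np.asarray(u2) > 0.5)).astype(int), linear=True),
        TaskDef("linear", lambda u1, u2: (np.asarray(u2) > np.asarray(u1)).astype(int), linear=True),
        TaskDef("xor", _xor),
        TaskDef("triangle", _in_triangle),
        TaskDef("checkers", _checkers),
        TaskDef("circle", lambda u1, u2: ((np.asarray(u1) - 0.5) ** 2 + (np.asarray(u2) - 0.5) ** 2 <= 0.3**2).astype(int)),
        TaskDef("sine", lambda u1, u2: (np.asarray(u2) > 0.5 + 0.25 * np.sin(2 * np.pi * np.asarray(u1))).astype(int)),
        TaskDef("rings", lambda u1, u2: ((0.15**2 <= (np.asarray(u1) - 0.5) ** 2 + (np.asarray(u2) - 0.5) ** 2) & ((np.asarray(u1) - 0.5) ** 2 + (np.asarray(u2) - 0.5) ** 2 <= 0.35**2)).astype(int)),
        TaskDef("dots", _dots),
    ]
}


def task_label(task: TaskDef | str, point) -> np.ndarray:
    """Evaluate a task's indicator at normalised points in [0, 1]^2."""
    if isinstance(task, str):
        task = TASKS[task]
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if pts.shape[1] != 2:
        raise ClassificationError("points must be pairs (u1, u2)")
    if np.any(pts < -1e-9) or np.any(pts > 1 + 1e-9):
        raise ClassificationError("point outside the unit square")
    labels = task.indicator(pts[:, 0], pts[:, 1])
    return labels if np.asarray(point).ndim > 1 else int(np.asarray(labels).ravel()[0])


# ---------------------------------------------------------------------------
# Phi score

@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ClassificationError("contingency counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ContingencyCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def phi_score(counts: ContingencyCounts) -> float:
    """Matthews correlation: (TP*TN - FP*FN) / sqrt of the marginal product.

    +1 for perfect predictions, -1 for completely wrong ones.  Any zero
    factor in the denominator (a degenerate margin) yields 0, the standard
    convention for an uninformative split.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def phi_accuracy(phi: float) -> float:
    """Map Phi from [-1, 1] onto the unit interval: (Phi + 1) / 2."""
    if not -1.0 - 1e-12 <= phi <= 1.0 + 1e-12:
        raise ClassificationError(f"Phi must lie in [-1, 1], got {phi}")
    return (float(phi) + 1.0) / 2.0


# ---------------------------------------------------------------------------
# standardisation and the linear readout

@dataclass(frozen=True)
class Standardization:
    mean: np.ndarray
    scale: np.ndarray

    def apply(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def standardize(X) -> tuple[np.ndarray, Standardization]:
    """Centre each column and scale to unit (population) variance.

    Zero-variance columns keep scale 1 (they become all-zero after
    centring) and trigger a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ClassificationError("need a 2-D matrix with at least two rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    degenerate = scale <= 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature column(s); scale set to 1",
            stacklevel=2,
        )
        scale = np.where(degenerate, 1.0, scale)
    params = Standardization(mean=mean, scale=scale)
    return params.apply(X), params


@dataclass
class ClassifierReadout:
    """Trained linear readout: weights over channels plus standardisation."""

    weights: np.ndarray
    intercept: float
    standardization: Standardization
    regularization: float = 1.0

    def decision_function(self, X) -> np.ndarray:
        Z = self.standardization.apply(X)
        return Z @ self.weights + self.intercept

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_linear_svc(
    features, labels, regularization: float = 1.0
) -> ClassifierReadout:
    """Train the linear support-vector readout on raw features.

    Features are standardised (parameters estimated from the training data
    only) before the regularized hinge-loss fit; the returned readout
    re-applies the stored standardisation to new inputs.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ClassificationError("training labels contain a single class")
    Z, params = standardize(features)
    clf = LinearSVC(C=regularization, dual=False, max_iter=20000, random_state=0)
    clf.fit(Z, y)
    return ClassifierReadout(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        standardization=params,
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    """Bookkeeping of the stratified leave-five-out evaluation."""

    records: pd.DataFrame            # columns: repeat, split, phi, phi_accuracy
    per_input_accuracy: np.ndarray   # fraction correct when held out, per input
    mean_phi: float
    mean_phi_accuracy: float
    n_evaluations: int


def _stratified_order(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random order interleaving the classes proportionally, so consecutive
    blocks of five are close to the global class ratio (best-effort
    stratification)."""
    order_keys = np.empty(y.size)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        # evenly spaced fractional positions with a random phase
        order_keys[perm] = (np.arange(idx.size) + rng.random()) / idx.size
    return np.argsort(order_keys, kind="stable")


def cross_validate(
    features,
    labels,
    repeats: int = 20,
    splits: int = 26,
    test_size: int = 5,
    seed: int = 0,
    trainer: Callable | None = None,
    regularization: float = 1.0,
) -> CVResult:
    """Stratified leave-``test_size``-out cross-validation.

    Per repeat the inputs are shuffled (class-interleaved) and partitioned
    into ``splits`` disjoint test sets of ``test_size``; inputs beyond
    ``splits * test_size`` are train-only for that repeat.  For each split
    a classifier is trained on the complement and the Phi score computed
    on the held-out five.  Defaults give the 20 x 26 = 520 evaluations of
    the published protocol.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    n = X.shape[0]
    if n < splits * test_size:
        raise ClassificationError(
            f"{n} inputs cannot supply {splits} disjoint test sets of {test_size}"
        )
    if len(np.unique(y)) < 2:
        raise ClassificationError("labels contain a single class")
    if trainer is None:
        trainer = lambda Xt, yt: train_linear_svc(Xt, yt, regularization)
    rng = np.random.default_rng(seed)
    rows = []
    held_out = np.zeros(n)
    correct = np.zeros(n)
    for repeat in range(repeats):
        for _attempt in range(5):
            order = _stratified_order(y, rng)
            ok = all(
                len(np.unique(y[np.delete(order, np.s_[s * test_size:(s + 1) * test_size])])) == 2
                for s in range(splits)
            )
            if ok:
                break
        else:
            raise ClassificationError(
                f"repeat {repeat}: could not build splits with two-class training folds"
            )
        for split in range(splits):
            test_idx = order[split * test_size:(split + 1) * test_size]
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            model = trainer(X[train_mask], y[train_mask])
            y_pred = model.predict(X[test_idx])
            counts = ContingencyCounts.from_predictions(y[test_idx], y_pred)
            phi = phi_score(counts)
            rows.append(
                {
                    "repeat": repeat,
                    "split": split,
                    "phi": phi,
                    "phi_accuracy": phi_accuracy(phi),
                    "test_indices": tuple(int(i) for i in test_idx),
                }
            )
            held_out[test_idx] += 1
            correct[test_idx] += (y_pred == y[test_idx]).astype(float)
    records = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        per_input = np.where(held_out > 0, correct / np.maximum(held_out, 1), np.nan)
    return CVResult(
        records=records,
        per_input_accuracy=per_input,
        mean_phi=float(records["phi"].mean()),
        mean_phi_accuracy=float(records["phi_accuracy"].mean()),
        n_evaluations=len(records),
    )


# ---------------------------------------------------------------------------
# baseline classifiers on the raw 2-D inputs

class ELMClassifier:
    """Extreme learning machine: fixed random tanh features + linear SVC.

    The feature map concatenates the raw inputs with ``n_hidden`` random
    tanh projections, so with ``n_hidden = 0`` the model reduces exactly
    to the linear SVC on the raw inputs.
    """

    def __init__(self, n_hidden: int = 100, regularization: float = 1.0, seed: int = 0):
        self.n_hidden = n_hidden
        self.regularization = regularization
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.seed)
        if self.n_hidden > 0:
            self._A = rng.normal(0, 2.0, size=(X.shape[1], self.n_hidden))
            self._b = rng.uniform(-1, 1, size=self.n_hidden)
        else:
            self._A = np.zeros((X.shape[1], 0))
            self._b = np.zeros(0)
        self._readout = train_linear_svc(self._map(X), y, self.regularization)
        return self

    def _map(self, X):
        X = np.asarray(X, dtype=float)
        return np.hstack([X, np.tanh(X @ self._A + self._b)])

    def predict(self, X):
        return self._readout.predict(self._map(X))


def _sk_trainer(factory):
    def trainer(Xt, yt):
        Z, params = standardize(Xt)
        model = factory()
        model.fit(Z, yt)

        class _Wrapped:
            def predict(self, X):
                return np.asarray(model.predict(params.apply(X))).astype(int)

        return _Wrapped()

    return trainer


def baseline_suite(
    points,
    labels,
    repeats: int = 20,
    splits: int = 26,
    test_size: int = 5,
    seed: int = 0,
    algorithms: Sequence[str] = ("lsvc", "svc_rbf", "mlp", "gp", "elm"),
) -> dict[str, CVResult]:
    """Run the CV protocol on the raw 2-D inputs with reference classifiers.

    These baselines quantify what the training layer achieves *without*
    the reservoir: a linear SVC, an RBF-kernel SVC, a small multilayer
    perceptron, a Gaussian-process classifier, and the in-package extreme
    learning machine.
    """
    factories: Mapping[str, Callable] = {
        "lsvc": lambda: None,  # handled by the default trainer
        "svc_rbf": lambda: SVC(kernel="rbf", C=1.0, random_state=0),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(50,), max_iter=2000, random_state=0
        ),
        "gp": lambda: GaussianProcessClassifier(random_state=0),
        "elm": lambda: None,
    }
    results: dict[str, CVResult] = {}
    for name in algorithms:
        if name not in factories:
            raise ClassificationError(f"unknown baseline {name!r}")
        if name == "lsvc":
            trainer = None
        elif name == "elm":
            trainer = lambda Xt, yt: ELMClassifier(seed=seed).fit(Xt, yt)
        else:
            trainer = _sk_trainer(factories[name])
        results[name] = cross_validate(
            points, labels, repeats=repeats, splits=splits,
            test_size=test_size, seed=seed, trainer=trainer,
        )
    return results
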