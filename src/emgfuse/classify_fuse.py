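"""Classifier bank (ELM, SVM, softmax) with per-class local fusion.

Three classifier families compete: an extreme learning machine (random fixed
hidden layer, ridge least-squares output weights) with five candidate
activations, a soft-margin SVM with six named kernels (linear, quadratic,
cubic and fine/medium/coarse Gaussian), and a multinomial-logistic softmax
layer.  Within ELM and SVM the best variant is picked by validation accuracy;
then each class is assigned to whichever family scores it best (per-class
recall on the validation split), ties broken by the fixed priority
ELM > SVM > SL.  Fused prediction gates per-class scores through the class's
assigned family and takes the argmax; every family exposes scores that
row-normalize to 1 so cross-family scores are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import softmax as _softmax
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "ELM_ACTIVATIONS",
    "SVM_KERNELS",
    "ElmModel",
    "SvmSpec",
    "SvmClassifier",
    "SoftmaxClassifier",
    "FusionTable",
    "train_elm",
    "train_svm",
    "train_softmax",
    "select_best_variant",
    "per_class_accuracy",
    "select_local_classifiers",
    "fuse_predict",
]

#: the five ELM activations, in declared (tie-break) order
ELM_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sine": np.sin,
    "tribas": lambda a: np.maximum(0.0, 1.0 - np.abs(a)),
    "radbas": lambda a: np.exp(-(a**2)),
    "logistic": lambda a: 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500))),
    "hardlim": lambda a: (a >= 0.0).astype(float),
}

SVM_KERNELS = ("linear", "quadratic", "cubic", "fine-gaussian", "medium-gaussian", "coarse-gaussian")

#: family priority for all tie-breaks
FAMILY_PRIORITY = ("ELM", "SVM", "SL")


def _onehot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


# --------------------------------------------------------------------------
# extreme learning machine
# --------------------------------------------------------------------------

@dataclass
class ElmModel:
    """Random-hidden-layer network; only the output weights are learned."""

    W: np.ndarray  # (H, d) fixed random input weights
    b: np.ndarray  # (H,) fixed random biases
    activation: str
    B: np.ndarray  # (H, n_classes) least-squares output weights
    classes: np.ndarray

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return ELM_ACTIVATIONS[self.activation](np.asarray(X, float) @ self.W.T + self.b)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self._hidden(X) @ self.B

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Softmax-normalized class scores (rows sum to 1)."""
        return _softmax(self.decision_scores(X), axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_elm(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int,
    activation: str = "sine",
    ridge: float = 1e-8,
    seed: int = 0,
) -> ElmModel:
    """Fit an ELM: W, b ~ Uniform(-1, 1); B solves the (ridge) least-squares
    system G B = onehot(y); with ridge = 0 the pseudoinverse is used."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if hidden < 1:
        raise ValueError("hidden unit count must be >= 1")
    if activation not in ELM_ACTIVATIONS:
        raise ValueError(f"activation must be one of {tuple(ELM_ACTIVATIONS)}")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=hidden)
    G = ELM_ACTIVATIONS[activation](X @ W.T + b)
    T = _onehot(y, classes)
    if ridge > 0:
        B = np.linalg.solve(G.T @ G + ridge * np.eye(hidden), G.T @ T)
    else:
        B = np.linalg.pinv(G) @ T
    return ElmModel(W=W, b=b, activation=activation, B=B, classes=classes)


# --------------------------------------------------------------------------
# support vector machine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SvmSpec:
    """One of the six named kernels with its conventional kernel scale.

    The Gaussian kernel scales follow the fine/medium/coarse convention
    s = sqrt(d)/4, sqrt(d), 4*sqrt(d) (d = feature count), i.e.
    gamma = 1/s^2.  Quadratic and cubic are polynomial kernels of degree
    2 and 3 with unit coef0.
    """

    kernel: str = "linear"
    box_constraint: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in SVM_KERNELS:
            raise ValueError(f"kernel must be one of {SVM_KERNELS}")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")

    def make_estimator(self, n_features: int) -> SVC:
        d = float(n_features)
        common = dict(C=self.box_constraint, decision_function_shape="ovr")
        if self.kernel == "linear":
            return SVC(kernel="linear", **common)
        if self.kernel == "quadratic":
            return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", **common)
        if self.kernel == "cubic":
            return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", **common)
        scale = {"fine-gaussian": np.sqrt(d) / 4.0, "medium-gaussian": np.sqrt(d), "coarse-gaussian": 4.0 * np.sqrt(d)}[self.kernel]
        return SVC(kernel="rbf", gamma=1.0 / scale**2, **common)


@dataclass
class SvmClassifier:
    spec: SvmSpec
    estimator: SVC
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, float))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        df = self.estimator.decision_function(np.asarray(X, float))
        if df.ndim == 1:  # binary: decision for classes_[1]
            df = np.column_stack([-df, df])
        return _softmax(df, axis=1)


def train_svm(X: np.ndarray, y: np.ndarray, spec: SvmSpec = SvmSpec()) -> SvmClassifier:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    est = spec.make_estimator(X.shape[1])
    est.fit(X, y)
    return SvmClassifier(spec=spec, estimator=est, classes=est.classes_)


# --------------------------------------------------------------------------
# softmax layer ("SL")
# --------------------------------------------------------------------------

@dataclass
class SoftmaxClassifier:
    estimator: LogisticRegression
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, float))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, float))


def train_softmax(X: np.ndarray, y: np.ndarray, l2: float = 1e-4, seed: int = 0) -> SoftmaxClassifier:
    """Multinomial logistic head; probabilities sum to 1 per row."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in softmax input")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    est = LogisticRegression(C=1.0 / max(l2, 1e-12), max_iter=2000, random_state=seed)
    est.fit(X, y)
    return SoftmaxClassifier(estimator=est, classes=est.classes_)


# --------------------------------------------------------------------------
# selection and fusion
# --------------------------------------------------------------------------

def select_best_variant(candidates: Sequence[tuple[str, object]], X_val: np.ndarray, y_val: np.ndarray) -> tuple[str, object, float]:
    """Pick the (variant_id, model) with the highest validation accuracy;
    ties go to the first in declared order."""
    if not candidates:
        raise ValueError("no candidate variants")
    best = None
    for vid, model in candidates:
        acc = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
        if best is None or acc > best[2]:
            best = (vid, model, acc)
    return best


def per_class_accuracy(y_pred: np.ndarray, y_true: np.ndarray, classes: Sequence | None = None) -> dict:
    """Recall of each class: correct among truth==c over count of truth==c.

    Classes absent from the truth are excluded (with a warning when
    explicitly requested via ``classes``).
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    out: dict = {}
    wanted = np.unique(y_true) if classes is None else np.asarray(classes)
    for c in wanted:
        mask = y_true == c
        if not mask.any():
            logging.getLogger(__name__).warning("class %r absent from truth; excluded", c)
            continue
        out[c.item() if hasattr(c, "item") else c] = float(np.mean(y_pred[mask] == c))
    return out


@dataclass
class FusionTable:
    """class -> (family, variant) assignment plus the selection accuracies."""

    assignment: dict  # class -> (family_id, variant_id)
    selection_accuracies: dict  # family_id -> {class: accuracy}

    def __post_init__(self) -> None:
        for c, (fam, _) in self.assignment.items():
            accs = {f: t.get(c, float("-inf")) for f, t in self.selection_accuracies.items()}
            if accs and accs[fam] < max(accs.values()):
                raise ValueError(f"class {c!r} not assigned to its best family")

    def owner(self, c) -> str:
        return self.assignment[c][0]


def select_local_classifiers(
    accuracy_tables: dict[str, dict],
    variant_ids: dict[str, str] | None = None,
) -> FusionTable:
    """Assign each class to the family with the highest per-class accuracy.

    ``accuracy_tables`` maps family id to {class: accuracy}; all tables must
    cover the same class set.  Ties break by the fixed priority ELM > SVM > SL
    (then declaration order for unknown families).
    """
    if not accuracy_tables:
        raise ValueError("no accuracy tables")
    families = list(accuracy_tables)
    class_sets = [frozenset(t) for t in accuracy_tables.values()]
    if len(set(class_sets)) != 1:
        raise ValueError(f"accuracy tables cover different class sets: {class_sets}")

    def rank(f: str) -> int:
        return FAMILY_PRIORITY.index(f) if f in FAMILY_PRIORITY else len(FAMILY_PRIORITY) + families.index(f)

    ordered = sorted(families, key=rank)
    variant_ids = variant_ids or {}
    assignment = {}
    for c in sorted(class_sets[0], key=lambda v: (str(type(v)), v)):
        best = max(ordered, key=lambda f: accuracy_tables[f][c])  # max keeps first tie
        assignment[c] = (best, variant_ids.get(best, best))
    return FusionTable(assignment=assignment, selection_accuracies=accuracy_tables)


def fuse_predict(fusion: FusionTable, score_tables: dict[str, np.ndarray], classes: Sequence) -> np.ndarray:
    """Per-class score gating: the fused score of class c is the score the
    class's assigned family gives it; predict the argmax (lowest class index
    on ties).  Every score table must be (n_samples, n_classes), columns in
    ``classes`` order, rows summing to 1."""
    classes = np.asarray(classes)
    n = None
    for fam, S in score_tables.items():
        S = np.asarray(S)
        if S.ndim != 2 or S.shape[1] != classes.size:
            raise ValueError(f"score table for {fam} has shape {S.shape}, expected (n, {classes.size})")
        n = S.shape[0] if n is None else n
        if S.shape[0] != n:
            raise ValueError("score tables disagree on sample count")
    fused = np.empty((n, classes.size))
    for j, c in enumerate(classes):
        key = c.item() if hasattr(c, "item") else c
        fam = fusion.owner(key)
        if fam not in score_tables:
            raise ValueError(f"missing score table for family {fam!r}")
        fused[:, j] = np.asarray(score_tables[fam])[:, j]
    return classes[np.argmax(fused, axis=1)]
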