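"""Class-conditional Gaussian virtual-sample generation.

Small-sample biosignal classifiers are starved for training data; virtual
sample generation (VSG) enlarges the training set from a fitted statistical
model of it.  Here each class c and feature j gets an independent Gaussian
N(mu[c,j], eta[c,j]^2) with mu/eta the within-class sample mean and sample
standard deviation (denominator N-1); virtual rows are drawn per feature from
those Gaussians.  Discrete (integer-coded) features are not perturbed: they
receive eta = 0 and the within-class mode, the degenerate draw from
N(mode, 0).

The replication factor R (1000 in the full profile) generates R virtual rows
per original training row, all from the row's class-conditional model; the
originals are kept alongside by default.  Augmentation must only ever see
training folds — the pipeline enforces this and the tests assert it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FeatureTable

__all__ = [
    "ClassGaussianModel",
    "AugmentationSpec",
    "fit_class_gaussian",
    "generate_virtual_samples",
    "augment_training_set",
    "infer_discrete_columns",
]


@dataclass
class AugmentationSpec:
    """R virtual rows per original row; originals kept when ``include_originals``."""

    replication_factor: int = 1000
    include_originals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replication_factor < 0:
            raise ValueError("replication_factor must be >= 0")


@dataclass
class ClassGaussianModel:
    """Per-class, per-feature (mu, eta) with the continuous/discrete split.

    ``eta`` is zero exactly on the discrete columns; ``mu`` holds the class
    mean for continuous columns and the class mode for discrete ones.
    """

    classes: np.ndarray
    mu: np.ndarray  # (n_classes, k)
    eta: np.ndarray  # (n_classes, k)
    is_discrete: np.ndarray  # (k,)
    feature_names: list[str]

    def __post_init__(self) -> None:
        if np.any(self.eta < 0):
            raise ValueError("eta must be nonnegative")
        if np.any(self.eta[:, self.is_discrete] != 0):
            raise ValueError("discrete features must have eta = 0")

    @property
    def feature_count(self) -> int:
        return self.mu.shape[1]

    @property
    def continuous_count(self) -> int:
        return int((~self.is_discrete).sum())

    def class_index(self, class_label) -> int:
        idx = np.nonzero(self.classes == class_label)[0]
        if idx.size == 0:
            raise KeyError(f"class {class_label!r} not in fitted model (have {list(self.classes)})")
        return int(idx[0])


def infer_discrete_columns(X: np.ndarray, max_levels: int = 10) -> np.ndarray:
    """Default heuristic: a column is discrete if every value is integral and
    it takes at most ``max_levels`` distinct values."""
    X = np.asarray(X, dtype=float)
    flags = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(np.isfinite(col)) and np.all(col == np.round(col)):
            flags[j] = np.unique(col).size <= max_levels
    return flags


def _class_mode(values: np.ndarray) -> float:
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])


def fit_class_gaussian(train: FeatureTable) -> ClassGaussianModel:
    """Fit mu (mean) and eta (sample sd, N-1 denominator) per class and feature.

    Continuous features need >= 2 rows per class for eta to exist; discrete
    features get eta = 0 and mu = the within-class mode.
    """
    classes = train.classes
    k = train.n_features
    mu = np.zeros((classes.size, k))
    eta = np.zeros((classes.size, k))
    cont = ~train.discrete
    for ci, c in enumerate(classes):
        rows = train.X[train.y == c]
        if rows.shape[0] < 2 and cont.any():
            raise ValueError(
                f"class {c!r} has {rows.shape[0]} row(s); the sample standard deviation "
                "needs >= 2 — add rows or mark the features discrete"
            )
        mu[ci, cont] = rows[:, cont].mean(axis=0)
        eta[ci, cont] = rows[:, cont].std(axis=0, ddof=1)
        for j in np.nonzero(train.discrete)[0]:
            mu[ci, j] = _class_mode(rows[:, j])
    return ClassGaussianModel(
        classes=classes,
        mu=mu,
        eta=eta,
        is_discrete=train.discrete.copy(),
        feature_names=list(train.feature_names),
    )


def generate_virtual_samples(
    model: ClassGaussianModel,
    class_label,
    m: int,
    seed: int = 0,
) -> FeatureTable:
    """Draw m virtual rows for one class from its per-feature Gaussians.

    Continuous feature j ~ N(mu[c,j], eta[c,j]^2) independently; discrete
    feature j is exactly mu[c,j] (the eta^2 = 0 degenerate draw).
    Deterministic given ``seed``.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    ci = model.class_index(class_label)
    rng = np.random.default_rng(seed)
    X = np.tile(model.mu[ci], (m, 1))
    cont = ~model.is_discrete
    if m > 0 and cont.any():
        X[:, cont] += model.eta[ci, cont] * rng.standard_normal((m, int(cont.sum())))
    return FeatureTable(
        X=X,
        y=np.full(m, class_label, dtype=model.classes.dtype),
        feature_names=list(model.feature_names),
        discrete=model.is_discrete.copy(),
        subject_id=np.full(m, -1, dtype=int),
        trial_id=np.full(m, -1, dtype=int),
    )


def augment_training_set(train: FeatureTable, spec: AugmentationSpec) -> FeatureTable:
    """Merge the training rows with R virtual rows per original row.

    Each class c with N_c original rows contributes R*N_c virtual rows drawn
    from that class's Gaussian, so balanced input stays balanced and the
    output holds N*(1+R) rows when originals are kept.
    """
    if spec.replication_factor == 0 and spec.include_originals:
        return train
    model = fit_class_gaussian(train)
    pieces = [train] if spec.include_originals else []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(model.classes.size)
    for ci, c in enumerate(model.classes):
        n_c = int((train.y == c).sum())
        m = spec.replication_factor * n_c
        pieces.append(generate_virtual_samples(model, c, m, seed=int(child_seeds[ci])))
    if not pieces:
        return generate_virtual_samples(model, model.classes[0], 0)
    return FeatureTable.concat(pieces)
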