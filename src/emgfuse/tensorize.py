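"""Multiway (tensor) views of feature vectors and coordinate transforms.

The spectrogram of one trial is naturally a (channel, frequency, time)
multiway array; this module provides the lossless reshape between flat feature
rows and that tensor view, mode-n unfolding/folding with a fixed row-major
(last-axis-fastest) element order so serialized tensors are portable, and a
small coordinate-transformation algebra: a transform carries its forward map
and Jacobian, composition obeys the chain rule J(T2∘T1)(x) = J2(T1(x))·J1(x),
and for affine maps Jacobian determinants multiply exactly.

The default pipeline transform is the identity — tensorization is then purely
an axis-structured view of the spectrogram — with ``CoordinateTransform`` as
the extension point for any domain-specific change of coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FeatureTensor",
    "CoordinateTransform",
    "tensorize_features",
    "unfold_mode",
    "fold_mode",
    "compose_transforms",
]


@dataclass
class FeatureTensor:
    """An N-way real array with named, unique axes."""

    data: np.ndarray
    axis_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis_names = tuple(self.axis_names)
        if len(self.axis_names) != self.data.ndim:
            raise ValueError(
                f"{len(self.axis_names)} axis names for a {self.data.ndim}-way array"
            )
        if len(set(self.axis_names)) != len(self.axis_names):
            raise ValueError("axis names must be unique")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def axis_index(self, axis: str) -> int:
        try:
            return self.axis_names.index(axis)
        except ValueError:
            raise KeyError(f"unknown axis {axis!r}; have {self.axis_names}") from None

    def flatten(self) -> np.ndarray:
        """Row-major flattening (last axis fastest); inverse of tensorize."""
        return self.data.reshape(-1)


def tensorize_features(row: np.ndarray, axis_spec: Sequence[tuple[str, int]]) -> FeatureTensor:
    """Reshape a flat feature vector into a named multiway array.

    ``axis_spec`` is an ordered list of (axis_name, size); the product of the
    sizes must equal the vector length, and ``FeatureTensor.flatten`` is the
    exact inverse.
    """
    row = np.asarray(row, dtype=float).reshape(-1)
    names = tuple(n for n, _ in axis_spec)
    sizes = tuple(int(s) for _, s in axis_spec)
    expected = int(np.prod(sizes)) if sizes else 1
    if row.size != expected:
        raise ValueError(
            f"vector length {row.size} does not match axis sizes {sizes} (product {expected})"
        )
    return FeatureTensor(row.reshape(sizes), axis_names=names)


def unfold_mode(t: FeatureTensor, axis: str) -> np.ndarray:
    """Mode-n unfolding: the named axis becomes the rows, the remaining axes
    are flattened row-major (last-axis-fastest) into the columns."""
    k = t.axis_index(axis)
    moved = np.moveaxis(t.data, k, 0)
    return moved.reshape(t.shape[k], -1)


def fold_mode(matrix: np.ndarray, axis: str, axis_names: Sequence[str], shape: Sequence[int]) -> FeatureTensor:
    """Inverse of :func:`unfold_mode` given the original axis order and shape."""
    axis_names = tuple(axis_names)
    shape = tuple(int(s) for s in shape)
    if axis not in axis_names:
        raise KeyError(f"unknown axis {axis!r}; have {axis_names}")
    k = axis_names.index(axis)
    rest = shape[:k] + shape[k + 1 :]
    moved = np.asarray(matrix, dtype=float).reshape((shape[k],) + rest)
    return FeatureTensor(np.moveaxis(moved, 0, k), axis_names=axis_names)


@dataclass
class CoordinateTransform:
    """A map R^n -> R^n together with its Jacobian matrix function.

    For affine transforms x -> A x + b the Jacobian is the constant matrix A.
    """

    forward: Callable[[np.ndarray], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    dim: int

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.dim:
            raise ValueError(f"transform expects dimension {self.dim}, got {x.shape[-1]}")
        return self.forward(x)

    @classmethod
    def identity(cls, dim: int) -> "CoordinateTransform":
        eye = np.eye(dim)
        return cls(forward=lambda x: np.asarray(x, dtype=float), jacobian=lambda x: eye, dim=dim)

    @classmethod
    def affine(cls, A: np.ndarray, b: np.ndarray | None = None) -> "CoordinateTransform":
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("affine transform needs a square matrix")
        b = np.zeros(A.shape[0]) if b is None else np.asarray(b, dtype=float)
        return cls(forward=lambda x: x @ A.T + b, jacobian=lambda x: A, dim=A.shape[0])


def compose_transforms(t1: CoordinateTransform, t2: CoordinateTransform) -> CoordinateTransform:
    """The composite T2∘T1 with chain-rule Jacobian J2(T1(x))·J1(x)."""
    if t1.dim != t2.dim:
        raise ValueError(f"dimension mismatch: {t1.dim} vs {t2.dim}")

    def forward(x: np.ndarray) -> np.ndarray:
        return t2.forward(t1.forward(x))

    def jacobian(x: np.ndarray) -> np.ndarray:
        return t2.jacobian(t1.forward(x)) @ t1.jacobian(x)

    return CoordinateTransform(forward=forward, jacobian=jacobian, dim=t1.dim)
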