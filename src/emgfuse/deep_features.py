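"""Stacked sparse autoencoders for unsupervised feature learning.

Each layer is a single-hidden-layer autoencoder with a linear decoder trained
to minimise

    L = 1/(2N) * sum ||x_hat - x||^2            (reconstruction)
      + lambda/2 * (||W_enc||^2 + ||W_dec||^2)  (weight decay)
      + beta * sum_j KL(rho || rho_hat_j)       (sparsity)

where KL(rho || r) = rho*ln(rho/r) + (1-rho)*ln((1-rho)/(1-r)) and rho_hat_j
is the mean activation fraction of hidden unit j.  With a purely linear
encoder the raw activations are unbounded, so rho_hat is computed on
logistic-squashed activations, keeping the KL term defined for every
transfer function.

The stack is trained greedily: layer 2 fits the codes of layer 1.  The full
profile uses hidden sizes [1200, 900] with lambda = 0.001, beta = 4 and
rho = 0.05 and a purely linear encoder transfer; tests shrink the hidden
sizes for speed.  The default optimizer is L-BFGS on the exact gradient
(deterministic given the init seed); plain full-batch gradient descent with a
fixed learning rate is available for step-by-step inspection, and its loss
trace is non-increasing for a small enough step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "AutoencoderSpec",
    "EncoderLayer",
    "EncoderStack",
    "kl_sparsity_penalty",
    "train_sparse_autoencoder",
    "train_encoder_stack",
    "encode_stack",
]

log = logging.getLogger(__name__)

_TRANSFERS = ("linear", "logistic", "satlin")
_RHO_CLIP = 1e-6


@dataclass
class AutoencoderSpec:
    """Hyperparameters of the stack; one layer reuses the same fields."""

    hidden_sizes: tuple[int, ...] = (1200, 900)
    l2_weight: float = 0.001
    sparsity_weight: float = 4.0
    sparsity_proportion: float = 0.05
    encoder_transfer: str = "linear"
    max_epochs: int = 200
    learning_rate: float = 0.01
    optimizer: str = "lbfgs"  # or "gd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity_proportion < 1.0):
            raise ValueError("sparsity_proportion must lie in (0, 1)")
        if self.l2_weight < 0 or self.sparsity_weight < 0:
            raise ValueError("l2_weight and sparsity_weight must be >= 0")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.encoder_transfer not in _TRANSFERS:
            raise ValueError(f"encoder_transfer must be one of {_TRANSFERS}")
        if self.optimizer not in ("lbfgs", "gd"):
            raise ValueError("optimizer must be 'lbfgs' or 'gd'")


@dataclass
class EncoderLayer:
    W: np.ndarray  # (hidden, in)
    b: np.ndarray  # (hidden,)
    transfer: str
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    reconstruction_mse: float = float("nan")  # per-element MSE at the final params

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W.shape[1]:
            raise ValueError(f"layer expects {self.W.shape[1]} inputs, got {X.shape[1]}")
        return _apply_transfer(X @ self.W.T + self.b, self.transfer)


@dataclass
class EncoderStack:
    layers: list[EncoderLayer]

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.W.shape[1] != prev.W.shape[0]:
                raise ValueError("layer input dimension must equal previous hidden size")

    @property
    def output_dim(self) -> int:
        return self.layers[-1].W.shape[0]


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def _apply_transfer(a: np.ndarray, transfer: str) -> np.ndarray:
    if transfer == "linear":
        return a
    if transfer == "logistic":
        return _sigmoid(a)
    if transfer == "satlin":  # positive saturating linear: clip to [0, 1]
        return np.clip(a, 0.0, 1.0)
    raise ValueError(f"unknown transfer {transfer!r}")


def _transfer_grad(a: np.ndarray, h: np.ndarray, transfer: str) -> np.ndarray:
    if transfer == "linear":
        return np.ones_like(a)
    if transfer == "logistic":
        return h * (1.0 - h)
    if transfer == "satlin":
        return ((a > 0.0) & (a < 1.0)).astype(float)
    raise ValueError(f"unknown transfer {transfer!r}")


def kl_sparsity_penalty(rho_hat: np.ndarray, rho: float) -> float:
    """Sum over hidden units of KL(rho || rho_hat_j).

    Nonnegative, and zero exactly when every mean activation equals rho.
    Components outside (0, 1) are clamped to [1e-6, 1 - 1e-6] with a warning.
    """
    rho_hat = np.asarray(rho_hat, dtype=float)
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        log.warning("rho_hat outside (0,1); clamping to [%g, %g]", _RHO_CLIP, 1 - _RHO_CLIP)
        rho_hat = np.clip(rho_hat, _RHO_CLIP, 1.0 - _RHO_CLIP)
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat)))
    )


def _loss_and_grad(params, X, d, H, spec: AutoencoderSpec):
    N = X.shape[0]
    W1, b1, W2, b2 = _unpack(params, d, H)
    a = X @ W1.T + b1
    h = _apply_transfer(a, spec.encoder_transfer)
    Xhat = h @ W2.T + b2
    R = Xhat - X

    mse = 0.5 * np.sum(R * R) / N
    reg = 0.5 * spec.l2_weight * (np.sum(W1 * W1) + np.sum(W2 * W2))

    # sparsity on logistic-squashed activations (identity view when the
    # transfer already is logistic)
    if spec.encoder_transfer == "logistic":
        s = h
        ds_da = h * (1.0 - h)
    else:
        s = _sigmoid(h)
        ds_dh = s * (1.0 - s)
        ds_da = ds_dh * _transfer_grad(a, h, spec.encoder_transfer)
    rho_hat = np.clip(s.mean(axis=0), _RHO_CLIP, 1.0 - _RHO_CLIP)
    rho = spec.sparsity_proportion
    kl = np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    loss = mse + reg + spec.sparsity_weight * kl

    dXhat = R / N
    gW2 = dXhat.T @ h + spec.l2_weight * W2
    gb2 = dXhat.sum(axis=0)
    dh = dXhat @ W2
    da = dh * _transfer_grad(a, h, spec.encoder_transfer)
    dkl_drho = -rho / rho_hat + (1 - rho) / (1 - rho_hat)  # (H,)
    da += (spec.sparsity_weight / N) * dkl_drho[None, :] * ds_da
    gW1 = da.T @ X + spec.l2_weight * W1
    gb1 = da.sum(axis=0)
    return loss, _pack(gW1, gb1, gW2, gb2)


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(params: np.ndarray, d: int, H: int):
    i = 0
    W1 = params[i : i + H * d].reshape(H, d); i += H * d
    b1 = params[i : i + H]; i += H
    W2 = params[i : i + d * H].reshape(d, H); i += d * H
    b2 = params[i : i + d]
    return W1, b1, W2, b2


def train_sparse_autoencoder(X: np.ndarray, spec: AutoencoderSpec, hidden: int | None = None) -> EncoderLayer:
    """Train one autoencoder layer and return its encoder half.

    ``hidden`` defaults to the first entry of ``spec.hidden_sizes``.  Inputs
    are assumed already standardized by the pipeline.  Deterministic given
    ``spec.seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty training matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in autoencoder input")
    H = int(hidden if hidden is not None else spec.hidden_sizes[0])
    d = X.shape[1]
    rng = np.random.default_rng(spec.seed)
    limit = np.sqrt(6.0 / (d + H))  # Glorot range
    W1 = rng.uniform(-limit, limit, size=(H, d))
    W2 = rng.uniform(-limit, limit, size=(d, H))
    params = _pack(W1, np.zeros(H), W2, np.zeros(d))

    trace: list[float] = []
    if spec.optimizer == "lbfgs":
        def cb(p):
            trace.append(_loss_and_grad(p, X, d, H, spec)[0])

        res = optimize.minimize(
            _loss_and_grad,
            params,
            args=(X, d, H, spec),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": spec.max_epochs, "ftol": 1e-12, "gtol": 1e-10},
            callback=cb,
        )
        params = res.x
    else:  # plain full-batch gradient descent, fixed step
        for _ in range(spec.max_epochs):
            loss, grad = _loss_and_grad(params, X, d, H, spec)
            trace.append(loss)
            params = params - spec.learning_rate * grad
    W1, b1, W2, b2 = _unpack(params, d, H)
    h = _apply_transfer(X @ W1.T + b1, spec.encoder_transfer)
    final_mse = float(np.mean((h @ W2.T + b2 - X) ** 2))
    return EncoderLayer(
        W=W1.copy(),
        b=b1.copy(),
        transfer=spec.encoder_transfer,
        loss_trace=np.array(trace),
        reconstruction_mse=final_mse,
    )


def train_encoder_stack(X: np.ndarray, spec: AutoencoderSpec) -> EncoderStack:
    """Greedy layer-wise training: each layer fits the previous layer's codes."""
    layers: list[EncoderLayer] = []
    codes = np.asarray(X, dtype=float)
    ss = np.random.SeedSequence(spec.seed)
    layer_seeds = ss.generate_state(len(spec.hidden_sizes))
    for li, h in enumerate(spec.hidden_sizes):
        layer_spec = replace(spec, seed=int(layer_seeds[li]))
        layer = train_sparse_autoencoder(codes, layer_spec, hidden=h)
        layers.append(layer)
        codes = layer.encode(codes)
    return EncoderStack(layers)


def encode_stack(stack: EncoderStack, X: np.ndarray) -> np.ndarray:
    """Apply every layer's transfer(W x + b) in sequence."""
    codes = np.asarray(X, dtype=float)
    for layer in stack.layers:
        codes = layer.encode(codes)
    return codes
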