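"""Chebyshev spectral graph-convolution classifier.

Architecture (one graph-convolution block, as a NumPy implementation with
analytic gradients):

    x (N nodes x F bands)
      -> graph convolution  y = sum_{k=0}^{K-1} T_k(L~) x theta_k   (N x H)
      -> ReLU -> dropout
      -> flatten (N*H) -> fully connected -> softmax over 2 classes

The Chebyshev matrices ``T_k(L~)`` are precomputed once per graph, so a
forward pass involves no eigendecomposition. Training minimizes

    loss = cross_entropy(labels, predictions) + alpha * ||w||

with Adam, stopping when the epoch loss drops to the threshold ``e`` or the
epoch budget ``MAX`` is exhausted. Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .graph import ChannelGraph, chebyshev_matrices

__all__ = ["ModelConfig", "ChebFilterParams", "ChebGCN", "cross_entropy_loss"]

_EPS = 1e-12
RegNorm = Literal["l2", "l2_squared", "l1"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults follow the published operating point: Chebyshev order K = 2,
    dropout 0.2, batch size 128, learning rate 5e-4, epoch budget 1000,
    stop threshold 1e-4.
    """

    K: int = 2
    hidden_width: int = 32
    n_classes: int = 2
    dropout: float = 0.2
    alpha: float = 1e-3
    reg_norm: RegNorm = "l2"
    learning_rate: float = 5e-4
    batch_size: int = 128
    max_epochs: int = 1000
    stop_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.stop_threshold <= 0:
            raise ValueError("learning_rate and stop_threshold must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class ChebFilterParams:
    """Learnable parameters: Chebyshev coefficients and the dense head."""

    theta: np.ndarray       # K x in_features x hidden_width
    conv_bias: np.ndarray   # hidden_width
    fc_weight: np.ndarray   # (n_nodes * hidden_width) x n_classes
    fc_bias: np.ndarray     # n_classes

    def as_list(self) -> list[np.ndarray]:
        return [self.theta, self.conv_bias, self.fc_weight, self.fc_bias]

    def weight_vector(self) -> np.ndarray:
        """All multiplicative weights flattened (biases excluded from the
        regularization penalty)."""
        return np.concatenate([self.theta.ravel(), self.fc_weight.ravel()])

    def copy(self) -> "ChebFilterParams":
        return ChebFilterParams(*[p.copy() for p in self.as_list()])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy_loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    params: ChebFilterParams | None = None,
    alpha: float = 0.0,
    reg_norm: RegNorm = "l2",
) -> float:
    """Mean cross-entropy plus ``alpha`` times a norm of the weights.

    Probabilities are clamped at 1e-12 so a confident wrong prediction
    yields a large finite loss rather than an infinity.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.any((y < 0) | (y >= p.shape[1])):
        raise ValueError("labels out of range for the probability columns")
    ce = -np.mean(np.log(np.clip(p[np.arange(len(y)), y], _EPS, None)))
    if alpha > 0 and params is not None:
        ce += alpha * _penalty(params.weight_vector(), reg_norm)
    return float(ce)


def _penalty(w: np.ndarray, reg_norm: RegNorm) -> float:
    if reg_norm == "l2":
        return float(np.sqrt(np.sum(w**2)))
    if reg_norm == "l2_squared":
        return float(np.sum(w**2))
    if reg_norm == "l1":
        return float(np.sum(np.abs(w)))
    raise ValueError(f"unknown regularization norm {reg_norm!r}")


def _penalty_grad(w: np.ndarray, reg_norm: RegNorm) -> np.ndarray:
    if reg_norm == "l2":
        norm = np.sqrt(np.sum(w**2))
        return w / norm if norm > 0 else np.zeros_like(w)
    if reg_norm == "l2_squared":
        return 2.0 * w
    if reg_norm == "l1":
        return np.sign(w)
    raise ValueError(f"unknown regularization norm {reg_norm!r}")


class ChebGCN:
    """The classifier bound to a fixed channel graph.

    Parameters
    ----------
    graph : ChannelGraph
        Provides the scaled Laplacian; the Chebyshev matrices ``T_k`` are
        precomputed here, once.
    in_features : int
        Features per node (number of frequency bands).
    config : ModelConfig
    """

    def __init__(self, graph: ChannelGraph, in_features: int,
                 config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        self.graph = graph
        self.n_nodes = graph.n_channels
        self.in_features = in_features
        if self.config.K == 1:
            # only T_0 = I is used; no Laplacian rescaling required
            self.cheb = np.eye(self.n_nodes)[None]
        else:
            self.cheb = chebyshev_matrices(graph.scaled_laplacian, self.config.K)
        self.rng = np.random.default_rng(self.config.seed)
        self.params = self._init_params()
        self.history: list[dict[str, float]] = []

    def _init_params(self) -> ChebFilterParams:
        cfg = self.config
        f, h, n = self.in_features, cfg.hidden_width, self.n_nodes
        lim1 = np.sqrt(6.0 / (f + h))
        theta = self.rng.uniform(-lim1, lim1, size=(cfg.K, f, h))
        lim2 = np.sqrt(6.0 / (n * h + cfg.n_classes))
        fc_w = self.rng.uniform(-lim2, lim2, size=(n * h, cfg.n_classes))
        return ChebFilterParams(
            theta=theta,
            conv_bias=np.zeros(h),
            fc_weight=fc_w,
            fc_bias=np.zeros(cfg.n_classes),
        )

    # ---- forward / backward -------------------------------------------

    def _forward(self, X: np.ndarray, *, training: bool = False,
                 params: ChebFilterParams | None = None) -> tuple[np.ndarray, dict]:
        """Probabilities plus the cache needed for the backward pass.

        ``X`` is segments x nodes x in_features.
        """
        p = params or self.params
        cfg = self.config
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.n_nodes or X.shape[2] != self.in_features:
            raise ValueError(
                f"expected batch x {self.n_nodes} x {self.in_features}, "
                f"got {X.shape}"
            )
        # P[k] = T_k(L~) X : (K, B, N, F)
        P = np.einsum("knm,bmf->kbnf", self.cheb, X)
        H = np.einsum("kbnf,kfh->bnh", P, p.theta) + p.conv_bias
        Z = np.maximum(H, 0.0)
        if training and cfg.dropout > 0:
            mask = (
                self.rng.random(Z.shape) >= cfg.dropout
            ).astype(float) / (1.0 - cfg.dropout)
        else:
            mask = None
        Zd = Z * mask if mask is not None else Z
        flat = Zd.reshape(X.shape[0], -1)
        logits = flat @ p.fc_weight + p.fc_bias
        probs = _softmax(logits)
        cache = {"P": P, "H": H, "mask": mask, "flat": flat, "probs": probs}
        return probs, cache

    def _backward(self, cache: dict, labels: np.ndarray,
                  params: ChebFilterParams) -> ChebFilterParams:
        cfg = self.config
        probs, flat, P, H, mask = (
            cache["probs"], cache["flat"], cache["P"], cache["H"], cache["mask"]
        )
        b = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(b), labels] -= 1.0
        dlogits /= b
        d_fc_w = flat.T @ dlogits
        d_fc_b = dlogits.sum(axis=0)
        dflat = dlogits @ params.fc_weight.T
        dZd = dflat.reshape(b, self.n_nodes, cfg.hidden_width)
        dZ = dZd * mask if mask is not None else dZd
        dH = dZ * (H > 0)
        d_theta = np.einsum("kbnf,bnh->kfh", P, dH)
        d_conv_b = dH.sum(axis=(0, 1))
        if cfg.alpha > 0:
            reg = cfg.alpha * _penalty_grad(
                params.weight_vector(), cfg.reg_norm
            )
            n_theta = params.theta.size
            d_theta += reg[:n_theta].reshape(params.theta.shape)
            d_fc_w += reg[n_theta:].reshape(params.fc_weight.shape)
        return ChebFilterParams(d_theta, d_conv_b, d_fc_w, d_fc_b)

    # ---- public API ----------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(X, training=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss(self, X: np.ndarray, labels: np.ndarray) -> float:
        probs = self.predict_proba(X)
        return cross_entropy_loss(
            probs, labels, self.params, self.config.alpha, self.config.reg_norm
        )

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "ChebGCN":
        """Mini-batch Adam until the epoch loss reaches the stop threshold
        or the epoch budget runs out; records per-epoch loss and accuracy in
        ``self.history``."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        n = X.shape[0]
        m = [np.zeros_like(p) for p in self.params.as_list()]
        v = [np.zeros_like(p) for p in self.params.as_list()]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.history = []
        for epoch in range(cfg.max_epochs):
            order = self.rng.permutation(n)
            batch_losses = []
            n_correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = self._forward(X[idx], training=True)
                batch_loss = cross_entropy_loss(
                    probs, y[idx], self.params, cfg.alpha, cfg.reg_norm
                )
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                batch_losses.append(batch_loss)
                n_correct += int((probs.argmax(axis=1) == y[idx]).sum())
                grads = self._backward(cache, y[idx], self.params)
                step += 1
                plist = self.params.as_list()
                for i, (p, g) in enumerate(zip(plist, grads.as_list())):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g**2
                    mhat = m[i] / (1 - beta1**step)
                    vhat = v[i] / (1 - beta2**step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss = float(np.mean(batch_losses))
            # train accuracy aggregated from the (dropout-active) minibatch
            # passes, avoiding a second full sweep per epoch
            self.history.append(
                {"epoch": epoch, "loss": epoch_loss,
                 "train_accuracy": n_correct / n}
            )
            if epoch_loss <= cfg.stop_threshold:
                break
        return self

    # ---- checkpointing --------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: config echo plus all parameter arrays (.npz)."""
        cfg = self.config
        np.savez(
            path,
            theta=self.params.theta,
            conv_bias=self.params.conv_bias,
            fc_weight=self.params.fc_weight,
            fc_bias=self.params.fc_bias,
            adjacency=self.graph.adjacency,
            config_json=np.str_(repr(cfg)),
        )

    def load_params(self, path) -> None:
        with np.load(path, allow_pickle=False) as f:
            self.params = ChebFilterParams(
                theta=f["theta"],
                conv_bias=f["conv_bias"],
                fc_weight=f["fc_weight"],
                fc_bias=f["fc_bias"],
            )
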