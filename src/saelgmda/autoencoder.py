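"""Sparse autoencoder for pair-feature dimensionality reduction.

A symmetric encoder-decoder network maps each (n_d + n_m)-dimensional pair
feature vector to a low-dimensional code (64 by default).  Training minimises

    E = MSE + lambda * Omega_sparsity + beta * Omega_weights

where MSE is the mean squared reconstruction error, Omega_sparsity is the sum
over hidden units of the KL divergence between Bernoulli variables with mean
``rho`` (the sparsity target) and the unit's batch-average activation, and
Omega_weights is half the sum of squared weights over all layers.  Hidden
layers use the rectifier; the output layer uses tanh.  Optimisation is Adam
on mini-batches, implemented in NumPy with explicit backpropagation so every
gradient is checkable against finite differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SAEConfig", "SparseAutoencoderModel", "sae_cost", "sae_cost_grad",
           "sae_fit", "sae_encode", "kl_bernoulli"]

_EPS = 1e-7  # clamp for batch-average activations; KL undefined at 0/1


@dataclass(frozen=True)
class SAEConfig:
    """Hyperparameters of the sparse autoencoder.

    ``layer_sizes`` lists the encoder sizes from input to bottleneck; the
    decoder mirrors them.  ``sparsity_weight`` (lambda), ``l2_weight`` (beta)
    and ``sparsity_target`` (rho) follow the usual sparse-autoencoder roles.
    The KL penalty applies to the bottleneck layer's units by default — the
    classic single-representation sparse-autoencoder penalty; set
    ``sparsity_all_hidden`` to spread it over every hidden layer.
    """

    layer_sizes: tuple[int, ...] = (331, 256, 128, 96, 64)
    sparsity_weight: float = 0.1
    l2_weight: float = 0.0005
    sparsity_target: float = 0.05
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    sparsity_all_hidden: bool = False
    rescale_inputs: bool = False

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least an input and a bottleneck layer")
        if any(int(s) < 1 for s in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        if self.sparsity_weight < 0 or self.l2_weight < 0:
            raise ValueError("sparsity_weight and l2_weight must be >= 0")
        if not (0 < self.sparsity_target < 1):
            raise ValueError("sparsity_target must lie in (0, 1)")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))

    def with_input_dim(self, d: int) -> "SAEConfig":
        return replace(self, layer_sizes=(int(d),) + self.layer_sizes[1:])


@dataclass
class SparseAutoencoderModel:
    """Weights, biases and activations of the full encoder-decoder stack.

    ``weights[l]`` has shape (in_dim, out_dim); ``activations[l]`` is
    ``'relu'`` or ``'tanh'``.  The first ``n_encoder_layers`` layers form the
    encoder; the remainder mirror it back to the input dimension.
    """

    weights: list
    biases: list
    activations: list
    n_encoder_layers: int
    loss_history: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def bottleneck_dim(self) -> int:
        return self.weights[self.n_encoder_layers - 1].shape[1]

    @property
    def hidden_layer_indices(self) -> list:
        """All layers except the final (output) one."""
        return list(range(len(self.weights) - 1))


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_prime(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "tanh":
        return 1.0 - a**2
    raise ValueError(f"unknown activation {kind!r}")


def init_model(cfg: SAEConfig, rng: np.random.Generator | None = None) -> SparseAutoencoderModel:
    """Glorot-uniform initialisation of the mirrored encoder-decoder stack."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sizes = list(cfg.layer_sizes) + list(cfg.layer_sizes[-2::-1])
    n_enc = len(cfg.layer_sizes) - 1
    weights, biases, acts = [], [], []
    n_layers = len(sizes) - 1
    for l in range(n_layers):
        fan_in, fan_out = sizes[l], sizes[l + 1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
        acts.append("tanh" if l == n_layers - 1 else "relu")
    return SparseAutoencoderModel(weights, biases, acts, n_enc)


def _forward(model: SparseAutoencoderModel, X: np.ndarray):
    pre, post = [], []
    a = X
    for W, b, act in zip(model.weights, model.biases, model.activations):
        z = a @ W + b
        a = _activate(z, act)
        pre.append(z)
        post.append(a)
    return pre, post


def kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    """Elementwise KL divergence KL(rho || rho_hat) for Bernoulli means."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    return rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))


def _penalized_layers(model: SparseAutoencoderModel, cfg: SAEConfig) -> list:
    if cfg.sparsity_all_hidden:
        return model.hidden_layer_indices
    return [model.n_encoder_layers - 1]


def sae_cost(
    model: SparseAutoencoderModel, batch: np.ndarray, cfg: SAEConfig
) -> tuple[float, float, float, float]:
    """Evaluate the cost on a batch; returns (total, mse, sparsity, weights).

    ``total = mse + sparsity_weight * sparsity + l2_weight * weights``.
    Batch-average activations are clamped to [1e-7, 1 - 1e-7] before the KL
    term, which is undefined at 0 and 1.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    _, post = _forward(model, batch)
    # mean over samples of the squared residual norm (sum over features):
    # keeps the reconstruction term on a scale where the conventional
    # sparsity/decay weights (0.1, 5e-4) are meaningful
    mse = float(np.mean(np.sum((batch - post[-1]) ** 2, axis=1)))
    sparsity = 0.0
    for l in _penalized_layers(model, cfg):
        rho_hat = post[l].mean(axis=0)
        clipped = np.clip(rho_hat, _EPS, 1 - _EPS)
        if not np.array_equal(clipped, rho_hat):
            logger.debug("clamped %d batch-average activations in layer %d",
                         int((clipped != rho_hat).sum()), l)
        sparsity += float(kl_bernoulli(cfg.sparsity_target, clipped).sum())
    weights_term = 0.5 * float(sum(np.sum(W**2) for W in model.weights))
    total = mse + cfg.sparsity_weight * sparsity + cfg.l2_weight * weights_term
    return total, mse, sparsity, weights_term


def sae_cost_grad(
    model: SparseAutoencoderModel, batch: np.ndarray, cfg: SAEConfig
) -> tuple[float, list, list]:
    """Cost and analytic gradients (dW list, db list) via backpropagation."""
    batch = np.asarray(batch, dtype=float)
    B, d = batch.shape
    pre, post = _forward(model, batch)
    n_layers = len(model.weights)
    rho = cfg.sparsity_target
    penalized = set(_penalized_layers(model, cfg))

    total, _, _, _ = sae_cost(model, batch, cfg)

    dW = [None] * n_layers
    db = [None] * n_layers
    # output layer: d(mse)/dA_L, mse = sum((X - A)^2) / B
    dA = 2.0 * (post[-1] - batch) / B
    for l in range(n_layers - 1, -1, -1):
        if l in penalized:
            rho_hat = post[l].mean(axis=0)
            inside = (rho_hat > _EPS) & (rho_hat < 1 - _EPS)
            clipped = np.clip(rho_hat, _EPS, 1 - _EPS)
            dkl = (-rho / clipped + (1 - rho) / (1 - clipped)) * inside
            dA = dA + cfg.sparsity_weight * dkl / B
        delta = dA * _activate_prime(pre[l], post[l], model.activations[l])
        a_prev = batch if l == 0 else post[l - 1]
        dW[l] = a_prev.T @ delta + cfg.l2_weight * model.weights[l]
        db[l] = delta.sum(axis=0)
        if l > 0:
            dA = delta @ model.weights[l].T
    return total, dW, db


class _Adam:
    def __init__(self, params: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def sae_fit(features: np.ndarray, cfg: SAEConfig) -> SparseAutoencoderModel:
    """Train the autoencoder on ``features`` (labels play no role).

    Deterministic given ``cfg.seed``: initialisation and epoch shuffling share
    one seeded generator.  The per-epoch mean batch cost is recorded in
    ``model.loss_history``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = features.shape
    if d != cfg.layer_sizes[0]:
        raise ValueError(
            f"feature dimension {d} does not match configured input size "
            f"{cfg.layer_sizes[0]}"
        )
    if cfg.rescale_inputs:
        features = 2.0 * features - 1.0
    rng = np.random.default_rng(cfg.seed)
    model = init_model(cfg, rng)
    params = model.weights + model.biases
    opt = _Adam(params, cfg.learning_rate)
    batch = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        costs, sizes = [], []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            total, dW, db = sae_cost_grad(model, features[idx], cfg)
            opt.step(params, dW + db)
            costs.append(total)
            sizes.append(len(idx))
        epoch_cost = float(np.average(costs, weights=sizes))
        model.loss_history.append(epoch_cost)
        logger.debug("epoch %d: mean batch cost %.6f", epoch + 1, epoch_cost)
    return model


def sae_encode(model: SparseAutoencoderModel, features: np.ndarray,
               rescale_inputs: bool = False) -> np.ndarray:
    """Map features through the encoder half; rows preserved in order."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width {features.shape[1] if features.ndim == 2 else '?'} "
            f"does not match model input dimension {model.input_dim}"
        )
    a = 2.0 * features - 1.0 if rescale_inputs else features
    for l in range(model.n_encoder_layers):
        z = a @ model.weights[l] + model.biases[l]
        a = _activate(z, model.activations[l])
    return a
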