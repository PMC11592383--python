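"""The single-channel 1D-CNN seizure classifier.

Architecture, for a standardized 1-s window of 178 samples:

    input 178x1
      -> conv(20 kernels, length 5, stride 1, valid) + ReLU -> 174x20
      -> dropout(0.5)
      -> conv(20x5) + ReLU -> 170x20 -> dropout(0.5)
      -> conv(20x5) + ReLU -> 166x20 -> dropout(0.5)
      -> maxpool(2)        -> 83x20
      -> flatten           -> 1660
      -> dense(50) + ReLU
      -> dense(1) + sigmoid -> P(seizure)

The forward pass, backpropagation and weight initialization are implemented
directly in NumPy: convolutions via a sliding-window view plus one GEMM per
layer, max-pooling with argmax routing for the gradient, and inverted
dropout active only in training mode.  Inference is a pure function of
(weights, input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelWeights",
    "relu",
    "sigmoid",
    "conv1d",
    "maxpool1d",
    "init_weights",
    "forward",
    "predict",
    "summary",
]


@dataclass
class ModelSpec:
    """Shape hyper-parameters of the classifier."""

    n_conv_layers: int = 3
    kernels_per_layer: int = 20
    kernel_length: int = 5
    conv_stride: int = 1
    dropout_rate: float = 0.5
    pool_size: int = 2
    dense_units: int = 50
    output_units: int = 1
    input_length: int = 178
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.conv_stride != 1:
            raise ValueError("only stride-1 valid convolution is supported")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.shape_chain()  # raises if the stack cannot be built

    def conv_output_lengths(self) -> list[int]:
        lengths, length = [], self.input_length
        for _ in range(self.n_conv_layers):
            length = length - self.kernel_length + 1
            if length < 1:
                raise ValueError("input too short for the convolution stack")
            lengths.append(length)
        return lengths

    def pooled_length(self) -> int:
        pooled = self.conv_output_lengths()[-1] // self.pool_size
        if pooled < 1:
            raise ValueError("input too short for pooling")
        return pooled

    def flat_width(self) -> int:
        return self.pooled_length() * self.kernels_per_layer

    def shape_chain(self) -> list[int]:
        """Feature counts through the stack, e.g. [178, 174, 170, 166, 83, 1660, 50, 1]."""
        return (
            [self.input_length]
            + self.conv_output_lengths()
            + [self.pooled_length(), self.flat_width(), self.dense_units,
               self.output_units]
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class ModelWeights:
    """Kernels/biases per conv layer and weight matrices/biases per dense layer.

    ``conv[i]`` is ``(W, b)`` with ``W`` of shape (kernel_length, in_channels,
    out_channels); ``dense[i]`` is ``(W, b)`` with ``W`` of shape
    (fan_in, fan_out).
    """

    conv: list[tuple[np.ndarray, np.ndarray]]
    dense: list[tuple[np.ndarray, np.ndarray]]

    def copy(self) -> "ModelWeights":
        return ModelWeights(
            conv=[(w.copy(), b.copy()) for w, b in self.conv],
            dense=[(w.copy(), b.copy()) for w, b in self.dense],
        )


def relu(x: np.ndarray) -> np.ndarray:
    """max(0, x) elementwise."""
    return np.maximum(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """1 / (1 + e^-x), computed stably for large |x|."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _corr_valid(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid stride-1 cross-correlation as k shifted GEMMs.

    ``x``: (B, L, C_in); ``W``: (k, C_in, K) -> (B, L-k+1, K).  Avoids the
    im2col copy, which dominates runtime at these layer sizes.
    """
    k = W.shape[0]
    L_out = x.shape[1] - k + 1
    z = x[:, 0:L_out, :] @ W[0]
    for j in range(1, k):
        z += x[:, j : j + L_out, :] @ W[j]
    return z


def conv1d(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, activation: bool = True
) -> np.ndarray:
    """Valid stride-1 1-D convolution (cross-correlation) + optional ReLU.

    ``x``: (B, L, C_in); ``W``: (k, C_in, K); ``b``: (K,).  Output
    (B, L-k+1, K).
    """
    x = np.atleast_3d(np.asarray(x, dtype=float))
    k, c_in, k_out = W.shape
    if x.shape[1] < k:
        raise ValueError(f"input length {x.shape[1]} < kernel length {k}")
    if x.shape[2] != c_in:
        raise ValueError(f"input has {x.shape[2]} channels, kernel expects {c_in}")
    z = _corr_valid(x, W) + b
    return relu(z) if activation else z


def maxpool1d(x: np.ndarray, pool_size: int = 2) -> np.ndarray:
    """Non-overlapping max pooling along the length axis; tail discarded."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :, None]
    B, L, C = x.shape
    if L < pool_size:
        raise ValueError("input shorter than one pooling window")
    n = L // pool_size
    pooled = x[:, : n * pool_size].reshape(B, n, pool_size, C).max(axis=2)
    return pooled[0, :, 0] if squeeze else pooled


def init_weights(spec: ModelSpec, seed: int = 0) -> ModelWeights:
    """Glorot-uniform kernels/matrices, zero biases, fully seeded."""
    rng = np.random.default_rng(seed)

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    conv, c_in = [], 1
    for _ in range(spec.n_conv_layers):
        k, K = spec.kernel_length, spec.kernels_per_layer
        conv.append((glorot((k, c_in, K), k * c_in, k * K), np.zeros(K)))
        c_in = K
    dense = [
        (
            glorot((spec.flat_width(), spec.dense_units),
                   spec.flat_width(), spec.dense_units),
            np.zeros(spec.dense_units),
        ),
        (
            glorot((spec.dense_units, spec.output_units),
                   spec.dense_units, spec.output_units),
            np.zeros(spec.output_units),
        ),
    ]
    return ModelWeights(conv=conv, dense=dense)


def forward(
    weights: ModelWeights,
    batch: np.ndarray,
    spec: ModelSpec | None = None,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Probabilities for a batch of standardized windows.

    In training mode, inverted dropout (scale by 1/keep) follows each
    convolutional layer and requires ``rng``; in inference mode the pass is
    deterministic.
    """
    spec = spec or ModelSpec()
    batch = np.asarray(batch, dtype=float)
    if batch.ndim == 1:
        batch = batch[None, :]
    if batch.shape[1] != spec.input_length:
        raise ValueError(
            f"windows of length {batch.shape[1]}; model expects {spec.input_length}"
        )
    if training_mode and spec.dropout_rate > 0 and rng is None:
        raise ValueError("training mode dropout requires an rng")

    cache: dict = {"conv": [], "dropout_masks": []}
    x = batch[:, :, None]
    for W, b in weights.conv:
        z = conv1d(x, W, b, activation=False)
        a = relu(z)
        if training_mode and spec.dropout_rate > 0:
            keep = 1.0 - spec.dropout_rate
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
            cache["dropout_masks"].append(mask)
        cache["conv"].append((x, z))
        x = a

    B, L, C = x.shape
    n_pool = L // spec.pool_size
    pool_in = x[:, : n_pool * spec.pool_size].reshape(B, n_pool, spec.pool_size, C)
    argmax = pool_in.argmax(axis=2)
    pooled = pool_in.max(axis=2)
    cache["pool"] = (x.shape, argmax)

    flat = pooled.reshape(B, -1)
    if flat.shape[1] != spec.flat_width():
        raise AssertionError("flatten width diverged from the spec shape chain")

    W0, b0 = weights.dense[0]
    z_hidden = flat @ W0 + b0
    hidden = relu(z_hidden)
    W1, b1 = weights.dense[1]
    logits = hidden @ W1 + b1
    probs = sigmoid(logits)[:, 0]
    cache.update(flat=flat, z_hidden=z_hidden, hidden=hidden, probs=probs)
    return (probs, cache) if return_cache else probs


def backward(
    weights: ModelWeights, cache: dict, targets: np.ndarray, spec: ModelSpec
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[tuple[np.ndarray, np.ndarray]]]:
    """Gradients of mean binary cross-entropy w.r.t. every weight array.

    Returns (conv_grads, dense_grads) mirroring the layout of ModelWeights.
    """
    probs = cache["probs"]
    B = probs.shape[0]
    dlogits = ((probs - targets) / B)[:, None]  # sigmoid+BCE shortcut

    W1, _ = weights.dense[1]
    dW1 = cache["hidden"].T @ dlogits
    db1 = dlogits.sum(axis=0)
    dhidden = dlogits @ W1.T
    dz_hidden = dhidden * (cache["z_hidden"] > 0)

    W0, _ = weights.dense[0]
    dW0 = cache["flat"].T @ dz_hidden
    db0 = dz_hidden.sum(axis=0)
    dflat = dz_hidden @ W0.T

    pool_in_shape, argmax = cache["pool"]
    Bp, L, C = pool_in_shape
    n_pool = L // spec.pool_size
    dpooled = dflat.reshape(Bp, n_pool, C)
    dpool_in = np.zeros((Bp, n_pool, spec.pool_size, C))
    bi, pi, ci = np.ogrid[:Bp, :n_pool, :C]
    dpool_in[bi, pi, argmax, ci] = dpooled[bi, pi, ci]
    dx = np.zeros(pool_in_shape)
    dx[:, : n_pool * spec.pool_size] = dpool_in.reshape(Bp, n_pool * spec.pool_size, C)

    conv_grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights.conv)
    for i in range(len(weights.conv) - 1, -1, -1):
        W, _ = weights.conv[i]
        x_in, z = cache["conv"][i]
        if cache["dropout_masks"]:
            dx = dx * cache["dropout_masks"][i]
        dz = dx * (z > 0)
        k, c_in, k_out = W.shape
        L_out = dz.shape[1]
        dW = np.stack([
            np.tensordot(x_in[:, j : j + L_out, :], dz, axes=([0, 1], [0, 1]))
            for j in range(k)
        ])
        db = dz.sum(axis=(0, 1))
        conv_grads[i] = (dW, db)
        if i > 0:
            # dX: full correlation of dz with the flipped kernel
            pad = np.pad(dz, ((0, 0), (k - 1, k - 1), (0, 0)))
            W_flip = np.ascontiguousarray(W[::-1].transpose(0, 2, 1))  # (k, K, c_in)
            dx = _corr_valid(pad, W_flip)
    return conv_grads, [(dW0, db0), (dW1, db1)]


def predict(
    weights: ModelWeights,
    batch: np.ndarray,
    threshold: float = 0.5,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Binary verdicts: 1 iff P(seizure) >= threshold.

    The tie at exactly the threshold resolves to 1, favouring sensitivity.
    """
    probs = forward(weights, batch, spec=spec, training_mode=False)
    return (probs >= threshold).astype(np.int64)


def summary(spec: ModelSpec | None = None) -> str:
    """Printable layer listing with kernel counts, sizes and output shapes."""
    spec = spec or ModelSpec()
    K, klen = spec.kernels_per_layer, spec.kernel_length
    rows = [("Layer", "Kernels", "Kernel size", "Activation", "Output shape")]
    for i, length in enumerate(spec.conv_output_lengths(), start=1):
        rows.append((f"Conv{i}", str(K), f"{klen} x 1", "ReLU", f"{length} x {K}"))
    rows.append(("Maxpool1", "-", f"{spec.pool_size} x 1", "-",
                 f"{spec.pooled_length()} x {K}"))
    rows.append(("Flatten", "-", "-", "-", str(spec.flat_width())))
    rows.append(("Dense", "-", "-", "ReLU", str(spec.dense_units)))
    rows.append(("Output", "-", "-", "Sigmoid", str(spec.output_units)))
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    return "\n".join(
        "  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows
    )
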