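"""Transformer-encoder fusion classifier, in NumPy with analytic gradients.

Architecture, segment matrix in, class probabilities out:

1. one temporal-CNN feature extractor per modality (two strided 1-D
   convolutions with ReLU), mapping a length-T channel to T′ × d_E
   embeddings (T′ = T/4 with the default strides);
2. feature-axis concatenation of the modality embeddings in fixed order,
   followed by a linear fusion projection to the encoder width d;
3. additive sinusoidal positional encoding
   ``P(i, 2j) = sin(i / 10000^{2j/d})``, ``P(i, 2j+1) = cos(i / 10000^{2j/d})``;
4. a stack of encoder layers, each computing
   ``H' = FeedForward(MultiHead(H)) + H`` — multi-head scaled dot-product
   self-attention ``softmax(QKᵀ/√d_k)V``, head concatenation projected by
   ``W_O``, a two-layer ReLU feed-forward block, one residual around the
   composition, and (by default) a post-residual LayerNorm which can be
   disabled for equation-level checks;
5. temporal mean pooling (or a learned CLS token) and a softmax linear
   classification head, trained with categorical cross-entropy.

Every layer implements ``forward``/``backward`` explicitly; gradients are
exact and float64 throughout, which the finite-difference tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "Param",
    "positional_encoding",
    "softmax",
    "scaled_dot_attention",
    "fuse_concat",
    "classify",
    "cross_entropy",
    "FeatureExtractor",
    "TransformerClassifier",
    "AdamOptimizer",
]

LOG_CLAMP = 1e-12  # floor inside cross-entropy logs


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``inner_dimension`` is an alternative handle on the attention geometry
    (grid values 4/8/16); when set it overrides ``n_heads``.  ``d_model``
    must be divisible by the head count and even (positional-encoding
    pairing).
    """

    modalities: tuple = ("hr", "gsr", "accel")
    embed_dim: int = 128  # d_E, per-modality embedding width
    cnn_hidden: int = 128
    d_model: int = 512  # fused encoder width after the linear projection
    n_layers: int = 2
    n_heads: int = 8
    ffn_dim: int | None = None  # defaults to 4 * d_model
    dropout: float = 0.2
    n_classes: int = 2
    kernel_sizes: tuple = (7, 5)
    strides: tuple = (2, 2)
    layer_norm: bool = True
    pooling: str = "mean"  # "mean" or "cls"
    inner_dimension: int | None = None

    def __post_init__(self) -> None:
        if self.inner_dimension is not None:
            self.n_heads = int(self.inner_dimension)
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even for sinusoidal positional encoding")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pooling not in ("mean", "cls"):
            raise ValueError(f"unknown pooling mode {self.pooling!r}")
        if len(self.modalities) < 1:
            raise ValueError("at least one modality branch is required")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def positional_encoding(T: int, d: int) -> np.ndarray:
    """Sinusoidal position matrix: column pair 2j/2j+1 holds
    sin/cos of ``i / 10000^{2j/d}`` at time step i."""
    if d % 2 != 0:
        raise ValueError("positional encoding width must be even")
    i = np.arange(T)[:, None]
    j = np.arange(d // 2)[None, :]
    angle = i / np.power(10000.0, 2.0 * j / d)
    P = np.empty((T, d))
    P[:, 0::2] = np.sin(angle)
    P[:, 1::2] = np.cos(angle)
    return P


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray):
    """``softmax(QKᵀ/√d_k) V``; returns (output, attention weights)."""
    d_k = Q.shape[-1]
    if d_k <= 0:
        raise ValueError("key dimensionality d_k must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    A = softmax(scores, axis=-1)
    return A @ V, A


def fuse_concat(*embeddings: np.ndarray) -> np.ndarray:
    """Feature-axis concatenation of per-modality embeddings (fixed caller
    order); all embeddings must share the time length T′."""
    lengths = {e.shape[-2] for e in embeddings}
    if len(lengths) != 1:
        raise ValueError(f"embeddings disagree on T': {sorted(lengths)}")
    return np.concatenate(embeddings, axis=-1)


def classify(E_final: np.ndarray, W_out: np.ndarray, b_out: np.ndarray) -> np.ndarray:
    """Softmax classification head over a pooled representation."""
    return softmax(E_final @ W_out + b_out, axis=-1)


def cross_entropy(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Categorical cross-entropy ``−Σ_c y_c log ŷ_c`` with the log clamped
    at 1e-12; ``y`` is one-hot (or a distribution)."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(-np.sum(y * np.log(np.clip(y_hat, LOG_CLAMP, None))))


# ---------------------------------------------------------------------------
# layers


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_uniform_init(rng, (d_in, d_out), d_in))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.W.grad += xf.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        return dy @ self.W.data.T


class Conv1d:
    """1-D convolution over (batch, time, channels), 'same'-style padding
    of (k−1)//2 so the output length is floor((T + 2p − k)/s) + 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2
        self.W = Param(_uniform_init(rng, (kernel, c_in, c_out), kernel * c_in))
        self.b = Param(np.zeros(c_out))
        self._xp = None
        self._t_out = None

    def parameters(self):
        return [self.W, self.b]

    def out_length(self, T: int) -> int:
        if T < self.kernel:
            raise ValueError(
                f"input length {T} shorter than the receptive field (kernel {self.kernel})"
            )
        return (T + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        To = self.out_length(T)
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        y = np.broadcast_to(self.b.data, (B, To, self.b.data.shape[0])).copy()
        for j in range(self.kernel):
            y += xp[:, j : j + self.stride * To : self.stride, :] @ self.W.data[j]
        self._xp, self._t_out = xp, To
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, To = self._xp, self._t_out
        dxp = np.zeros_like(xp)
        self.b.grad += dy.sum(axis=(0, 1))
        for j in range(self.kernel):
            sl = slice(j, j + self.stride * To, self.stride)
            self.W.grad[j] += np.einsum("bti,bto->io", xp[:, sl, :], dy)
            dxp[:, sl, :] += dy @ self.W.data[j].T
        if self.pad:
            return dxp[:, self.pad : -self.pad, :]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Param(np.ones(d))
        self.beta = Param(np.zeros(d))
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        N = xhat.shape[-1]
        self.gamma.grad += np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        self.beta.grad += np.sum(dy, axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.gamma.data
        return (
            inv
            / N
            * (N * dxhat - dxhat.sum(axis=-1, keepdims=True) - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))
        )


class MultiHeadSelfAttention:
    """h-head scaled dot-product self-attention with output projection."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(f"width {d_model} not divisible by {n_heads} heads")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng)
        self.Wk = Linear(d_model, d_model, rng)
        self.Wv = Linear(d_model, d_model, rng)
        self.Wo = Linear(d_model, d_model, rng)
        self._cache = None

    def parameters(self):
        return self.Wq.parameters() + self.Wk.parameters() + self.Wv.parameters() + self.Wo.parameters()

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        return x.reshape(B, T, self.h, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, H: np.ndarray) -> np.ndarray:
        Q = self._split(self.Wq.forward(H))
        K = self._split(self.Wk.forward(H))
        V = self._split(self.Wv.forward(H))
        scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(self.d_k)
        A = softmax(scores, axis=-1)
        O = A @ V
        self._cache = (Q, K, V, A)
        return self.Wo.forward(self._merge(O))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        Q, K, V, A = self._cache
        dO = self._split(self.Wo.backward(dout))
        dA = dO @ np.swapaxes(V, -1, -2)
        dV = np.swapaxes(A, -1, -2) @ dO
        dS = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dS /= np.sqrt(self.d_k)
        dQ = dS @ K
        dK = np.swapaxes(dS, -1, -2) @ Q
        dH = self.Wq.backward(self._merge(dQ))
        dH += self.Wk.backward(self._merge(dK))
        dH += self.Wv.backward(self._merge(dV))
        return dH


class FeedForward:
    def __init__(self, d_model: int, ffn_dim: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, ffn_dim, rng)
        self.act = ReLU()
        self.lin2 = Linear(ffn_dim, d_model, rng)

    def parameters(self):
        return self.lin1.parameters() + self.lin2.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lin2.forward(self.act.forward(self.lin1.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.act.backward(self.lin2.backward(dy)))


class EncoderLayer:
    """One encoder block: ``H' = FFN(MultiHead(H)) + H`` with a single
    residual around the composed branch, dropout on the branch, and an
    optional post-residual LayerNorm."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, drop_rng: np.random.Generator):
        self.mha = MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_dim, rng)
        self.drop_attn = Dropout(cfg.dropout, drop_rng)
        self.drop_ffn = Dropout(cfg.dropout, drop_rng)
        self.norm = LayerNorm(cfg.d_model) if cfg.layer_norm else None

    def parameters(self):
        ps = self.mha.parameters() + self.ffn.parameters()
        if self.norm is not None:
            ps += self.norm.parameters()
        return ps

    def forward(self, H: np.ndarray, train: bool) -> np.ndarray:
        Z = self.drop_attn.forward(self.mha.forward(H), train)
        F = self.drop_ffn.forward(self.ffn.forward(Z), train)
        out = F + H
        if self.norm is not None:
            out = self.norm.forward(out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.norm is not None:
            dy = self.norm.backward(dy)
        dF = self.drop_ffn.backward(dy)
        dZ = self.drop_attn.backward(self.ffn.backward(dF))
        return self.mha.backward(dZ) + dy


class FeatureExtractor:
    """Per-modality temporal-CNN feature extractor: two strided 1-D
    convolutions with ReLU, length T in, (T′, d_E) embedding out."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        k1, k2 = cfg.kernel_sizes
        s1, s2 = cfg.strides
        self.conv1 = Conv1d(1, cfg.cnn_hidden, k1, s1, rng)
        self.act1 = ReLU()
        self.conv2 = Conv1d(cfg.cnn_hidden, cfg.embed_dim, k2, s2, rng)
        self.act2 = ReLU()

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def out_length(self, T: int) -> int:
        return self.conv2.out_length(self.conv1.out_length(T))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.act1.backward(self.conv2.backward(self.act2.backward(dy))))


class TransformerClassifier:
    """The full classifier; deterministic given ``seed`` and serial use."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        root = np.random.default_rng(seed)
        init_rng = np.random.default_rng(root.integers(2**31))
        drop_rng = np.random.default_rng(root.integers(2**31))
        cfg = config
        self.branches = [FeatureExtractor(cfg, init_rng) for _ in cfg.modalities]
        self.fusion = Linear(len(cfg.modalities) * cfg.embed_dim, cfg.d_model, init_rng)
        self.drop_in = Dropout(cfg.dropout, drop_rng)
        self.layers = [EncoderLayer(cfg, init_rng, drop_rng) for _ in range(cfg.n_layers)]
        self.cls_token = Param(_uniform_init(init_rng, (cfg.d_model,), cfg.d_model)) if cfg.pooling == "cls" else None
        self.head = Linear(cfg.d_model, cfg.n_classes, init_rng)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.branches:
            ps += b.parameters()
        ps += self.fusion.parameters()
        if self.cls_token is not None:
            ps.append(self.cls_token)
        for layer in self.layers:
            ps += layer.parameters()
        ps += self.head.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data[...] = arr

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``X`` of shape (B, T, n_modalities)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != len(self.config.modalities):
            raise ValueError(
                f"expected (B, T, {len(self.config.modalities)}) input, got {X.shape}"
            )
        embs = [b.forward(X[:, :, m : m + 1]) for m, b in enumerate(self.branches)]
        E = fuse_concat(*embs)  # (B, T', M*d_E)
        H = self.fusion.forward(E)
        Tp = H.shape[1]
        H = H + positional_encoding(Tp, self.config.d_model)
        H = self.drop_in.forward(H, train)
        if self.cls_token is not None:
            tok = np.broadcast_to(self.cls_token.data, (H.shape[0], 1, H.shape[2]))
            H = np.concatenate([tok, H], axis=1)
        for layer in self.layers:
            H = layer.forward(H, train)
        if self.config.pooling == "cls":
            pooled = H[:, 0, :]
        else:
            pooled = H.mean(axis=1)
        self._cache = H.shape
        return self.head.forward(pooled)

    def _backward_from_logits(self, dlogits: np.ndarray) -> None:
        B, Tfull, D = self._cache
        dpooled = self.head.backward(dlogits)
        if self.config.pooling == "cls":
            dH = np.zeros((B, Tfull, D))
            dH[:, 0, :] = dpooled
        else:
            dH = np.repeat(dpooled[:, None, :] / Tfull, Tfull, axis=1)
        for layer in reversed(self.layers):
            dH = layer.backward(dH)
        if self.cls_token is not None:
            self.cls_token.grad += dH[:, 0, :].sum(axis=0)
            dH = dH[:, 1:, :]
        dH = self.drop_in.backward(dH)
        dE = self.fusion.backward(dH)
        dE_splits = np.split(dE, len(self.branches), axis=-1)
        for b, dEm in zip(self.branches, dE_splits):
            b.backward(dEm)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X, train=False), axis=-1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X, train=False), axis=-1)

    def loss_and_grad(self, X: np.ndarray, y: np.ndarray, train: bool = True) -> float:
        """Mean cross-entropy over the batch; accumulates parameter grads."""
        y = np.asarray(y, dtype=int)
        logits = self.forward(X, train=train)
        probs = softmax(logits, axis=-1)
        B = len(y)
        loss = -np.mean(np.log(np.clip(probs[np.arange(B), y], LOG_CLAMP, None)))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        self._backward_from_logits(dlogits)
        return float(loss)


class AdamOptimizer:
    """Adam with decoupled-from-nothing classic L2 (weight decay added to
    the gradient, as an optimizer-side regulariser)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
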