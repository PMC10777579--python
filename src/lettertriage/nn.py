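"""Neural building blocks: linear/embedding/layer-norm layers, multi-head
self-attention, a small transformer encoder, a 1-D text convolution head,
softmax cross-entropy, and Adam.

Everything runs on the package's own autograd (see :mod:`lettertriage.autograd`);
shapes follow the text-classification convention (batch, time, channels).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

NEG_INF = -1e9


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def train(self):
        self.training = True
        for v in vars(self).values():
            for m in _collect_modules(v):
                m.train()
        return self

    def eval(self):
        self.training = False
        for v in vars(self).values():
            for m in _collect_modules(v):
                m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator,
                 trainable: bool = True, pad_index: int | None = 0):
        super().__init__()
        mat = rng.normal(0.0, 1.0 / np.sqrt(dim), (n_vocab, dim))
        if pad_index is not None:
            mat[pad_index] = 0.0
        self.weight = Tensor(mat, requires_grad=trainable)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.take_rows(ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; the mask is drawn from the module's own rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant; grad-safe
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer class labels.

    Computed through log-sum-exp on the logits, so probabilities of exactly
    zero are never taken through a bare log.
    """
    labels = np.asarray(labels)
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()


class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if hidden % n_heads != 0:
            raise ValueError("hidden size must divide evenly across heads")
        self.n_heads = n_heads
        self.d_head = hidden // n_heads
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)

    def __call__(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        B, T, H = x.shape
        nh, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,T,H) -> (B,nh,T,dh)
            return t.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        # additive mask: invalid key positions get a large negative score
        bias = (1.0 - attention_mask[:, None, None, :]) * NEG_INF
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, H)
        return self.out(ctx)


class TransformerLayer(Module):
    """Post-norm transformer block (attention -> add & norm -> FFN -> add & norm)."""

    def __init__(self, hidden: int, n_heads: int, ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(hidden, n_heads, rng)
        self.norm1 = LayerNorm(hidden)
        self.ff1 = Linear(hidden, ff, rng)
        self.ff2 = Linear(ff, hidden, rng)
        self.norm2 = LayerNorm(hidden)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, attention_mask)))
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class TinyTransformerEncoder(Module):
    """A desk-scale contextual encoder with the BERT-style interface.

    Returns per-token hidden states; the first position (the start special)
    serves as the pooled representation H of the whole text.
    """

    def __init__(self, n_vocab: int, hidden: int = 32, n_heads: int = 2,
                 n_layers: int = 2, ff: int = 64, max_len: int = 256,
                 dropout: float = 0.1, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.max_len = max_len
        self.tok = Embedding(n_vocab, hidden, rng, pad_index=0)
        self.pos = Tensor(
            rng.normal(0.0, 0.02, (max_len, hidden)), requires_grad=True
        )
        self.norm = LayerNorm(hidden)
        self.layers = [
            TransformerLayer(hidden, n_heads, ff, dropout, rng)
            for _ in range(n_layers)
        ]

    def __call__(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds encoder limit {self.max_len}")
        x = self.tok(ids) + self.pos[:T]
        x = self.norm(x)
        for layer in self.layers:
            x = layer(x, attention_mask)
        return x  # (B, T, hidden)


class TextConvHead(Module):
    """1-D convolutions over time with per-filter max pooling.

    Kernel widths default to (2, 3, 4) with two filters each, so the pooled
    feature vector has dimension 6; a linear layer maps it to the class
    logits. Pad positions are masked to a large negative value before the
    max-pool so padding can never win the max.
    """

    def __init__(self, in_channels: int, n_classes: int,
                 kernel_sizes: tuple[int, ...] = (2, 3, 4),
                 filters_per_kernel: int = 2, dropout: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kernel_sizes = tuple(kernel_sizes)
        self.filters_per_kernel = filters_per_kernel
        self.weights = []
        self.biases = []
        for k in self.kernel_sizes:
            scale = 1.0 / np.sqrt(k * in_channels)
            self.weights.append(
                Tensor(rng.normal(0.0, scale, (k, in_channels, filters_per_kernel)),
                       requires_grad=True)
            )
            self.biases.append(
                Tensor(np.zeros(filters_per_kernel), requires_grad=True)
            )
        self.drop = Dropout(dropout, rng)
        self.pooled_dim = len(self.kernel_sizes) * filters_per_kernel
        self.head = Linear(self.pooled_dim, n_classes, rng)

    def conv_maps(self, x: Tensor) -> list[Tensor]:
        """Valid 1-D convolutions: input (B, m, C) -> list of (B, m-k+1, F)."""
        B, m, C = x.shape
        maps = []
        for k, W, b in zip(self.kernel_sizes, self.weights, self.biases):
            L = m - k + 1
            if L < 1:
                raise ValueError(f"sequence length {m} shorter than kernel {k}")
            acc = x[:, 0:L, :] @ W[0]
            for i in range(1, k):
                acc = acc + x[:, i:i + L, :] @ W[i]
            maps.append((acc + b).relu())
        return maps

    def __call__(self, x: Tensor, attention_mask: np.ndarray | None = None) -> Tensor:
        maps = self.conv_maps(x)
        pooled = []
        for k, fmap in zip(self.kernel_sizes, maps):
            if attention_mask is not None:
                L = fmap.shape[1]
                # a window is valid iff every position it covers is valid
                win_valid = attention_mask[:, :L].copy()
                for i in range(1, k):
                    win_valid = win_valid * attention_mask[:, i:i + L]
                fmap = fmap + Tensor((1.0 - win_valid[:, :, None]) * NEG_INF)
            pooled.append(fmap.max(axis=1))
        feat = self.drop(concat(pooled, axis=-1))
        return self.head(feat)


class Adam:
    """Adam with standard moment defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
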