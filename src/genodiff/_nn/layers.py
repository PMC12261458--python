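"""Neural network modules on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, softmax


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Base class: parameter discovery via attribute walk, state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.weight = parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.bias = parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution over (n, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        fan_in = c_in * kernel_size
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.weight = parameter(rng.uniform(-limit, limit, size=(c_out, c_in, kernel_size)))
        self.bias = parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = parameter(rng.normal(0.0, 0.02, size=(n_embeddings, dim)))

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, tokens, d = x.shape
        qkv = self.qkv(x)  # (n, T, 3d)
        qkv = qkv.reshape(n, tokens, 3, self.n_heads, self.d_head)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, n, heads, T, d_head)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = q @ k.swapaxes(-1, -2) * (self.d_head ** -0.5)
        att = softmax(att, axis=-1)
        out = att @ v  # (n, heads, T, d_head)
        out = out.transpose(0, 2, 1, 3).reshape(n, tokens, d)
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: LN → MHSA → residual; LN → FFN → residual."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).silu())


def sinusoidal_time_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Fixed sin/cos features of a normalized time t ∈ [0, 1]; shape (n, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    angles = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(angles), np.cos(angles)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb
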