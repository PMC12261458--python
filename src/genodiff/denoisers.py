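"""Noise-prediction architectures for the diffusion model.

Four interchangeable denoisers behind one interface, all mapping
``(x: n x G_pad x 8, t: normalized time in [0,1], y: class index or None)``
to a predicted noise tensor of the same shape:

* ``UNetMLP`` — U-Net whose levels mix the gene axis with dense layers
  (no attention); position-aware but parameter-hungry.
* ``UNetCNN`` — U-Net with 1-D convolutions along the gene axis; captures
  short/medium-range structure with few parameters but no absolute position.
* ``CombinedDenoiser`` — the learned convex combination
  ``(1 - lambda(t)) * MLP(x,t,y) + lambda(t) * CNN(x,t,y)`` with a scalar
  lambda(t) produced by a 2-layer perceptron with sigmoid output; both
  submodels and the mixer train jointly through this output.
* ``TransformerDenoiser`` — encoder with gene-patch tokens, learnable
  positional embeddings, and two extra tokens carrying t and y.

Conditioning uses a sinusoidal embedding of t plus a learned class
embedding, summed and injected additively in the up-projection blocks
(U-Nets) or as tokens (transformer). ``y=None`` selects a dedicated null
class embedding (unconditional generation).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._nn import (
    Conv1d,
    Embedding,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    parameter,
    sinusoidal_time_embedding,
)

_T_EMB_DIM = 32


class ConditioningEmbed(Module):
    """Summed sinusoidal-t and learned-y embedding of dimension cond_dim."""

    def __init__(self, n_classes: int, cond_dim: int, rng: np.random.Generator):
        self.n_classes = n_classes
        self.t_proj = Linear(_T_EMB_DIM, cond_dim, rng)
        self.y_embed = Embedding(n_classes + 1, cond_dim, rng)  # index n_classes = null

    def forward(self, t: np.ndarray, y: np.ndarray | None, n: int) -> Tensor:
        t_emb = Tensor(sinusoidal_time_embedding(np.broadcast_to(t, (n,)), _T_EMB_DIM))
        idx = np.full(n, self.n_classes) if y is None else np.asarray(y, dtype=np.intp)
        return self.t_proj(t_emb).silu() + self.y_embed(idx)


class Denoiser(Module):
    """Interface: forward(x, t, y) -> epsilon-hat with the shape of x."""

    arch: str = "base"
    config: dict

    def forward(self, x, t, y) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _as_tensor(x) -> Tensor:
        return x if isinstance(x, Tensor) else Tensor(x)

    def save(self, path: str | Path, seed: int | None = None, codec_fingerprint: str = "") -> None:
        meta = {
            "arch": self.arch,
            "config": self.config,
            "seed": seed,
            "codec_fingerprint": codec_fingerprint,
        }
        state = {f"param::{k}": v for k, v in self.state_dict().items()}
        np.savez_compressed(path, meta=np.array(json.dumps(meta)), **state)


def load_denoiser(path: str | Path) -> Denoiser:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    cls = {c.arch: c for c in (UNetMLP, UNetCNN, CombinedDenoiser, TransformerDenoiser)}[
        meta["arch"]
    ]
    model = cls.from_config(meta["config"])
    model.load_state_dict(state)
    return model


def _check_divisible(g_pad: int, depth: int) -> None:
    if g_pad % (1 << depth):
        raise ValueError(f"gene axis length {g_pad} is not divisible by 2**{depth}")


class UNetMLP(Denoiser):
    """Dense U-Net: each level fully connects the flattened gene axis.

    Down blocks halve the gene axis, up blocks double it and concatenate the
    skip activation from the matching down level; conditioning is added
    inside the up blocks. No attention.
    """

    arch = "unet_mlp"

    def __init__(
        self,
        g_pad: int,
        depth: int,
        n_classes: int,
        cond_dim: int = 32,
        seed: int = 0,
    ):
        _check_divisible(g_pad, depth)
        rng = np.random.default_rng(seed)
        self.config = dict(
            g_pad=g_pad, depth=depth, n_classes=n_classes, cond_dim=cond_dim, seed=seed
        )
        self.g_pad, self.depth = g_pad, depth
        feats = [(g_pad >> i) * 8 for i in range(depth + 1)]
        self.cond = ConditioningEmbed(n_classes, cond_dim, rng)
        self.down = [Linear(feats[i], feats[i + 1], rng) for i in range(depth)]
        self.mid = Linear(feats[depth], feats[depth], rng)
        self.up = [Linear(feats[i + 1] * 2, feats[i], rng) for i in reversed(range(depth))]
        self.cond_proj = [Linear(cond_dim, feats[i], rng) for i in reversed(range(depth))]
        self.out = Linear(feats[0], feats[0], rng)

    @classmethod
    def from_config(cls, cfg: dict) -> "UNetMLP":
        return cls(**cfg)

    def forward(self, x, t, y) -> Tensor:
        x = self._as_tensor(x)
        n = x.shape[0]
        cond = self.cond(np.asarray(t), y, n)
        flat = x.reshape(n, self.g_pad * 8)
        h = flat
        acts = []
        for lin in self.down:
            h = lin(h).silu()
            acts.append(h)  # down-block output, same width as the paired up input
        h = self.mid(h).silu()
        for lin, proj, skip in zip(self.up, self.cond_proj, reversed(acts)):
            h = Tensor.cat([h, skip], axis=1)
            h = (lin(h) + proj(cond)).silu()
        # top-level residual: the predicted noise approaches x_t itself at
        # high noise levels, so the net only has to learn the correction
        return (flat + self.out(h)).reshape(n, self.g_pad, 8)


class UNetCNN(Denoiser):
    """1-D convolutional U-Net along the gene axis (8 coefficient channels).

    Down: conv + SiLU + average-pool(2); up: nearest upsample(2) + skip
    concatenation + conv, with conditioning added per channel in up blocks.
    """

    arch = "unet_cnn"

    def __init__(
        self,
        g_pad: int,
        depth: int,
        n_classes: int,
        base_channels: int = 16,
        kernel_size: int = 5,
        cond_dim: int = 32,
        seed: int = 0,
    ):
        _check_divisible(g_pad, depth)
        rng = np.random.default_rng(seed)
        self.config = dict(
            g_pad=g_pad,
            depth=depth,
            n_classes=n_classes,
            base_channels=base_channels,
            kernel_size=kernel_size,
            cond_dim=cond_dim,
            seed=seed,
        )
        self.g_pad, self.depth = g_pad, depth
        ch = [8] + [base_channels << i for i in range(depth)]
        self.cond = ConditioningEmbed(n_classes, cond_dim, rng)
        self.down = [Conv1d(ch[i], ch[i + 1], kernel_size, rng) for i in range(depth)]
        self.mid = Conv1d(ch[depth], ch[depth], kernel_size, rng)
        self.up = [
            Conv1d(2 * ch[i + 1], ch[i], kernel_size, rng) for i in reversed(range(depth))
        ]
        self.cond_proj = [Linear(cond_dim, ch[i], rng) for i in reversed(range(depth))]
        self.out = Conv1d(8, 8, kernel_size, rng)

    @classmethod
    def from_config(cls, cfg: dict) -> "UNetCNN":
        return cls(**cfg)

    @staticmethod
    def _pool2(h: Tensor) -> Tensor:
        n, c, length = h.shape
        return h.reshape(n, c, length // 2, 2).mean(axis=3)

    @staticmethod
    def _up2(h: Tensor) -> Tensor:
        n, c, length = h.shape
        h = h.reshape(n, c, length, 1)
        return Tensor.cat([h, h], axis=3).reshape(n, c, 2 * length)

    def forward(self, x, t, y) -> Tensor:
        x = self._as_tensor(x)
        n = x.shape[0]
        cond = self.cond(np.asarray(t), y, n)
        chan = x.transpose(0, 2, 1)  # (n, 8, G)
        h = chan
        skips = []
        for conv in self.down:
            h = conv(h).silu()
            skips.append(h)
            h = self._pool2(h)
        h = self.mid(h).silu()
        for conv, proj, skip in zip(self.up, self.cond_proj, reversed(skips)):
            h = Tensor.cat([self._up2(h), skip], axis=1)
            bias = proj(cond).reshape(n, -1, 1)
            h = (conv(h) + bias).silu()
        # top-level residual, as in the MLP variant
        return (chan + self.out(h)).transpose(0, 2, 1)


class MixingFunction(Module):
    """lambda(t): 2-layer perceptron on the noise level with sigmoid output,
    so lambda(t) in [0, 1] and the combined model stays a convex mixture."""

    def __init__(self, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.l1 = Linear(1, hidden, rng)
        self.l2 = Linear(hidden, 1, rng)

    def forward(self, t: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(t, dtype=np.float64).reshape(-1, 1))
        return self.l2(self.l1(t).tanh()).sigmoid()


class CombinedDenoiser(Denoiser):
    """Learned convex combination of an MLP U-Net and a CNN U-Net:
    ``(1 - lambda(t)) * MLP(x,t,y) + lambda(t) * CNN(x,t,y)``."""

    arch = "combined"

    def __init__(self, mlp: UNetMLP, cnn: UNetCNN, mixer: MixingFunction | None = None, seed: int = 0):
        self.mlp = mlp
        self.cnn = cnn
        self.mixer = mixer if mixer is not None else MixingFunction(seed=seed)
        self.config = dict(mlp=mlp.config, cnn=cnn.config, seed=seed)

    @classmethod
    def from_config(cls, cfg: dict) -> "CombinedDenoiser":
        return cls(UNetMLP(**cfg["mlp"]), UNetCNN(**cfg["cnn"]), seed=cfg.get("seed", 0))

    def forward(self, x, t, y) -> Tensor:
        lam = self.mixer(np.asarray(t))  # (n, 1)
        if (lam.data < 0).any() or (lam.data > 1).any():
            raise ValueError("mixing coefficient lambda(t) left [0, 1]")
        n = lam.shape[0]
        lam = lam.reshape(n, 1, 1)
        return (1.0 - lam) * self.mlp.forward(x, t, y) + lam * self.cnn.forward(x, t, y)


class TransformerDenoiser(Denoiser):
    """Encoder over gene-patch tokens with learnable positional embeddings
    and two extra tokens for t and y."""

    arch = "transformer"

    def __init__(
        self,
        g_pad: int,
        n_classes: int,
        patch_size: int = 8,
        d_model: int = 64,
        n_heads: int = 4,
        n_layers: int = 2,
        d_ff: int = 128,
        seed: int = 0,
    ):
        if g_pad % patch_size:
            raise ValueError(f"patch size {patch_size} does not divide gene axis {g_pad}")
        rng = np.random.default_rng(seed)
        self.config = dict(
            g_pad=g_pad,
            n_classes=n_classes,
            patch_size=patch_size,
            d_model=d_model,
            n_heads=n_heads,
            n_layers=n_layers,
            d_ff=d_ff,
            seed=seed,
        )
        self.g_pad, self.patch_size = g_pad, patch_size
        self.n_classes = n_classes
        self.n_patches = g_pad // patch_size
        self.patch_in = Linear(patch_size * 8, d_model, rng)
        self.patch_out = Linear(d_model, patch_size * 8, rng)
        self.t_proj = Linear(_T_EMB_DIM, d_model, rng)
        self.y_embed = Embedding(n_classes + 1, d_model, rng)
        self.pos = parameter(rng.normal(0.0, 0.02, size=(self.n_patches + 2, d_model)))
        self.layers = [TransformerEncoderLayer(d_model, n_heads, d_ff, rng) for _ in range(n_layers)]

    @classmethod
    def from_config(cls, cfg: dict) -> "TransformerDenoiser":
        return cls(**cfg)

    def forward(self, x, t, y) -> Tensor:
        x = self._as_tensor(x)
        n = x.shape[0]
        t_tok = self.t_proj(
            Tensor(sinusoidal_time_embedding(np.broadcast_to(np.asarray(t), (n,)), _T_EMB_DIM))
        ).reshape(n, 1, -1)
        idx = np.full(n, self.n_classes) if y is None else np.asarray(y, dtype=np.intp)
        y_tok = self.y_embed(idx).reshape(n, 1, -1)
        patches = x.reshape(n, self.n_patches, self.patch_size * 8)
        tokens = Tensor.cat([t_tok, y_tok, self.patch_in(patches)], axis=1)
        h = tokens + self.pos
        for layer in self.layers:
            h = layer(h)
        out = self.patch_out(h[:, 2:, :])
        # top-level residual, as in the U-Net variants
        return x + out.reshape(n, self.g_pad, 8)


def build_denoiser(arch: str, g_pad: int, depth: int, n_classes: int, seed: int = 0) -> Denoiser:
    """Factory covering the four architectures with desk-scale defaults."""
    if arch == "unet_mlp":
        return UNetMLP(g_pad, depth, n_classes, seed=seed)
    if arch == "unet_cnn":
        return UNetCNN(g_pad, depth, n_classes, seed=seed)
    if arch == "combined":
        return CombinedDenoiser(
            UNetMLP(g_pad, depth, n_classes, seed=seed),
            UNetCNN(g_pad, depth, n_classes, seed=seed + 1),
            seed=seed + 2,
        )
    if arch == "transformer":
        patch = 8 if g_pad % 8 == 0 else 4
        return TransformerDenoiser(g_pad, n_classes, patch_size=patch, seed=seed)
    raise ValueError(f"unknown architecture {arch!r}")
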