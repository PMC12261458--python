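"""Denoising-diffusion machinery over gene embeddings.

Standard Gaussian DDPM formulation on the ``n x G_pad x 8`` embedding
tensor: a linear beta schedule, the closed-form forward marginal
``x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps``, an epsilon-prediction MSE
objective, and full-length ancestral sampling (no step skipping, no
classifier-free guidance — full-step generation preserved sample quality and
guidance brought no accuracy gain, so both stay off).

Two contracts hold everywhere: noise is drawn only at live coefficient
slots, and the clamp mask is re-applied after every operation, so padded
slots are exactly zero at all times. Time is exposed to denoisers as
normalized t/T in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, no_grad
from .gene_embedding import GeneEmbedding, apply_clamp


@dataclass(frozen=True)
class NoiseSchedule:
    """Linear beta schedule with cached cumulative products.

    Arrays are indexed by step t in 1..T via ``beta[t-1]`` etc.;
    ``alpha_bar[t-1]`` is the product of (1 - beta) up to and including t.
    """

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray
    kind: str = "linear"

    def abar(self, t) -> np.ndarray:
        """alpha_bar at step(s) t in 1..T."""
        return self.alpha_bar[np.asarray(t) - 1]


def build_schedule(T: int, beta_start: float = 1e-4, beta_end: float = 0.02) -> NoiseSchedule:
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 < beta_start <= beta_end < 1.0):
        raise ValueError("need 0 < beta_start <= beta_end < 1")
    beta = np.linspace(beta_start, beta_end, T)
    alpha = 1.0 - beta
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=np.cumprod(alpha))


@dataclass
class DiffusionConfig:
    """Training/sampling settings; the seed is recorded in every artifact."""

    T: int = 1000
    beta_start: float = 1e-4
    beta_end: float = 0.02
    depth: int = 3
    batch_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 40
    seed: int = 0
    conditional: bool = True

    def __post_init__(self) -> None:
        for name in ("T", "depth", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def schedule(self) -> NoiseSchedule:
        return build_schedule(self.T, self.beta_start, self.beta_end)


def forward_noise(
    x0: np.ndarray, t, epsilon: np.ndarray, schedule: NoiseSchedule, clamp_mask: np.ndarray
) -> np.ndarray:
    """Closed-form forward marginal at step t, clamped at padded slots."""
    if epsilon.shape != x0.shape:
        raise ValueError(f"epsilon shape {epsilon.shape} != x0 shape {x0.shape}")
    abar = np.asarray(schedule.abar(t), dtype=np.float64)
    abar = abar.reshape((-1,) + (1,) * (x0.ndim - 1)) if abar.ndim else abar
    x_t = np.sqrt(abar) * x0 + np.sqrt(1.0 - abar) * epsilon
    return apply_clamp(x_t, clamp_mask)


def draw_noise(shape: tuple[int, ...], clamp_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard normal at live slots, exactly zero at padded slots."""
    return apply_clamp(rng.standard_normal(shape), clamp_mask)


def training_step(
    model,
    optimizer: Adam,
    batch: np.ndarray,
    labels: np.ndarray | None,
    schedule: NoiseSchedule,
    clamp_mask: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """One epsilon-prediction MSE step over live slots; returns the loss."""
    n = batch.shape[0]
    t = rng.integers(1, schedule.T + 1, size=n)
    eps = draw_noise(batch.shape, clamp_mask, rng)
    x_t = forward_noise(batch, t, eps, schedule, clamp_mask)
    pred = model.forward(x_t, t / schedule.T, labels)
    n_live = float(clamp_mask.sum())
    diff = (pred - eps) * clamp_mask
    loss = (diff ** 2.0).sum() * (1.0 / (n * n_live))
    value = loss.item()
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite training loss (t range {t.min()}-{t.max()}, "
            f"|x_t| max {np.abs(x_t).max():.3g})"
        )
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return value


def epsilon_mse(model, batch, labels, schedule, clamp_mask, rng) -> float:
    """Validation-style loss: same objective as training_step, no update."""
    n = batch.shape[0]
    t = rng.integers(1, schedule.T + 1, size=n)
    eps = draw_noise(batch.shape, clamp_mask, rng)
    x_t = forward_noise(batch, t, eps, schedule, clamp_mask)
    with no_grad():
        pred = model.forward(x_t, t / schedule.T, labels).data
    n_live = float(clamp_mask.sum())
    return float((((pred - eps) * clamp_mask) ** 2).sum() / (n * n_live))


def sample(
    model,
    n: int,
    y,
    schedule: NoiseSchedule,
    clamp_mask: np.ndarray,
    rng: np.random.Generator,
    x0_clip: float | np.ndarray | None = None,
) -> np.ndarray:
    """Ancestral sampling over all T steps with clamping after every step.

    y is a class index (broadcast), an array of per-sample indices, or None
    for unconditional generation. Posterior variance is beta-tilde.

    ``x0_clip`` bounds the implied clean sample at every step (the standard
    clip-denoised stabilization): the PCA embedding space has a bounded data
    range by construction, and clipping the x0 estimate to it stops
    prediction errors early in the reverse chain from compounding. Pass a
    scalar (symmetric bound) or a ``(G_pad, 8)`` array; None disables.
    """
    if n <= 0:
        raise ValueError("number of samples must be positive")
    labels = None
    if y is not None:
        labels = np.broadcast_to(np.asarray(y, dtype=np.intp), (n,)).copy()
    shape = (n,) + clamp_mask.shape
    x = draw_noise(shape, clamp_mask, rng)
    for t in range(schedule.T, 0, -1):
        abar_t = schedule.alpha_bar[t - 1]
        alpha_t = schedule.alpha[t - 1]
        beta_t = schedule.beta[t - 1]
        abar_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
        t_norm = np.full(n, t / schedule.T)
        with no_grad():
            eps_hat = model.forward(x, t_norm, labels).data
        if x0_clip is None:
            mean = (x - beta_t / np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(alpha_t)
        else:
            x0_hat = (x - np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(abar_t)
            x0_hat = np.clip(x0_hat, -np.asarray(x0_clip), np.asarray(x0_clip))
            # posterior mean of q(x_{t-1} | x_t, x0_hat)
            mean = (
                np.sqrt(abar_prev) * beta_t / (1.0 - abar_t) * x0_hat
                + np.sqrt(alpha_t) * (1.0 - abar_prev) / (1.0 - abar_t) * x
            )
        if t > 1:
            var = beta_t * (1.0 - abar_prev) / (1.0 - abar_t)
            x = mean + np.sqrt(var) * draw_noise(shape, clamp_mask, rng)
        else:
            x = mean
        x = apply_clamp(x, clamp_mask)
    return x


def embedding_clip_bound(embedding: GeneEmbedding, margin: float = 1.2) -> np.ndarray:
    """Per-slot symmetric bound on plausible clean coefficients, taken from
    the training embedding's observed extremes with a safety margin."""
    return margin * np.abs(embedding.tensor).max(axis=0)


def one_shot_reconstruct(
    model,
    x0: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    clamp_mask: np.ndarray,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Single-shot denoising: noise x0 to level t, invert in one step.

    Returns (x_p, ||x0 - x_p||) where the norm runs over live slots only
    (padded slots are zero in both). Monitoring this reconstruction error on
    validation data tracks generation quality during training.
    """
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t must lie in [1, {schedule.T}]")
    abar_t = float(schedule.abar(t))
    if abar_t <= 0.0:
        raise ValueError("alpha_bar at t is zero; one-shot inversion undefined")
    eps = draw_noise(x0.shape, clamp_mask, rng)
    x_t = forward_noise(x0, t, eps, schedule, clamp_mask)
    t_norm = np.full(x0.shape[0], t / schedule.T)
    with no_grad():
        eps_hat = model.forward(x_t, t_norm, labels).data
    x_p = (x_t - np.sqrt(1.0 - abar_t) * eps_hat) / np.sqrt(abar_t)
    x_p = apply_clamp(x_p, clamp_mask)
    return x_p, float(np.linalg.norm(x0 - x_p))


@dataclass
class TrainingHistory:
    steps: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    recon_steps: list[int] = field(default_factory=list)
    recon_error: list[float] = field(default_factory=list)

    def to_frame(self):
        """Step/loss log with the one-shot reconstruction error merged in
        (NaN at steps where it was not measured)."""
        import pandas as pd

        frame = pd.DataFrame({"step": self.steps, "loss": self.loss})
        recon = pd.DataFrame({"step": self.recon_steps, "recon_error": self.recon_error})
        return frame.merge(recon, on="step", how="left")


def train_denoiser(
    model,
    embedding: GeneEmbedding,
    config: DiffusionConfig,
    rng: np.random.Generator | None = None,
    val_fraction: float = 0.1,
    recon_t_fraction: float = 0.5,
    log_every: int = 50,
) -> TrainingHistory:
    """Train an epsilon-predictor on an embedded cohort.

    Holds out ``val_fraction`` of samples to track the one-shot
    reconstruction error at a fixed noise level while training on the rest.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    schedule = config.schedule()
    mask = embedding.clamp_mask
    n = embedding.n_samples
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train = embedding.tensor[train_idx]
    y_train = embedding.labels[train_idx] if config.conditional else None
    x_val = embedding.tensor[val_idx]
    y_val = embedding.labels[val_idx] if config.conditional else None
    recon_t = max(1, int(round(recon_t_fraction * schedule.T)))

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(train_idx))
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            labels = y_train[idx] if y_train is not None else None
            loss = training_step(model, optimizer, x_train[idx], labels, schedule, mask, rng)
            history.steps.append(step)
            history.loss.append(loss)
            if step % log_every == 0:
                _, err = one_shot_reconstruct(
                    model, x_val, recon_t, schedule, mask, rng, labels=y_val
                )
                history.recon_steps.append(step)
                history.recon_error.append(err)
            step += 1
    return history
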