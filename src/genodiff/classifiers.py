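"""Classifier harnesses for train-synthetic-test-real and augmentation runs.

Classifiers consume embedding-space inputs (``n x G_pad x 8`` tensors).
Three architectures are available: a common MLP (scikit-learn
``MLPClassifier`` on the flattened tensor), a small 1-D CNN, and a compact
transformer encoder, the latter two built on the in-repo autodiff core. All
runs are deterministic under their recorded seed, stop early on a validation
split, and are always *evaluated on real held-out data*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from ._nn import Adam, Conv1d, Linear, Module, Tensor, TransformerEncoderLayer, log_softmax, no_grad
from .evaluation import recovery_rate
from .gene_embedding import GeneEmbedding

ARCHITECTURES = ("mlp", "cnn", "transformer")


@dataclass(frozen=True)
class ClassifierSpec:
    architecture: str = "mlp"
    n_classes: int = 2
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 8
    val_fraction: float = 0.15
    l2_penalty: float = 1e-4  # MLP weight decay (sklearn alpha)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def _as_tensor3d(X) -> np.ndarray:
    if isinstance(X, GeneEmbedding):
        return X.tensor
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("classifier input must be (n, G_pad, 8)")
    return X


class _SklearnMLP:
    """Flattened-input MLP; thin wrapper keeping the common interface."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.net = MLPClassifier(
            hidden_layer_sizes=(128, 64),
            alpha=spec.l2_penalty,
            max_iter=500,
            early_stopping=True,
            n_iter_no_change=spec.patience,
            validation_fraction=spec.val_fraction,
            learning_rate_init=spec.learning_rate,
            random_state=spec.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnMLP":
        n = X.shape[0]
        self.net.fit(X.reshape(n, -1), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(X.reshape(X.shape[0], -1))


class _CNNNet(Module):
    def __init__(self, n_classes: int, rng: np.random.Generator):
        self.c1 = Conv1d(8, 16, 5, rng)
        self.c2 = Conv1d(16, 32, 5, rng)
        self.head = Linear(32, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x.transpose(0, 2, 1)  # (n, 8, G)
        h = self.c1(h).silu()
        n, c, length = h.shape
        h = h.reshape(n, c, length // 2, 2).mean(axis=3)
        h = self.c2(h).silu()
        h = h.mean(axis=2)  # global average pool
        return self.head(h)


class _TransformerNet(Module):
    def __init__(self, g_pad: int, n_classes: int, rng: np.random.Generator, patch: int = 8):
        if g_pad % patch:
            patch = 4 if g_pad % 4 == 0 else 2
        self.patch = patch
        self.n_patches = g_pad // patch
        d_model = 32
        self.embed = Linear(patch * 8, d_model, rng)
        from ._nn import parameter

        self.pos = parameter(rng.normal(0.0, 0.02, size=(self.n_patches, d_model)))
        self.layers = [TransformerEncoderLayer(d_model, 4, 64, rng) for _ in range(2)]
        self.head = Linear(d_model, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        tokens = self.embed(x.reshape(n, self.n_patches, self.patch * 8)) + self.pos
        for layer in self.layers:
            tokens = layer(tokens)
        return self.head(tokens.mean(axis=1))


class _AutodiffClassifier:
    """Cross-entropy training with early stopping on a validation split."""

    def __init__(self, spec: ClassifierSpec, g_pad: int):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        if spec.architecture == "cnn":
            self.net = _CNNNet(spec.n_classes, self.rng)
        else:
            self.net = _TransformerNet(g_pad, spec.n_classes, self.rng)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_AutodiffClassifier":
        spec = self.spec
        n = X.shape[0]
        perm = self.rng.permutation(n)
        n_val = max(1, int(round(spec.val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        onehot = np.eye(spec.n_classes)[y]
        opt = Adam(self.net.parameters(), lr=spec.learning_rate)
        best_acc, best_state, since_best = -1.0, None, 0
        for _ in range(spec.epochs):
            order = self.rng.permutation(len(tr_idx))
            for lo in range(0, len(order), spec.batch_size):
                idx = tr_idx[order[lo : lo + spec.batch_size]]
                logits = self.net(Tensor(X[idx]))
                logp = log_softmax(logits, axis=-1)
                loss = -(logp * onehot[idx]).sum(axis=1).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
            acc = float(np.mean(self._predict_arr(X[val_idx]) == y[val_idx]))
            if acc > best_acc + 1e-12:
                best_acc, best_state, since_best = acc, self.net.state_dict(), 0
            else:
                since_best += 1
                if since_best >= spec.patience:
                    break
        if best_state is not None:
            self.net.load_state_dict(best_state)
        return self

    def _predict_arr(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.intp)
        with no_grad():
            for lo in range(0, X.shape[0], 256):
                logits = self.net(Tensor(X[lo : lo + 256])).data
                out[lo : lo + 256] = logits.argmax(axis=1)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict_arr(X)


def train_classifier(spec: ClassifierSpec, X, y: np.ndarray):
    """Train one classifier on embedding-space inputs; deterministic per seed."""
    X = _as_tensor3d(X)
    y = np.asarray(y, dtype=np.intp)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if spec.architecture == "mlp":
        model = _SklearnMLP(spec)
    else:
        model = _AutodiffClassifier(spec, g_pad=X.shape[1])
    return model.fit(X, y)


def accuracy(model, X, y: np.ndarray) -> float:
    X = _as_tensor3d(X)
    return float(np.mean(model.predict(X) == np.asarray(y)))


@dataclass
class GridCell:
    a_r: float
    a_s: float
    recovery: float
    seed: int


@dataclass
class ExperimentGrid:
    """generator x classifier accuracy/recovery matrix."""

    cells: dict[tuple[str, str], GridCell] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "generator": g,
                "classifier": c,
                "a_r": cell.a_r,
                "a_s": cell.a_s,
                "recovery_pct": 100.0 * cell.recovery,
                "seed": cell.seed,
            }
            for (g, c), cell in self.cells.items()
        ]
        return pd.DataFrame(rows)


def recovery_experiment(
    real_train: GeneEmbedding,
    real_test: GeneEmbedding,
    syn_sets: dict[str, GeneEmbedding],
    specs: list[ClassifierSpec],
) -> ExperimentGrid:
    """Train-synthetic-test-real grid.

    For each (generator, classifier) cell: a_r is test accuracy after
    training on the real training embedding, a_s after training on that
    generator's synthetic embedding, R = a_s / a_r; all three evaluated on
    the same real held-out test embedding.
    """
    grid = ExperimentGrid()
    real_classes = set(np.unique(real_train.labels))
    for name, syn in syn_sets.items():
        if set(np.unique(syn.labels)) != real_classes:
            raise ValueError(f"synthetic set {name!r} is missing classes present in real data")
    for spec in specs:
        base = train_classifier(spec, real_train, real_train.labels)
        a_r = accuracy(base, real_test, real_test.labels)
        for name, syn in syn_sets.items():
            model = train_classifier(spec, syn, syn.labels)
            a_s = accuracy(model, real_test, real_test.labels)
            grid.cells[(name, spec.architecture)] = GridCell(
                a_r=a_r, a_s=a_s, recovery=recovery_rate(a_r, a_s), seed=spec.seed
            )
    return grid


def _stratified_subsample(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    idx: list[int] = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        k = int(round(fraction * len(members)))
        if k < 2:
            raise ValueError(f"fraction {fraction} leaves <2 samples for class {c}")
        idx.extend(rng.choice(members, size=k, replace=False))
    return np.sort(np.array(idx))


def augmentation_experiment(
    real_train: GeneEmbedding,
    fractions: list[float],
    syn_set: GeneEmbedding,
    spec: ClassifierSpec,
    real_test: GeneEmbedding,
    seed: int = 0,
):
    """Accuracy with an f-fraction of real data, alone vs topped up with
    synthetic samples to the full real training size (stratified, seeded)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_full = real_train.n_samples
    rows = []
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("fractions must lie in (0, 1]")
        sub_idx = (
            np.arange(n_full) if f >= 1.0 else _stratified_subsample(real_train.labels, f, rng)
        )
        sub = real_train.subset(sub_idx)
        model = train_classifier(spec, sub, sub.labels)
        acc_alone = accuracy(model, real_test, real_test.labels)

        n_top = n_full - sub.n_samples
        if n_top > 0:
            if syn_set.n_samples < n_top:
                raise ValueError("synthetic set too small to top up to full training size")
            top_idx = rng.choice(syn_set.n_samples, size=n_top, replace=False)
            X_aug = np.concatenate([sub.tensor, syn_set.tensor[top_idx]], axis=0)
            y_aug = np.concatenate([sub.labels, syn_set.labels[top_idx]])
            model_aug = train_classifier(spec, X_aug, y_aug)
            acc_aug = accuracy(model_aug, real_test, real_test.labels)
        else:
            acc_aug = acc_alone
        rows.append(
            {
                "fraction": f,
                "n_real": sub.n_samples,
                "accuracy_real_only": acc_alone,
                "accuracy_augmented": acc_aug,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
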