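"""Quality and privacy metrics for synthetic cohorts.

Nearest-neighbour adversarial accuracy (NNAA) asks how often a point's
nearest neighbour in the *other* set is farther than its nearest neighbour
in its *own* set (excluding itself):

    AA_truth = (1/n) sum_i 1( d_truth,syn(i) > d_truth,truth(i) )
    AA_syn   = (1/n) sum_i 1( d_syn,truth(i) > d_syn,syn(i) )

Both near 0.5 means the metric cannot tell the sets apart; values near 0
signal copying/overfitting, near 1 underfitting. Privacy loss is the
difference of AA_truth computed against the generator's training split and
against a held-out split:

    PrivacyLoss = AA_truth(train, syn) - AA_truth(test, syn)

The recovery rate R = a_s / a_r compares test accuracy of a classifier
trained on synthetic data with one trained on real data (train-synthetic,
test-real). The duplicate audit reports minimum L1/L2/cosine cross-set
distances and counts near-exact copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

_METRICS = {"l1": "cityblock", "l2": "euclidean", "cosine": "cosine"}


def _pairwise(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}")
    if metric == "cosine":
        # define distance 1 for zero-norm inputs instead of nan
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (a @ b.T) / np.outer(na, nb)
        sim[~np.isfinite(sim)] = 0.0
        return 1.0 - sim
    return cdist(a, b, metric=_METRICS[metric])


@dataclass
class NNAAReport:
    aa_truth: float
    aa_syn: float
    metric: str
    n_truth: int
    n_syn: int
    seed: int | None = None

    @property
    def mean_aa(self) -> float:
        return 0.5 * (self.aa_truth + self.aa_syn)


def _subsample_pair(
    truth: np.ndarray, syn: np.ndarray, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-size subsets (without replacement) when set sizes differ."""
    if len(truth) == len(syn):
        return truth, syn
    rng = np.random.default_rng(seed)
    m = min(len(truth), len(syn))
    if len(truth) > m:
        truth = truth[rng.choice(len(truth), size=m, replace=False)]
    else:
        syn = syn[rng.choice(len(syn), size=m, replace=False)]
    return truth, syn


def adversarial_accuracy(
    truth: np.ndarray, syn: np.ndarray, metric: str = "l2", seed: int | None = None
) -> NNAAReport:
    """NNAA between a truth set and a synthetic set.

    Within-set nearest neighbours exclude the point itself; the indicator is
    a strict inequality, so exact distance ties count as 0. If the sets
    differ in size the larger is subsampled to match (seeded).
    """
    truth = np.asarray(truth, dtype=np.float64)
    syn = np.asarray(syn, dtype=np.float64)
    if truth.ndim != 2 or syn.ndim != 2 or truth.shape[1] != syn.shape[1]:
        raise ValueError(
            f"point sets must be 2-D with equal dimensionality; got {truth.shape} and {syn.shape}"
        )
    if len(truth) < 2 or len(syn) < 2:
        raise ValueError("each set needs at least 2 points")
    truth, syn = _subsample_pair(truth, syn, seed)

    cross = _pairwise(truth, syn, metric)  # (n_truth, n_syn)
    within_t = _pairwise(truth, truth, metric)
    np.fill_diagonal(within_t, np.inf)
    within_s = _pairwise(syn, syn, metric)
    np.fill_diagonal(within_s, np.inf)

    d_ts = cross.min(axis=1)
    d_tt = within_t.min(axis=1)
    d_st = cross.min(axis=0)
    d_ss = within_s.min(axis=1)
    return NNAAReport(
        aa_truth=float(np.mean(d_ts > d_tt)),
        aa_syn=float(np.mean(d_st > d_ss)),
        metric=metric,
        n_truth=len(truth),
        n_syn=len(syn),
        seed=seed,
    )


@dataclass
class PrivacyLossReport:
    privacy_loss: float          # AA_truth(train, syn) - AA_truth(test, syn)
    privacy_loss_mean_aa: float  # secondary: difference of (AA_truth + AA_syn)/2
    train_report: NNAAReport
    test_report: NNAAReport


def privacy_loss(
    train_truth: np.ndarray,
    test_truth: np.ndarray,
    syn: np.ndarray,
    metric: str = "l2",
    seed: int | None = None,
) -> PrivacyLossReport:
    """Privacy loss from one synthetic set against train and held-out truth.

    Large positive values mean synthetic points sit closer to the training
    split than to unseen data — evidence of memorization. The mean-AA variant
    is reported as a secondary diagnostic only.
    """
    rep_tr = adversarial_accuracy(train_truth, syn, metric=metric, seed=seed)
    rep_te = adversarial_accuracy(test_truth, syn, metric=metric, seed=seed)
    return PrivacyLossReport(
        privacy_loss=rep_tr.aa_truth - rep_te.aa_truth,
        privacy_loss_mean_aa=rep_tr.mean_aa - rep_te.mean_aa,
        train_report=rep_tr,
        test_report=rep_te,
    )


def recovery_rate(a_r: float, a_s: float) -> float:
    """R = a_s / a_r, the fraction of real-data accuracy recovered when
    training on synthetic data. Reported x100 on the percent scale."""
    if a_r <= 0:
        raise ValueError("real-data accuracy a_r must be positive")
    return a_s / a_r


@dataclass
class DuplicateAudit:
    min_distance: dict[str, float]
    argmin_pair: dict[str, tuple[int, int]]
    duplicate_count: int
    tolerance: float


def duplicate_audit(
    real: np.ndarray, syn: np.ndarray, tolerance: float = 1e-6
) -> DuplicateAudit:
    """Minimum cross-set L1/L2/cosine distances and near-copy count.

    The duplicate count is the number of (synthetic, real) pairs with L2
    distance below ``tolerance``; zero confirms no synthetic point reproduces
    a real one.
    """
    real = np.asarray(real, dtype=np.float64)
    syn = np.asarray(syn, dtype=np.float64)
    if real.size == 0 or syn.size == 0:
        raise ValueError("point sets must be non-empty")
    if real.ndim != 2 or syn.ndim != 2 or real.shape[1] != syn.shape[1]:
        raise ValueError("point sets must be 2-D with equal dimensionality")
    min_d: dict[str, float] = {}
    arg: dict[str, tuple[int, int]] = {}
    l2 = None
    for name in ("l1", "l2", "cosine"):
        d = _pairwise(syn, real, name)
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        min_d[name] = float(d[i, j])
        arg[name] = (int(i), int(j))
        if name == "l2":
            l2 = d
    return DuplicateAudit(
        min_distance=min_d,
        argmin_pair=arg,
        duplicate_count=int((l2 < tolerance).sum()),
        tolerance=tolerance,
    )
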