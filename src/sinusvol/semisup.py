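"""Semi-supervised self-training with confidence-filtered pseudo-labels
and a mixture-model loss split.

The procedure: train on the labelled pool (warm-up); then, per round,
(1) predict the unlabelled self-training pool and keep each pixel's
argmax class as its pseudo-label wherever the maximum class probability
clears a confidence threshold τ (other pixels are ignored); (2) model
the per-slice loss distribution of the combined pool with a
two-component Gaussian mixture fit by EM and keep the lower-loss
("clean") component; (3) retrain on labelled slices plus clean
pseudo-labelled slices, the noisy remainder contributing only an
optional entropy-minimisation term.  Hard pseudo-labels already push
predicted distributions toward low entropy, so the explicit entropy
weight defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn, segnet
from .segnet import SegModel, TrainConfig

__all__ = [
    "DataSplit",
    "PseudoLabelSet",
    "LossPartition",
    "TrainState",
    "make_split",
    "pseudo_label",
    "entropy_term",
    "fit_loss_mixture",
    "self_train",
]


@dataclass(frozen=True)
class DataSplit:
    """Disjoint subject-id pools for the study design."""

    labeled_train: tuple[str, ...]
    labeled_val: tuple[str, ...]
    unlabeled_selftrain: tuple[str, ...]
    unlabeled_test: tuple[str, ...]

    def __post_init__(self):
        pools = [self.labeled_train, self.labeled_val,
                 self.unlabeled_selftrain, self.unlabeled_test]
        flat = [i for p in pools for i in p]
        if len(flat) != len(set(flat)):
            raise ValueError("split pools are not pairwise disjoint")


def make_split(labeled_ids, unlabeled_ids, labeled_ratio: float = 0.8,
               selftrain_fraction: float = 0.2, seed: int = 0) -> DataSplit:
    """Randomly partition subject ids into the four pools.

    The labelled pool splits ``floor(ratio*n)`` train / remainder
    validation; ``floor(fraction*m)`` of the unlabelled pool goes to
    self-training, the rest to test.  Deterministic under ``seed``.
    """
    labeled_ids = list(labeled_ids)
    unlabeled_ids = list(unlabeled_ids)
    if not labeled_ids:
        raise ValueError("labelled pool is empty")
    if not 0.0 < labeled_ratio < 1.0:
        raise ValueError("labeled_ratio must be in (0,1): both sub-pools "
                         "must be non-empty")
    if not 0.0 <= selftrain_fraction <= 1.0:
        raise ValueError("selftrain_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    lab = [labeled_ids[i] for i in rng.permutation(len(labeled_ids))]
    unl = [unlabeled_ids[i] for i in rng.permutation(len(unlabeled_ids))]
    n_train = int(np.floor(labeled_ratio * len(lab)))
    if n_train == 0 or n_train == len(lab):
        raise ValueError("labelled split leaves an empty pool")
    n_self = int(np.floor(selftrain_fraction * len(unl)))
    return DataSplit(
        labeled_train=tuple(lab[:n_train]),
        labeled_val=tuple(lab[n_train:]),
        unlabeled_selftrain=tuple(unl[:n_self]),
        unlabeled_test=tuple(unl[n_self:]),
    )


@dataclass(frozen=True)
class PseudoLabelSet:
    """Argmax labels with low-confidence pixels masked to -1."""

    labels: np.ndarray  # (N, H, W) int, -1 = ignore
    tau: float
    coverage: float


def pseudo_label(model: SegModel, unlabeled_slices: np.ndarray,
                 tau: float = 0.9, batch_size: int = 32) -> PseudoLabelSet:
    """Pseudo-label slices: per-pixel argmax, retained where the max
    class probability is at least τ."""
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"confidence threshold must be in (0,1], got {tau}")
    was_training = model.training
    model.eval()
    labels = []
    kept = 0
    total = 0
    for i in range(0, len(unlabeled_slices), batch_size):
        logits = model.forward(unlabeled_slices[i:i + batch_size])
        probs = nn.softmax(logits, axis=1)
        arg = probs.argmax(axis=1)
        maxp = probs.max(axis=1)
        keep = maxp >= tau
        labels.append(np.where(keep, arg, -1).astype(np.int64))
        kept += int(keep.sum())
        total += keep.size
    model.train(was_training)
    return PseudoLabelSet(labels=np.concatenate(labels), tau=tau,
                          coverage=kept / max(total, 1))


def entropy_term(prob_maps: np.ndarray) -> float:
    """Mean per-pixel Shannon entropy of class-probability maps."""
    p = np.asarray(prob_maps, dtype=np.float64)
    class_axis = 0 if p.ndim == 3 else 1
    h = -(p * np.log(np.maximum(p, 1e-12))).sum(axis=class_axis)
    return float(h.mean())


def _entropy_grad(logits: np.ndarray):
    """Mean per-pixel entropy and its gradient w.r.t. the logits."""
    p = nn.softmax(logits, axis=1)
    logp = np.log(np.maximum(p, 1e-12))
    h = -(p * logp).sum(axis=1)
    n = h.size
    dlogits = -p * (logp + h[:, None]) / n
    return float(h.mean()), dlogits.astype(logits.dtype)


@dataclass(frozen=True)
class LossPartition:
    """Two-component Gaussian mixture split of per-sample losses."""

    losses: np.ndarray
    means: tuple[float, float]  # (clean, noisy): clean has the lower mean
    variances: tuple[float, float]
    weights: tuple[float, float]
    clean_posterior: np.ndarray
    clean_ids: np.ndarray
    noisy_ids: np.ndarray
    log_likelihoods: np.ndarray  # per-EM-iteration trace


def fit_loss_mixture(per_sample_losses, max_iter: int = 200,
                     tol: float = 1e-6) -> LossPartition:
    """EM fit of a two-component Gaussian mixture to normalised losses.

    Losses are min-max normalised; components initialise at the 25th
    and 75th loss percentiles, so the fit is deterministic.  Samples
    with posterior >= 0.5 under the lower-mean component are clean.
    Identical losses degenerate to a single cluster: all samples clean.
    """
    losses = np.asarray(per_sample_losses, dtype=np.float64)
    if losses.ndim != 1 or len(losses) < 4:
        raise ValueError("need at least 4 per-sample losses")
    span = losses.max() - losses.min()
    all_ids = np.arange(len(losses))
    if span == 0:
        return LossPartition(
            losses=losses, means=(float(losses[0]),) * 2,
            variances=(0.0, 0.0), weights=(1.0, 0.0),
            clean_posterior=np.ones(len(losses)),
            clean_ids=all_ids, noisy_ids=np.array([], dtype=int),
            log_likelihoods=np.array([]))
    x = (losses - losses.min()) / span
    mu = np.percentile(x, [25.0, 75.0])
    var = np.full(2, max(x.var() / 4.0, 1e-4))
    w = np.array([0.5, 0.5])
    lls = []
    resp = None
    for _ in range(max_iter):
        # E step
        log_pdf = (-0.5 * np.log(2 * np.pi * var)[None, :]
                   - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :])
        log_joint = np.log(np.maximum(w, 1e-300))[None, :] + log_pdf
        m = log_joint.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        if lls and abs(ll - lls[-1]) < tol:
            lls.append(ll)
            break
        lls.append(ll)
        # M step
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) \
            / np.maximum(nk, 1e-12)
        var = np.maximum(var, 1e-6)
    clean_comp = int(np.argmin(mu))
    post = resp[:, clean_comp]
    clean = post >= 0.5
    order = np.argsort(mu)
    return LossPartition(
        losses=losses,
        means=(float(mu[order[0]]), float(mu[order[1]])),
        variances=(float(var[order[0]]), float(var[order[1]])),
        weights=(float(w[order[0]]), float(w[order[1]])),
        clean_posterior=post,
        clean_ids=all_ids[clean],
        noisy_ids=all_ids[~clean],
        log_likelihoods=np.array(lls))


@dataclass
class TrainState:
    """Model plus per-round bookkeeping of a self-training run."""

    model: SegModel
    split: DataSplit
    history: list[dict] = field(default_factory=list)


def _pool_arrays(data, ids):
    xs = [data[i][0] for i in ids]
    ys = [data[i][1] for i in ids if data[i][1] is not None]
    x = np.concatenate(xs) if xs else None
    y = np.concatenate(ys) if ys else None
    return x, y


def self_train(
    model: SegModel,
    split: DataSplit,
    data: dict[str, tuple[np.ndarray, np.ndarray | None]],
    rounds: int = 3,
    tau: float = 0.9,
    lambda_entropy: float = 0.0,
    round_cfg: TrainConfig | None = None,
) -> TrainState:
    """Iterated pseudo-label self-training (see module docstring).

    ``data`` maps subject id to ``(X, Y)`` slice arrays; Y may be None
    for unlabelled subjects.  The model must already be warmed up on
    the labelled pool.  Test-pool subjects are never touched.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    cfg = round_cfg or TrainConfig(epochs=4)
    x_lab, y_lab = _pool_arrays(data, split.labeled_train)
    x_val, y_val = _pool_arrays(data, split.labeled_val)
    train_ids = set(split.labeled_train) | set(split.unlabeled_selftrain) \
        | set(split.labeled_val)
    assert not train_ids & set(split.unlabeled_test), \
        "test subjects must never enter training"
    state = TrainState(model=model, split=split)
    x_self = None
    if split.unlabeled_selftrain:
        x_self = np.concatenate([data[i][0] for i in split.unlabeled_selftrain])
    opt = nn.Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    for rnd in range(rounds):
        rec: dict = {"round": rnd}
        if x_self is not None and len(x_self):
            pseudo = pseudo_label(model, x_self, tau)
            rec["coverage"] = pseudo.coverage
            x_pool = np.concatenate([x_lab, x_self])
            y_pool = np.concatenate([y_lab, pseudo.labels])
            losses = segnet.per_sample_losses(model, x_pool, y_pool,
                                              ignore_index=cfg.ignore_index)
            part = fit_loss_mixture(losses)
            n_lab = len(x_lab)
            clean_pseudo = part.clean_ids[part.clean_ids >= n_lab]
            noisy_pseudo = part.noisy_ids[part.noisy_ids >= n_lab]
            rec["n_clean_pseudo"] = int(len(clean_pseudo))
            rec["n_noisy_pseudo"] = int(len(noisy_pseudo))
            rec["mixture_means"] = part.means
            x_train = np.concatenate([x_lab, x_pool[clean_pseudo]])
            y_train = np.concatenate([y_lab, y_pool[clean_pseudo]])
        else:
            x_train, y_train = x_lab, y_lab
            noisy_pseudo = np.array([], dtype=int)
        hist = segnet.train_supervised(
            model, x_train, y_train,
            replace(cfg, seed=cfg.seed + rnd), opt=opt)
        rec["train_loss"] = hist[-1]["train_loss"]
        if lambda_entropy > 0 and len(noisy_pseudo):
            x_noisy = x_pool[noisy_pseudo]
            rng = np.random.default_rng(cfg.seed + 1000 + rnd)
            order = rng.permutation(len(x_noisy))
            model.train(True)
            for i in range(0, len(order), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                if len(idx) < 2:
                    continue
                model.zero_grad()
                logits = model.forward(x_noisy[idx])
                _, dlogits = _entropy_grad(logits)
                model.backward(lambda_entropy * dlogits)
                opt.step()
        if x_val is not None:
            rec["val_dice"] = segnet.mean_foreground_dice(model, x_val, y_val)
        state.history.append(rec)
    return state
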