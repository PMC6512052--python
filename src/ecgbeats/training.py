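"""Dataset splitting and mini-batch Adam training.

The default split plan mirrors the study's per-class training/test counts
on the MIT-BIH beat pool (NSR 10,000/5,000; LBBB 6,025/2,000; RBBB
5,728/1,400; APC 1,870/600; PVC 4,928/1,200).  When a class has fewer
beats than requested — the usual case on synthetic data — both counts are
scaled down proportionally and a warning is recorded.

Optimization is plain Adam (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8,
bias correction on) over shuffled mini-batches of 100 beats for 10 epochs,
with categorical cross-entropy on the softmax output.  Everything is
driven by explicit seeds; a (seed, data, config) triple reproduces
bit-identical trained parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import CLASS_ORDER, ClassLabel
from .inception import NetworkInstance
from .layers import cross_entropy_grad, softmax
from .segmentation import NormalizedBeat

__all__ = ["SplitPlan", "TrainConfig", "make_split", "train", "adam_step"]

#: study per-class (train, test) beat counts
DEFAULT_COUNTS: dict[ClassLabel, tuple[int, int]] = {
    ClassLabel.NSR: (10_000, 5_000),
    ClassLabel.LBBB: (6_025, 2_000),
    ClassLabel.RBBB: (5_728, 1_400),
    ClassLabel.APC: (1_870, 600),
    ClassLabel.PVC: (4_928, 1_200),
}


@dataclass
class SplitPlan:
    """Per-class (train, test) beat counts plus the sampling seed."""

    counts: dict[ClassLabel, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    seed: int = 0


def make_split(
    beats: list[NormalizedBeat], plan: SplitPlan
) -> tuple[list[NormalizedBeat], list[NormalizedBeat]]:
    """Sample disjoint train/test sets per class, without replacement.

    If a class offers fewer beats than ``train + test`` requested, both
    counts are reduced proportionally (floor) to fit availability, and a
    ``UserWarning`` records the reduction.  A class present in the plan but
    absent from ``beats`` is an error.
    """
    rng = np.random.default_rng(plan.seed)
    by_class: dict[ClassLabel, list[NormalizedBeat]] = {c: [] for c in plan.counts}
    for beat in beats:
        if beat.label in by_class:
            by_class[beat.label].append(beat)
    train_set: list[NormalizedBeat] = []
    test_set: list[NormalizedBeat] = []
    for label in CLASS_ORDER:
        if label not in plan.counts:
            continue
        pool = by_class[label]
        if not pool:
            raise ValueError(f"class {label.value} absent from the beat pool")
        n_train, n_test = plan.counts[label]
        available = len(pool)
        if n_train + n_test > available:
            scale = available / (n_train + n_test)
            n_train_new = int(n_train * scale)
            n_test_new = int(n_test * scale)
            warnings.warn(
                f"{label.value}: requested {n_train}+{n_test} beats but only "
                f"{available} available; using {n_train_new}+{n_test_new}",
                UserWarning,
                stacklevel=2,
            )
            n_train, n_test = n_train_new, n_test_new
        order = rng.permutation(available)
        train_set.extend(pool[i] for i in order[:n_train])
        test_set.extend(pool[i] for i in order[n_train : n_train + n_test])
    return train_set, test_set


@dataclass(frozen=True)
class TrainConfig:
    """Adam + mini-batch hyperparameters (study defaults)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 100
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def adam_step(
    param: np.ndarray,
    grad: np.ndarray,
    m: np.ndarray,
    v: np.ndarray,
    t: int,
    config: TrainConfig,
) -> None:
    """One in-place Adam update with bias correction.

    m <- b1 m + (1-b1) g;  v <- b2 v + (1-b2) g^2;
    p <- p - lr * (m / (1-b1^t)) / (sqrt(v / (1-b2^t)) + eps)
    """
    b1, b2 = config.beta1, config.beta2
    m *= b1
    m += (1 - b1) * grad
    v *= b2
    v += (1 - b2) * grad * grad
    m_hat = m / (1 - b1**t)
    v_hat = v / (1 - b2**t)
    param -= config.learning_rate * m_hat / (np.sqrt(v_hat) + config.epsilon)


def _labels_to_indices(beats: list[NormalizedBeat]) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.array([lookup[b.label] for b in beats], dtype=int)


def train(
    model: NetworkInstance,
    train_beats: list[NormalizedBeat],
    config: TrainConfig = TrainConfig(),
) -> tuple[NetworkInstance, list[dict]]:
    """Train in place; returns the model and a per-epoch loss/accuracy trace.

    Each epoch reshuffles with the config seed's stream and sweeps
    mini-batches of ``batch_size`` (final partial batch included).  The
    trace entry per epoch holds the mean mini-batch loss and the
    training-set accuracy at epoch end.
    """
    if not train_beats:
        raise ValueError("empty training set")
    x = np.stack([np.asarray(b.values, dtype=float) for b in train_beats])[:, None, :]
    y = _labels_to_indices(train_beats)
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    grads = model.gradients()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    t = 0
    trace: list[dict] = []
    n = x.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = softmax(model.forward_logits(x[idx]))
            loss, grad_logits = cross_entropy_grad(probs, y[idx])
            model.zero_grad()
            model.backward(grad_logits)
            t += 1
            for p, g, m, v in zip(params, grads, m_state, v_state):
                adam_step(p, g, m, v, t, config)
            losses.append(loss)
        acc = evaluate_accuracy(model, x, y)
        trace.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": acc}
        )
    return model, trace


def evaluate_accuracy(
    model: NetworkInstance, x: np.ndarray, y: np.ndarray, batch_size: int = 500
) -> float:
    """Fraction of beats whose argmax probability matches the label."""
    hits = 0
    for start in range(0, x.shape[0], batch_size):
        probs = model.forward(x[start : start + batch_size])
        hits += int((probs.argmax(axis=1) == y[start : start + batch_size]).sum())
    return hits / x.shape[0]
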