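"""Training loop: Adadelta on cross-entropy + L2, patience-based early stop.

Training stops when the test-set cost shows no improvement greater than
``improvement_tol`` for ``patience`` consecutive epochs, where improvement
at epoch e is cost(e-1) - cost(e).  The rule is exposed as a pure function
of the cost sequence so it can be unit-tested without any learning.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..sampling import PatchSet
from .layers import softmax_cross_entropy
from .network import ConvNet


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001  # Adadelta learning rate eta
    rho: float = 0.9  # Adadelta decay
    l2_weight: float = 1e-4
    batch_size: int = 128
    patience: int = 5
    improvement_tol: float = 1e-3
    train_fraction: float = 0.8
    max_epochs: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingHistory:
    train_cost: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_cost: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = ""

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_cost) + 1),
                "train_cost": self.train_cost,
                "train_accuracy": self.train_accuracy,
                "test_cost": self.test_cost,
                "test_accuracy": self.test_accuracy,
            }
        )


class TrainingDivergedError(RuntimeError):
    def __init__(self, message: str, history: TrainingHistory):
        super().__init__(message)
        self.history = history


def early_stop_epoch(costs, patience: int = 5, tol: float = 1e-3) -> int | None:
    """Apply the patience rule to a test-cost sequence.

    Returns the 1-based epoch after which training stops (the epoch that
    completes the run of ``patience`` consecutive epochs with improvement
    <= tol), or None if the sequence never triggers the rule.  The cost
    before epoch 1 is taken as +inf, so with tol = inf the rule fires after
    exactly ``patience`` epochs.
    """
    run = 0
    prev = np.inf
    for epoch, cost in enumerate(costs, start=1):
        if prev - cost > tol:
            run = 0
        else:
            run += 1
        if run >= patience:
            return epoch
        prev = cost
    return None


def split_discovery(
    patchset: PatchSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PatchSet, PatchSet]:
    """Disjoint, exhaustive, label-stratified train/test split of a PatchSet."""
    if len(patchset) == 0:
        raise ValueError("cannot split an empty PatchSet")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx = []
    test_idx = []
    for label in np.unique(patchset.labels):
        idx = np.flatnonzero(patchset.labels == label)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return patchset.subset(train_idx), patchset.subset(test_idx)


def _evaluate(model: ConvNet, patchset: PatchSet, batch: int) -> tuple[float, float]:
    """Dropout-free cross-entropy and accuracy over a PatchSet."""
    probs = model.predict_proba(patchset.patches, batch=batch)
    labels = patchset.labels.astype(int)
    eps = 1e-12
    cost = float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean())
    acc = float((probs.argmax(axis=1) == labels).mean())
    return cost, acc


def train(
    model: ConvNet,
    train_set: PatchSet,
    test_set: PatchSet,
    config: TrainConfig | None = None,
) -> tuple[ConvNet, TrainingHistory]:
    """Fit the classifier; returns the model and its training history."""
    config = config or TrainConfig()
    config.validate()
    for name, ps in (("train", train_set), ("test", test_set)):
        if len(ps) == 0:
            raise ValueError(f"{name} set is empty")
        if len(np.unique(ps.labels)) < 2:
            raise ValueError(f"{name} set must contain both classes")

    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(lr=config.lr, rho=config.rho)
    history = TrainingHistory()
    x_train = train_set.patches
    y_train = train_set.labels.astype(int)
    n = len(x_train)

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        batch_losses = []
        batch_hits = 0
        for lo in range(0, n, config.batch_size):
            sel = perm[lo : lo + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.forward(xb, train=True, rng=rng)
            loss, probs, dlogits = softmax_cross_entropy(logits, yb)
            if config.l2_weight > 0:
                loss += config.l2_weight * sum(
                    float((w.astype(np.float64) ** 2).sum()) for w, _ in model.l2_params()
                )
            model.backward(dlogits)
            if config.l2_weight > 0:
                for w, gw in model.l2_params():
                    gw += 2.0 * config.l2_weight * w
            opt.step(model.grads())
            batch_losses.append(loss)
            batch_hits += int((probs.argmax(axis=1) == yb).sum())

        train_cost = float(np.mean(batch_losses))
        train_acc = batch_hits / n
        test_cost, test_acc = _evaluate(model, test_set, config.batch_size)
        history.train_cost.append(train_cost)
        history.train_accuracy.append(train_acc)
        history.test_cost.append(test_cost)
        history.test_accuracy.append(test_acc)

        if not (np.isfinite(train_cost) and np.isfinite(test_cost)):
            history.stopped_epoch = epoch
            history.stop_reason = "diverged"
            raise TrainingDivergedError(
                f"non-finite cost at epoch {epoch}", history
            )

        stop = early_stop_epoch(
            history.test_cost, patience=config.patience, tol=config.improvement_tol
        )
        if stop is not None:
            history.stopped_epoch = stop
            history.stop_reason = "patience"
            break
    else:
        history.stopped_epoch = config.max_epochs
        history.stop_reason = "max_epochs"

    return model, history
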