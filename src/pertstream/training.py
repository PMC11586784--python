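"""Condition-level data splitting and the training loop.

Splitting is by perturbation condition, never by cell, so "unseen
perturbation" is well defined: a test condition is tagged by how many of
its constituent genes appear in any training condition (e.g. "0/2 unseen"
for a two-gene condition whose genes were both trained on as part of some
condition).  Control cells are not a condition; they are available to every
split as model inputs.

Training pairs each perturbed cell with a control cell drawn at random
(with replacement, re-drawn every epoch from the epoch's seeded stream) as
the model input; control cells themselves enter batches with an empty
perturbation set so the VAE stream also sees unperturbed data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PerturbDataset, parse_condition
from .losses import LossWeights, autofocus_loss, direction_loss, kl_loss, total_loss
from .model import DualStreamModel
from .nn import Adam, StepLR, clip_grad_norm

__all__ = ["SplitSpec", "SplitAssignment", "split_conditions", "train", "TrainResult"]

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train: float = 0.70
    val: float = 0.20
    test: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not math.isclose(self.train + self.val + self.test, 1.0, abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split fractions must be non-negative")


@dataclass
class SplitAssignment:
    assignment: dict  # condition name -> "train" | "val" | "test"
    unseen_tags: dict  # test condition name -> "k/z unseen"

    def conditions(self, split: str) -> list:
        return sorted(c for c, s in self.assignment.items() if s == split)


def split_conditions(dataset: PerturbDataset, spec: SplitSpec) -> SplitAssignment:
    """Assign each non-control condition to train/val/test by seeded shuffle.

    Counts are floors of the fractions with the remainder going to train.
    Test conditions get an unseen tag counting constituent genes absent
    from every training condition.
    """
    conditions = dataset.conditions()
    n = len(conditions)
    if n < 3:
        raise ValueError(f"need at least 3 non-control conditions, got {n}")
    n_train = int(np.floor(spec.train * n))
    n_val = int(np.floor(spec.val * n))
    n_test = int(np.floor(spec.test * n))
    n_train += n - (n_train + n_val + n_test)

    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [conditions[i] for i in order]
    assignment = {}
    for c in shuffled[:n_train]:
        assignment[c] = "train"
    for c in shuffled[n_train:n_train + n_val]:
        assignment[c] = "val"
    for c in shuffled[n_train + n_val:]:
        assignment[c] = "test"

    train_genes: set = set()
    for c, s in assignment.items():
        if s == "train":
            train_genes |= parse_condition(c)
    unseen_tags = {}
    for c, s in assignment.items():
        if s != "test":
            continue
        genes = parse_condition(c)
        unseen = sum(1 for g in genes if g not in train_genes)
        unseen_tags[c] = f"{unseen}/{len(genes)} unseen"
    return SplitAssignment(assignment=assignment, unseen_tags=unseen_tags)


def _stratified_order(cells: np.ndarray, cond_names: list, rng: np.random.Generator) -> np.ndarray:
    """Condition-stratified cell order: shuffle within each condition, then
    interleave round-robin so every batch sees every condition."""
    by_cond: dict[str, list] = {}
    for i in cells:
        by_cond.setdefault(cond_names[i], []).append(i)
    queues = [rng.permutation(v) for _, v in sorted(by_cond.items())]
    queues = [queues[i] for i in rng.permutation(len(queues))]
    order = []
    depth = max(len(q) for q in queues)
    for j in range(depth):
        for q in queues:
            if j < len(q):
                order.append(q[j])
    return np.array(order, dtype=np.intp)


@dataclass
class TrainResult:
    model: DualStreamModel
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _cells_of_split(dataset: PerturbDataset, splits: SplitAssignment, split: str) -> np.ndarray:
    wanted = set(splits.conditions(split))
    labels = dataset.condition_labels()
    return np.flatnonzero(np.array([l in wanted for l in labels]))


def _batch_losses(model, x_in, target, perts, names, ctrl_mean, weights, training, rng):
    pred, mu, sigma = model.forward(x_in, perts, training=training, rng=rng)
    groups: dict[str, list] = {}
    for i, name in enumerate(names):
        groups.setdefault(name, []).append(i)
    kl = kl_loss(mu, sigma) if model.config.use_vae else None
    af = autofocus_loss(pred, target, groups, weights.y_exp)
    dr = direction_loss(pred, target, ctrl_mean, groups)
    tot = total_loss(kl, af, dr, weights, use_vae=model.config.use_vae)
    return tot, kl, af, dr


def train(
    model: DualStreamModel,
    dataset: PerturbDataset,
    splits: SplitAssignment,
    weights: LossWeights | None = None,
    epochs: int = 20,
    lr: float = 1e-3,
    weight_decay: float = 5e-4,
    step_size: int = 1,
    gamma: float = 0.5,
    batch_size: int = 64,
    grad_clip: float = 5.0,
    seed: int = 0,
) -> TrainResult:
    """Train with Adam (weight decay as L2) and a step LR schedule that
    multiplies the rate by `gamma` every `step_size` epochs.  Gradients are
    clipped to a global norm of `grad_clip` before each step (the autofocus
    loss has heavy-tailed gradients).  Tracks train and validation losses
    per epoch; the returned model carries the parameters of the best
    (lowest validation loss) epoch.
    """
    if list(model.gene_names) != list(dataset.gene_names):
        raise ValueError("model and dataset gene lists differ")
    weights = weights or LossWeights()

    ctrl_idx = np.flatnonzero(dataset.control_mask())
    ctrl_mean = dataset.control_mean()
    train_cells = np.concatenate([_cells_of_split(dataset, splits, "train"), ctrl_idx])
    val_cells = _cells_of_split(dataset, splits, "val")
    labels = dataset.labels
    cond_names = dataset.condition_labels()

    ss = np.random.SeedSequence(seed)
    rng_epochs, rng_eps, rng_val = [np.random.default_rng(s) for s in ss.spawn(3)]
    # fixed control pairing for validation: stable loss across epochs
    val_ctrl = rng_val.choice(ctrl_idx, size=val_cells.size, replace=True) if val_cells.size else None

    optimizer = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    scheduler = StepLR(optimizer, step_size=step_size, gamma=gamma)

    rows = []
    best_val = np.inf
    best_epoch = 0
    best_state = [a.copy() for a in model.state_arrays()]
    for epoch in range(1, epochs + 1):
        epoch_lr = scheduler.current_lr
        order = _stratified_order(train_cells, cond_names, rng_epochs)
        pairing = rng_epochs.choice(ctrl_idx, size=order.size, replace=True)
        sums = {"total": 0.0, "kl": 0.0, "autofocus": 0.0, "direction": 0.0}
        n_batches = 0
        for start in range(0, order.size, batch_size):
            cells = order[start:start + batch_size]
            ctrls = pairing[start:start + batch_size]
            perts = [labels[i] for i in cells]
            names = [cond_names[i] for i in cells]
            # control cells reconstruct themselves; perturbed cells start
            # from a drawn control cell
            x_in = np.where(
                np.array([len(p) == 0 for p in perts])[:, None],
                dataset.expression[cells],
                dataset.expression[ctrls],
            )
            target = dataset.expression[cells]
            tot, kl, af, dr = _batch_losses(
                model, x_in, target, perts, names, ctrl_mean, weights, True, rng_eps
            )
            if not np.isfinite(tot.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            optimizer.zero_grad()
            tot.backward()
            if grad_clip:
                clip_grad_norm(optimizer.params, grad_clip)
            optimizer.step()
            sums["total"] += float(tot.data)
            sums["kl"] += float(kl.data) if kl is not None else 0.0
            sums["autofocus"] += float(af.data)
            sums["direction"] += dr
            n_batches += 1

        val_loss = np.nan
        if val_cells.size:
            v_sum, v_batches = 0.0, 0
            for start in range(0, val_cells.size, batch_size):
                v_cells = val_cells[start:start + batch_size]
                v_ctrls = val_ctrl[start:start + batch_size]
                v_tot, _, _, _ = _batch_losses(
                    model,
                    dataset.expression[v_ctrls],
                    dataset.expression[v_cells],
                    [labels[i] for i in v_cells],
                    [cond_names[i] for i in v_cells],
                    ctrl_mean,
                    weights,
                    False,
                    None,
                )
                v_sum += float(v_tot.data)
                v_batches += 1
            val_loss = v_sum / v_batches
            model.zero_grad()
        rows.append(
            {
                "epoch": epoch,
                "lr": epoch_lr,
                "train_loss": sums["total"] / n_batches,
                "val_loss": val_loss,
                "kl": sums["kl"] / n_batches,
                "autofocus": sums["autofocus"] / n_batches,
                "direction": sums["direction"] / n_batches,
            }
        )
        logger.info(
            "epoch %d lr=%.2e train=%.4f val=%.4f",
            epoch, epoch_lr, rows[-1]["train_loss"], val_loss,
        )
        if val_cells.size and val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = [a.copy() for a in model.state_arrays()]
        scheduler.step()

    if val_cells.size:
        model.load_state_arrays(best_state)
    else:
        best_epoch, best_val = epochs, rows[-1]["train_loss"]
    return TrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
    )
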