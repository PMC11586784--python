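"""Training losses: KL, autofocus, and direction terms.

The total objective is ``L = L_KL + beta * L_autofocus + lambda * L_direction``.

* ``L_KL`` is the standard non-negative KL divergence of the diagonal
  Gaussian posterior from the unit Gaussian prior, averaged over the batch.
* ``L_autofocus`` raises the per-gene absolute error to the power ``2 + y``
  (y >= 0), automatically up-weighting large errors — i.e. the strongly
  differentially expressed genes — relative to plain MSE (y = 0 recovers
  MSE exactly).  Errors are averaged per gene, per cell, then per
  perturbation group.
* ``L_direction`` penalizes disagreement in the *sign* of the deviation
  from the control mean, ``h = sign(pred - ctrl) - sign(true - ctrl)``,
  squared and group-averaged; it lies in [0, 4] and ignores magnitudes.
  Because sign() has zero derivative almost everywhere the term carries no
  gradient; it acts as a monitored component of the objective.

All three accept either plain arrays (returning floats, for evaluation) or
autodiff tensors (returning tensors, for training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossWeights", "kl_loss", "autofocus_loss", "direction_loss", "total_loss"]

logger = logging.getLogger(__name__)


@dataclass
class LossWeights:
    """beta weights the autofocus term, lam the direction term, y_exp is the
    autofocus exponent increment (error power = 2 + y_exp)."""

    beta: float = 1.0
    lam: float = 0.1
    y_exp: float = 1.0

    def __post_init__(self):
        if self.beta < 0 or self.lam < 0 or self.y_exp < 0:
            raise ValueError("loss weights must be non-negative")


def _group_weights(condition_groups, n_cells: int) -> np.ndarray:
    """Per-cell weights realizing mean-over-groups of mean-over-cells."""
    if condition_groups is None:
        condition_groups = {"all": np.arange(n_cells)}
    groups = [np.asarray(idx, dtype=np.intp) for idx in dict(condition_groups).values()]
    nonempty = [g for g in groups if g.size > 0]
    if len(nonempty) < len(groups):
        logger.warning("skipping %d empty condition group(s)", len(groups) - len(nonempty))
    if not nonempty:
        raise ValueError("no non-empty condition groups")
    w = np.zeros(n_cells)
    for g in nonempty:
        w[g] += 1.0 / (len(nonempty) * g.size)
    return w


def kl_loss(mu, sigma):
    """Batch-mean KL( N(mu, sigma^2) || N(0, I) ) = -1/2 sum(1 + log s^2 - mu^2 - s^2)."""
    sigma_data = sigma.data if isinstance(sigma, Tensor) else np.asarray(sigma, dtype=float)
    if (sigma_data <= 0).any():
        raise ValueError("sigma must be strictly positive")
    if isinstance(mu, Tensor) and isinstance(sigma, Tensor):
        term = 1.0 + (sigma**2.0).log() - mu**2.0 - sigma**2.0
        return (term.sum(axis=-1) * -0.5).mean()
    mu_data = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma_data = np.atleast_2d(sigma_data)
    per_sample = -0.5 * (1.0 + np.log(sigma_data**2) - mu_data**2 - sigma_data**2).sum(axis=-1)
    return float(per_sample.mean())


def autofocus_loss(pred, true, condition_groups=None, y_exp: float = 1.0):
    """Grouped mean of |pred - true| ** (2 + y_exp); y_exp = 0 is exactly MSE."""
    if y_exp < 0:
        raise ValueError("y_exp must be >= 0")
    is_tensor = isinstance(pred, Tensor)
    true_data = true.data if isinstance(true, Tensor) else np.asarray(true, dtype=float)
    pred_data = pred.data if is_tensor else np.asarray(pred, dtype=float)
    if pred_data.shape != true_data.shape:
        raise ValueError(f"shape mismatch {pred_data.shape} vs {true_data.shape}")
    w = _group_weights(condition_groups, pred_data.shape[0])
    if is_tensor:
        per_cell = ((pred - Tensor(true_data)).abs() ** (2.0 + y_exp)).mean(axis=1)
        return (per_cell * Tensor(w)).sum()
    per_cell = (np.abs(pred_data - true_data) ** (2.0 + y_exp)).mean(axis=1)
    return float(per_cell @ w)


def direction_loss(pred, true, ctrl_mean, condition_groups=None) -> float:
    """Grouped mean of h(u)^2 with h = sign(pred - ctrl) - sign(true - ctrl).

    Three-valued sign; the result lies in [0, 4] and depends only on the
    direction of deviations from the control mean, never their size.
    """
    pred_data = pred.data if isinstance(pred, Tensor) else np.asarray(pred, dtype=float)
    true_data = true.data if isinstance(true, Tensor) else np.asarray(true, dtype=float)
    ctrl = np.asarray(ctrl_mean, dtype=float)
    if pred_data.shape != true_data.shape:
        raise ValueError(f"shape mismatch {pred_data.shape} vs {true_data.shape}")
    h = np.sign(pred_data - ctrl[None, :]) - np.sign(true_data - ctrl[None, :])
    per_cell = (h**2).mean(axis=1)
    w = _group_weights(condition_groups, pred_data.shape[0])
    return float(per_cell @ w)


def total_loss(kl, autofocus, direction, weights: LossWeights, use_vae: bool = True):
    """Weighted sum L = L_KL + beta * L_autofocus + lambda * L_direction;
    the KL term is dropped when the VAE stream is disabled."""
    total = weights.beta * autofocus + weights.lam * direction
    if use_vae and kl is not None:
        total = total + kl
    return total
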