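"""Evaluation metrics and genetic-interaction (GI) scoring.

Per condition, metrics compare predicted and true *mean* expression
profiles against the control mean:

* top-20-DE MSE — squared error of the mean prediction over the 20 genes
  with the largest true |mean shift| from control (DE ranking always comes
  from the true data, never from predictions);
* the fraction of those top-DE genes predicted within ±5% of the true mean;
* the Pearson correlation of predicted versus true mean deltas over all
  genes.

GI scoring regresses the two-gene perturbation's mean delta profile on the
two single-perturbation delta profiles (no intercept) with a robust
Theil–Sen-style estimator — least squares on many random 3-row subsets,
aggregated by the spatial (geometric) median — and summarizes the
coefficients (c1, c2) by the magnitude score sqrt(c1² + c2²).  Ranking
magnitudes flags candidate synergy (top) and suppressor (bottom) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConditionSummary",
    "GIResult",
    "top_de_genes",
    "mse_top_de",
    "fraction_within_tolerance",
    "pearson_delta_corr",
    "theil_sen_fit",
    "magnitude_score",
    "classify_gi",
    "gi_score_correlation",
    "aggregate_mse",
]

logger = logging.getLogger(__name__)


def top_de_genes(true_mean: np.ndarray, ctrl_mean: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k genes with the largest |true_mean - ctrl_mean|.

    Ties break toward the lower gene index; k is truncated to the gene
    count with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    true_mean = np.asarray(true_mean, dtype=float)
    ctrl_mean = np.asarray(ctrl_mean, dtype=float)
    m = true_mean.size
    if k > m:
        logger.warning("k=%d exceeds %d genes; truncating", k, m)
        k = m
    shift = np.abs(true_mean - ctrl_mean)
    # stable sort on (-shift, index): equal shifts keep ascending index order
    order = np.argsort(-shift, kind="stable")
    return order[:k]


@dataclass
class ConditionSummary:
    """Mean-profile summary of one perturbation condition."""

    condition: str
    true_mean: np.ndarray
    pred_mean: np.ndarray
    ctrl_mean: np.ndarray
    k: int = 20
    top_de: np.ndarray = field(init=False)

    def __post_init__(self):
        self.true_mean = np.asarray(self.true_mean, dtype=float)
        self.pred_mean = np.asarray(self.pred_mean, dtype=float)
        self.ctrl_mean = np.asarray(self.ctrl_mean, dtype=float)
        for v in (self.true_mean, self.pred_mean, self.ctrl_mean):
            if not np.isfinite(v).all():
                raise ValueError("non-finite values in condition summary")
        self.top_de = top_de_genes(self.true_mean, self.ctrl_mean, self.k)


def mse_top_de(summary: ConditionSummary) -> float:
    """Mean squared error of predicted vs true mean over the top-DE genes."""
    idx = summary.top_de
    diff = summary.pred_mean[idx] - summary.true_mean[idx]
    return float(np.mean(diff**2))


def fraction_within_tolerance(summary: ConditionSummary, tol: float = 0.05) -> float:
    """Fraction of top-DE genes with |pred - true| <= tol * |true|.

    Genes whose true mean is exactly zero count as hits iff |pred| <= 1e-8.
    """
    idx = summary.top_de
    true = summary.true_mean[idx]
    pred = summary.pred_mean[idx]
    zero = true == 0
    hits = np.where(zero, np.abs(pred) <= 1e-8, np.abs(pred - true) <= tol * np.abs(true))
    return float(hits.mean())


def pearson_delta_corr(summary: ConditionSummary) -> float:
    """Pearson r between predicted and true mean deltas over all genes."""
    pd_ = summary.pred_mean - summary.ctrl_mean
    td = summary.true_mean - summary.ctrl_mean
    if pd_.size < 2:
        raise ValueError("need at least 2 genes")
    if np.ptp(pd_) == 0 or np.ptp(td) == 0:
        logger.warning("constant delta vector; returning 0.0")
        return 0.0
    return float(stats.pearsonr(pd_, td).statistic)


def aggregate_mse(summaries: list, tags: dict | None = None) -> dict:
    """Fig-3-style aggregation: per unseen-tag mean MSE with a normal
    approximation 95% CI (mean ± 1.96 SEM) over conditions."""
    groups: dict[str, list] = {}
    for s in summaries:
        tag = (tags or {}).get(s.condition, "all")
        groups.setdefault(tag, []).append(mse_top_de(s))
    out = {}
    for tag, values in sorted(groups.items()):
        arr = np.array(values)
        sem = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        out[tag] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "ci95": (float(arr.mean() - 1.96 * sem), float(arr.mean() + 1.96 * sem)),
        }
    return out


# --------------------------------------------------------------------------
# Theil–Sen genetic-interaction scoring
# --------------------------------------------------------------------------

def _spatial_median(points: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    x = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - x, axis=1)
        if (d < tol).any():
            return points[d.argmin()]
        w = 1.0 / d
        x_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def theil_sen_fit(
    X: np.ndarray, y: np.ndarray, n_subsets: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Robust no-intercept fit of y ≈ c1*X[:,0] + c2*X[:,1].

    Solves least squares on `n_subsets` seeded random subsets of 3 rows and
    aggregates the per-subset coefficient pairs by their spatial median,
    which resists a minority of gross outliers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"X must be (m, 2), got {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    m = X.shape[0]
    if m < 3:
        raise ValueError("need at least 3 genes (rows)")
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("rank-deficient single-perturbation profiles")
    rng = np.random.default_rng(seed)
    coefs = []
    for _ in range(n_subsets):
        rows = rng.choice(m, size=3, replace=False)
        sub = X[rows]
        if np.linalg.matrix_rank(sub) < 2:
            continue
        beta, *_ = np.linalg.lstsq(sub, y[rows], rcond=None)
        coefs.append(beta)
    if not coefs:
        raise ValueError("all subsets were rank-deficient")
    c1, c2 = _spatial_median(np.array(coefs))
    return float(c1), float(c2)


def magnitude_score(c1: float, c2: float) -> float:
    """Euclidean norm sqrt(c1² + c2²) of the GI regression coefficients."""
    if not (np.isfinite(c1) and np.isfinite(c2)):
        raise ValueError("coefficients must be finite")
    return float(np.hypot(c1, c2))


@dataclass
class GIResult:
    """Theil–Sen coefficients and magnitude for one two-gene condition."""

    condition: str
    c1: float
    c2: float
    magnitude: float = field(init=False)

    def __post_init__(self):
        self.magnitude = magnitude_score(self.c1, self.c2)


def classify_gi(scores: dict, k: int = 20) -> tuple[list, list]:
    """Top-k magnitudes -> candidate synergy, bottom-k -> candidate
    suppressor pairs; ties break by condition name.  k is truncated to
    floor(n/2) with a warning when fewer than 2k conditions are scored."""
    n = len(scores)
    if n < 2 * k:
        k = n // 2
        logger.warning("fewer than 2k conditions; truncating k to %d", k)
    ranked = sorted(scores, key=lambda c: (-scores[c], c))
    synergy = sorted(ranked[:k])
    suppressor = sorted(ranked[n - k:]) if k else []
    return synergy, suppressor


def gi_score_correlation(predicted: dict, truth: dict) -> float:
    """Pearson r between predicted and true magnitude scores over matched
    two-gene conditions."""
    if set(predicted) != set(truth):
        raise ValueError("condition sets differ")
    if len(predicted) < 2:
        raise ValueError("need at least 2 conditions")
    keys = sorted(predicted)
    p = np.array([predicted[c] for c in keys], dtype=float)
    t = np.array([truth[c] for c in keys], dtype=float)
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        logger.warning("constant magnitude vector; returning 0.0")
        return 0.0
    return float(stats.pearsonr(p, t).statistic)
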