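"""End-to-end helpers chaining model predictions into metric tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import PerturbDataset, condition_name, parse_condition
from .evaluation import (
    ConditionSummary,
    GIResult,
    fraction_within_tolerance,
    gi_score_correlation,
    mse_top_de,
    pearson_delta_corr,
    theil_sen_fit,
)
from .model import DualStreamModel

__all__ = [
    "condition_summaries",
    "baseline_summaries",
    "metrics_table",
    "gi_tables",
]

logger = logging.getLogger(__name__)


def condition_summaries(
    model: DualStreamModel,
    dataset: PerturbDataset,
    conditions: list,
    k: int = 20,
    max_ctrl_cells: int = 100,
    seed: int = 0,
) -> list:
    """Predicted/true/control mean-profile summaries for each condition."""
    ctrl_mean = dataset.control_mean()
    out = []
    for cond in conditions:
        pert = parse_condition(cond) if isinstance(cond, str) else frozenset(cond)
        name = condition_name(pert)
        pred_mean = model.predict_condition_mean(
            dataset, pert, max_cells=max_ctrl_cells, seed=seed
        )
        out.append(
            ConditionSummary(
                condition=name,
                true_mean=dataset.condition_mean(name),
                pred_mean=pred_mean,
                ctrl_mean=ctrl_mean,
                k=k,
            )
        )
    return out


def baseline_summaries(dataset: PerturbDataset, conditions: list, k: int = 20) -> list:
    """Summaries for the no-change baseline predictor (control mean)."""
    ctrl_mean = dataset.control_mean()
    return [
        ConditionSummary(
            condition=cond,
            true_mean=dataset.condition_mean(cond),
            pred_mean=ctrl_mean.copy(),
            ctrl_mean=ctrl_mean,
            k=k,
        )
        for cond in conditions
    ]


def metrics_table(summaries: list, tags: dict | None = None) -> pd.DataFrame:
    """Per-condition metric report."""
    tags = tags or {}
    rows = [
        {
            "condition": s.condition,
            "unseen_tag": tags.get(s.condition, ""),
            "mse_top20": mse_top_de(s),
            "frac_within_5pct": fraction_within_tolerance(s),
            "pearson_delta": pearson_delta_corr(s),
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def _delta_design(deltas: dict, pair: frozenset) -> tuple[np.ndarray, list]:
    g1, g2 = sorted(pair)
    return np.column_stack([deltas[g1], deltas[g2]]), [g1, g2]


def gi_tables(
    model: DualStreamModel,
    dataset: PerturbDataset,
    double_conditions: list,
    n_subsets: int = 2000,
    seed: int = 0,
    max_ctrl_cells: int = 100,
) -> tuple[pd.DataFrame, float]:
    """Predicted and ground-truth GI coefficients for two-gene conditions.

    For each pair A+B the double-perturbation mean delta (over control) is
    regressed on the single-perturbation mean deltas — predicted profiles
    from the model, true profiles from the data.  Returns the per-pair
    table and the Pearson correlation between predicted and true magnitude
    scores (NaN when fewer than 2 pairs are scorable).
    """
    ctrl_mean = dataset.control_mean()
    available = set(dataset.conditions())
    pred_single: dict[str, np.ndarray] = {}
    true_single: dict[str, np.ndarray] = {}

    def predicted_delta(pert: frozenset) -> np.ndarray:
        return (
            model.predict_condition_mean(dataset, pert, max_cells=max_ctrl_cells, seed=seed)
            - ctrl_mean
        )

    rows = []
    pred_scores: dict[str, float] = {}
    true_scores: dict[str, float] = {}
    for cond in double_conditions:
        pair = parse_condition(cond) if isinstance(cond, str) else frozenset(cond)
        name = condition_name(pair)
        if len(pair) != 2:
            raise ValueError(f"{name!r} is not a two-gene condition")
        singles = sorted(pair)
        if any(g not in available for g in singles):
            logger.warning("skipping %s: single-perturbation data missing", name)
            continue
        for g in singles:
            if g not in pred_single:
                pred_single[g] = predicted_delta(frozenset({g}))
                true_single[g] = dataset.condition_mean(g) - ctrl_mean
        x_pred, _ = _delta_design(pred_single, pair)
        x_true, _ = _delta_design(true_single, pair)
        y_pred = predicted_delta(pair)
        y_true = dataset.condition_mean(name) - ctrl_mean
        pc1, pc2 = theil_sen_fit(x_pred, y_pred, n_subsets=n_subsets, seed=seed)
        tc1, tc2 = theil_sen_fit(x_true, y_true, n_subsets=n_subsets, seed=seed)
        pred_gi = GIResult(name, pc1, pc2)
        true_gi = GIResult(name, tc1, tc2)
        pred_scores[name] = pred_gi.magnitude
        true_scores[name] = true_gi.magnitude
        rows.append(
            {
                "condition": name,
                "c1": pc1,
                "c2": pc2,
                "magnitude": pred_gi.magnitude,
                "true_c1": tc1,
                "true_c2": tc2,
                "true_magnitude": true_gi.magnitude,
            }
        )
    table = pd.DataFrame(rows)
    pcc = (
        gi_score_correlation(pred_scores, true_scores)
        if len(pred_scores) >= 2
        else float("nan")
    )
    return table, pcc
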