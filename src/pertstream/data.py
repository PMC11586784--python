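"""The in-memory perturbation dataset container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PerturbDataset", "parse_condition", "condition_name", "DataError"]

CTRL = "ctrl"


class DataError(ValueError):
    """Raised for datasets violating the container invariants."""


def parse_condition(label: str) -> frozenset:
    """Parse a condition label: 'ctrl' -> empty set, 'A+B' -> {A, B}."""
    label = label.strip()
    if label == CTRL or label == "":
        return frozenset()
    genes = [g.strip() for g in label.split("+")]
    if any(not g for g in genes):
        raise DataError(f"malformed condition label {label!r}")
    return frozenset(genes)


def condition_name(perturbation: frozenset) -> str:
    """Canonical label of a perturbation set: 'ctrl' or sorted genes joined by '+'."""
    if not perturbation:
        return CTRL
    return "+".join(sorted(perturbation))


@dataclass
class PerturbDataset:
    """Cells x genes expression with per-cell perturbation label sets.

    ``expression`` is a dense non-negative (n_cells, n_genes) array;
    ``labels[i]`` is the (possibly empty) frozenset of gene names perturbed
    in cell i — the empty set marks a control cell.
    """

    expression: np.ndarray
    labels: list
    gene_names: list

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=np.float64)
        self.labels = [frozenset(l) for l in self.labels]
        self.gene_names = list(self.gene_names)
        if self.expression.ndim != 2:
            raise DataError("expression must be 2-D (cells x genes)")
        n, m = self.expression.shape
        if len(self.labels) != n:
            raise DataError(f"{len(self.labels)} labels for {n} cells")
        if len(self.gene_names) != m:
            raise DataError(f"{len(self.gene_names)} gene names for {m} columns")
        if np.isnan(self.expression).any():
            raise DataError("expression contains NaN")
        if (self.expression < 0).any():
            raise DataError("expression contains negative entries")
        known = set(self.gene_names)
        for lab in self.labels:
            unknown = lab - known
            if unknown:
                raise DataError(f"perturbed gene(s) not in gene_names: {sorted(unknown)}")
        if not any(len(l) == 0 for l in self.labels):
            raise DataError("dataset has no control cells")

    # ------------------------------------------------------------------ views
    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def condition_labels(self) -> list:
        """Per-cell canonical condition strings."""
        return [condition_name(l) for l in self.labels]

    def conditions(self, include_control: bool = False) -> list:
        """Sorted unique non-control condition names (plus 'ctrl' on request)."""
        names = sorted({condition_name(l) for l in self.labels if l})
        if include_control:
            names = [CTRL] + names
        return names

    def control_mask(self) -> np.ndarray:
        return np.array([len(l) == 0 for l in self.labels])

    def cells_of(self, condition: str) -> np.ndarray:
        target = parse_condition(condition)
        return np.flatnonzero(np.array([l == target for l in self.labels]))

    def control_mean(self) -> np.ndarray:
        return self.expression[self.control_mask()].mean(axis=0)

    def condition_mean(self, condition: str) -> np.ndarray:
        cells = self.cells_of(condition)
        if cells.size == 0:
            raise KeyError(f"no cells for condition {condition!r}")
        return self.expression[cells].mean(axis=0)

    def equals(self, other: "PerturbDataset") -> bool:
        return (
            self.gene_names == other.gene_names
            and self.labels == other.labels
            and np.array_equal(self.expression, other.expression)
        )
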