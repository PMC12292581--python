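"""Metrics and report arithmetic for noisy class-incremental benchmarks.

Final Average Accuracy (FAA) is the unweighted mean of per-task test
accuracies after the last task has been trained — i.e. the mean of the last
row of the lower-triangular accuracy matrix.  Selection purity is the
percentage of a selected subset whose observed label matches the true label;
``1 - mean purity`` is an *equivalent noise ratio*, and reductions relative
to the injected rates summarise how much of the label noise the filter
removed.

The published benchmark tables ship as versioned fixture CSVs (one file per
table) so that all aggregate numbers can be regression-tested as pure
arithmetic, without any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyMatrix",
    "PurityReport",
    "NoiseReduction",
    "final_average_accuracy",
    "purity",
    "noise_reduction",
    "improvement_summary",
    "load_table",
    "table_improvement",
]


@dataclass
class AccuracyMatrix:
    """Lower-triangular record: rows[t][tau] is the accuracy (percent) on
    task tau's test set after finishing training on task t (tau <= t)."""

    rows: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t, row in enumerate(self.rows):
            if len(row) != t + 1:
                raise ValueError(f"row {t} must have {t + 1} entries, got {len(row)}")
            if any(not (0.0 <= v <= 100.0) for v in row):
                raise ValueError(f"accuracies must be percentages in [0, 100]: {row}")

    def append_row(self, row: list[float]) -> None:
        self.rows.append([float(v) for v in row])
        self.__post_init__()

    @property
    def n_tasks(self) -> int:
        return len(self.rows)

    @property
    def last_row(self) -> list[float]:
        if not self.rows:
            raise ValueError("empty accuracy matrix")
        return self.rows[-1]

    @property
    def faa(self) -> float:
        return final_average_accuracy(self)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_tasks
        grid = np.full((n, n), np.nan)
        for t, row in enumerate(self.rows):
            grid[t, : t + 1] = row
        return pd.DataFrame(grid,
                            index=[f"after_task{t + 1}" for t in range(n)],
                            columns=[f"task{t + 1}" for t in range(n)])


def final_average_accuracy(matrix) -> float:
    """Unweighted mean over the last row of the accuracy matrix (percent)."""
    if isinstance(matrix, AccuracyMatrix):
        row = matrix.last_row
    else:
        rows = list(matrix)
        if not rows:
            raise ValueError("empty accuracy matrix")
        row = rows[-1]
    return float(np.mean(np.asarray(row, dtype=np.float64)))


def purity(selected: np.ndarray, is_clean: np.ndarray) -> float:
    """Percentage of selected samples whose observed label is correct."""
    selected = np.asarray(selected, dtype=bool)
    is_clean = np.asarray(is_clean, dtype=bool)
    if selected.shape != is_clean.shape:
        raise ValueError("mask shape mismatch")
    if not selected.any():
        raise ValueError("empty selection: purity undefined")
    return float(100.0 * is_clean[selected].mean())


@dataclass
class PurityReport:
    """Per-task selection purities (percent) at one injected noise rate."""

    noise_rate: float
    per_task: list[float]

    @property
    def mean_purity(self) -> float:
        return float(np.mean(self.per_task))

    @property
    def equivalent_noise_ratio(self) -> float:
        return float(1.0 - self.mean_purity / 100.0)


@dataclass
class NoiseReduction:
    per_level: list[float]  # percent reduction at each injected rate
    mean: float
    max: float


def noise_reduction(original_rates, equivalent_rates) -> NoiseReduction:
    """Percent reduction 100*(orig - equiv)/orig per level, with mean/max."""
    orig = np.asarray(original_rates, dtype=np.float64)
    equiv = np.asarray(equivalent_rates, dtype=np.float64)
    if orig.shape != equiv.shape:
        raise ValueError("rate list length mismatch")
    if np.any(orig <= 0):
        raise ValueError("original rates must be positive")
    red = 100.0 * (orig - equiv) / orig
    return NoiseReduction(per_level=red.tolist(), mean=float(red.mean()),
                          max=float(red.max()))


def improvement_summary(faa_a, faa_b) -> tuple[float, float]:
    """Mean and max of element-wise FAA(a) - FAA(b) over a shared noise grid."""
    a = np.asarray(faa_a, dtype=np.float64)
    b = np.asarray(faa_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("noise-rate grids do not align")
    d = a - b
    return float(d.mean()), float(d.max())


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged benchmark fixture table, e.g. ``load_table("table2")``."""
    ref = resources.files("dscnl") / "fixtures" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def table_improvement(table: pd.DataFrame, method_a: str, method_b: str
                      ) -> tuple[float, float]:
    """Mean/max FAA improvement of ``method_a`` over ``method_b`` from a
    method-by-noise-rate fixture table (first column = method name)."""
    key = table.columns[0]
    rates = table.columns[1:]
    rows = table.set_index(key)
    if method_a not in rows.index or method_b not in rows.index:
        raise KeyError(f"methods {method_a!r}/{method_b!r} not both in table")
    return improvement_summary(rows.loc[method_a, rates].astype(float).to_numpy(),
                               rows.loc[method_b, rates].astype(float).to_numpy())
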