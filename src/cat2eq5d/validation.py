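"""Predictive-accuracy reporting: MAE/RMSE, subgroup tables, bubble charts.

Metrics are observation-level: every visit counts once, so a patient with
many visits weighs more — matching a validation design that reports N in
observations rather than patients.

Subgroup partitions:

* severity stage 1 / 2 / 3,
* observed-utility bands < 0.25, [0.25, 0.5), [0.5, 0.75), >= 0.75
  (lower-inclusive; the bottom band is open below so states worse than dead
  still land in a band),
* CAT total bands 0-10, 11-20, 21-30, 31-40 (inclusive integer ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

UTILITY_BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("utility < 0.25", -np.inf, 0.25),
    ("0.25 <= utility < 0.5", 0.25, 0.5),
    ("0.5 <= utility < 0.75", 0.5, 0.75),
    ("utility >= 0.75", 0.75, np.inf),
)

CAT_BANDS: Tuple[Tuple[str, int, int], ...] = (
    ("0 <= CAT <= 10", 0, 10),
    ("11 <= CAT <= 20", 11, 20),
    ("21 <= CAT <= 30", 21, 30),
    ("31 <= CAT <= 40", 31, 40),
)

BUBBLE_LO, BUBBLE_HI = -0.7, 1.0


def _paired(pred, actual) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, a


def mae(pred, actual) -> float:
    """Mean absolute error between predicted and observed utilities."""
    p, a = _paired(pred, actual)
    return float(np.mean(np.abs(p - a)))


def rmse(pred, actual) -> float:
    """Root mean squared error between predicted and observed utilities."""
    p, a = _paired(pred, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def pearson_correlation(x, y) -> float:
    """Product-moment correlation (e.g. observed utility vs CAT total)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need at least two pairs of equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class SubgroupRow:
    subgroup: str
    n: int
    mean_pred: float
    min_pred: float
    max_pred: float
    mae: float
    rmse: float


@dataclass
class ValidationReport:
    """Per-subgroup accuracy table (full set, stages, utility and CAT bands)."""

    model: str
    rows: List[SubgroupRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subgroup": r.subgroup,
                    "N": r.n,
                    "mean": r.mean_pred,
                    "min": r.min_pred,
                    "max": r.max_pred,
                    "MAE": r.mae,
                    "RMSE": r.rmse,
                }
                for r in self.rows
            ]
        )

    def row(self, subgroup: str) -> SubgroupRow:
        for r in self.rows:
            if r.subgroup == subgroup:
                return r
        raise KeyError(subgroup)


def _row(name: str, pred: np.ndarray, actual: np.ndarray) -> SubgroupRow:
    if pred.size == 0:
        return SubgroupRow(name, 0, np.nan, np.nan, np.nan, np.nan, np.nan)
    return SubgroupRow(
        subgroup=name,
        n=int(pred.size),
        mean_pred=float(pred.mean()),
        min_pred=float(pred.min()),
        max_pred=float(pred.max()),
        mae=mae(pred, actual),
        rmse=rmse(pred, actual),
    )


def subgroup_report(
    df: pd.DataFrame,
    pred_col: str = "pred_utility",
    actual_col: str = "utility",
    model: Optional[str] = None,
) -> ValidationReport:
    """Accuracy table over the full set and every subgroup partition.

    ``df`` needs the prediction and observed-utility columns plus
    ``cat_total``; stage rows appear when a ``stage`` column is present.
    """
    for col in (pred_col, actual_col, "cat_total"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    if df[actual_col].isna().any():
        raise ValueError("observed utility missing for some observations")
    pred = df[pred_col].to_numpy(dtype=float)
    actual = df[actual_col].to_numpy(dtype=float)
    cat_total = df["cat_total"].to_numpy(dtype=float)

    report = ValidationReport(model=model or str(df.get("model", pd.Series(["?"])).iloc[0]))
    report.rows.append(_row("full", pred, actual))
    if "stage" in df.columns and df["stage"].notna().all():
        stage = df["stage"].to_numpy(dtype=int)
        for s in (1, 2, 3):
            m = stage == s
            report.rows.append(_row(f"stage {s}", pred[m], actual[m]))
    for name, lo, hi in UTILITY_BANDS:
        m = (actual >= lo) & (actual < hi)
        report.rows.append(_row(name, pred[m], actual[m]))
    for name, lo, hi in CAT_BANDS:
        m = (cat_total >= lo) & (cat_total <= hi)
        report.rows.append(_row(name, pred[m], actual[m]))
    return report


@dataclass
class BubbleGrid:
    """Joint histogram of (predicted, observed) utility for bubble charts."""

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray  # (pred_bin, actual_bin)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format nonzero cells: bin centers and counts."""
        centers = (self.edges[:-1] + self.edges[1:]) / 2
        pi, ai = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "pred_center": centers[pi],
                "actual_center": centers[ai],
                "count": self.counts[pi, ai],
            }
        )


def bubble_grid(pred, actual, bin_width: float = 0.05) -> BubbleGrid:
    """Bin paired utilities on [-0.7, 1]: half-open bins, final bin closed.

    The grid's marginal over predicted bins is the histogram of the
    predictions; counts conserve N.
    """
    p, a = _paired(pred, actual)
    if not (np.isfinite(p).all() and np.isfinite(a).all()):
        raise ValueError("non-finite utilities")
    n_bins = int(round((BUBBLE_HI - BUBBLE_LO) / bin_width))
    edges = BUBBLE_LO + bin_width * np.arange(n_bins + 1)

    def index(v: np.ndarray) -> np.ndarray:
        i = np.floor((v - BUBBLE_LO) / bin_width).astype(int)
        return np.clip(i, 0, n_bins - 1)  # top edge closes the final bin

    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (index(p), index(a)), 1)
    return BubbleGrid(bin_width=bin_width, edges=edges, counts=counts)


def plot_bubble_grid(grid: BubbleGrid, ax=None, max_size: float = 600.0):
    """Render a bubble chart (predicted on x, observed on y); returns the axes.

    Plotting is a side effect only; all analysis runs off the counts.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cells = grid.to_frame()
    sizes = max_size * cells["count"] / cells["count"].max()
    ax.scatter(cells["pred_center"], cells["actual_center"], s=sizes, alpha=0.5)
    ax.plot([BUBBLE_LO, BUBBLE_HI], [BUBBLE_LO, BUBBLE_HI], "k--", lw=1)
    ax.set_xlabel("predicted utility")
    ax.set_ylabel("observed utility")
    return ax
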