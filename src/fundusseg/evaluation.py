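"""Segmentation metrics, weighted averaging, error histograms and reports.

The five pixel-overlap metrics are the Jaccard index JI = TP/(TP+FP+FN),
Dice coefficient DC = 2TP/(2TP+FP+FN), sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total. Dataset-level summaries use the
test-image-count weighted average sum(metric_i * n_i) / sum(n_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "SegMetrics", "confusion_counts", "seg_metrics",
    "weighted_average", "ErrorHistogram", "error_histogram", "dataset_report",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(gt_mask: np.ndarray, pred_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two binary masks of the same shape."""
    gt = np.asarray(gt_mask)
    pred = np.asarray(pred_mask)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    gt = gt > 0
    pred = pred > 0
    tp = int(np.count_nonzero(gt & pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    tn = int(np.count_nonzero(~gt & ~pred))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class SegMetrics:
    """The five overlap metrics; None marks an undefined (0/0) metric."""

    ji: float | None
    dc: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def seg_metrics(counts: ConfusionCounts) -> SegMetrics:
    """JI, DC, sensitivity, specificity and accuracy from confusion counts.

    Metrics with a zero denominator (e.g. JI when both masks are empty) are
    reported as None rather than silently coerced to 0 or 1.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    return SegMetrics(
        ji=_ratio(tp, tp + fp + fn),
        dc=_ratio(2 * tp, 2 * tp + fp + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=(tp + tn) / counts.total,
    )


def weighted_average(values, weights) -> float:
    """Image-count weighted mean: sum(v_i * n_i) / sum(n_i)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.size == 0:
        raise ValueError("empty values or weights")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float((values * weights).sum() / weights.sum())


@dataclass
class ErrorHistogram:
    """Fixed-width histogram of nonnegative errors with half-open bins."""

    bin_width: float
    counts: np.ndarray       # per-bin counts, bin k covers [k*w, (k+1)*w)
    n: int

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width

    def cumulative_fraction_below(self, threshold: float) -> float:
        """Fraction of errors strictly below ``threshold`` (a bin boundary)."""
        k = int(round(threshold / self.bin_width))
        return float(self.counts[:k].sum() / self.n)

    def to_frame(self) -> pd.DataFrame:
        cum = np.cumsum(self.counts) / self.n
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "count": self.counts,
            "cum_fraction": cum,
        })


def error_histogram(errors, bin_width: float = 0.01) -> ErrorHistogram:
    """Bin nonnegative errors into half-open bins [k*w, (k+1)*w)."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("no errors to bin")
    if np.any(errors < 0):
        raise ValueError("errors must be nonnegative")
    idx = np.floor(errors / bin_width).astype(int)
    counts = np.bincount(idx, minlength=int(idx.max()) + 1)
    return ErrorHistogram(bin_width=bin_width, counts=counts, n=errors.size)


_ERROR_COLS = ["CDRE", "CDARE", "RDARE", "ADRRE", "ACRRE", "ARRRE"]
_METRIC_COLS = ["JI_disc", "DC_disc", "JI_cup", "DC_cup"]


def dataset_report(records: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group and total mean errors/metrics, one row per group plus "Total".

    ``records`` has one row per image with any subset of the columns CDRE,
    CDARE, RDARE, ADRRE, ACRRE, ARRRE, JI_disc, DC_disc, JI_cup, DC_cup and
    a group label column. Totals are the image-count weighted average of
    the group means (equivalently the grand mean over images).
    """
    if len(records) == 0:
        raise ValueError("no records to report")
    if group_col not in records.columns:
        raise ValueError(f"missing group column {group_col!r}")
    cols = [c for c in _ERROR_COLS + _METRIC_COLS if c in records.columns]
    grouped = records.groupby(group_col, sort=True)
    table = grouped[cols].mean()
    table.insert(0, "n", grouped.size())
    total = {"n": int(table["n"].sum())}
    for c in cols:
        total[c] = weighted_average(table[c].to_numpy(), table["n"].to_numpy())
    table.loc["Total"] = pd.Series(total)
    table["n"] = table["n"].astype(int)
    table.index.name = group_col
    return table
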