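"""Aggregation into ROI-wise / filewise tables and Pearson correlation.

Per-pair metric records (one row per scan x augmentation x ROI) are
aggregated to one row per ROI or per file, and the resulting metric
columns are correlated pairwise with Pearson's r.  Significance is a
two-tailed Student t-test on ``t = r * sqrt((n-2) / (1-r^2))`` with
``n - 2`` degrees of freedom.  Missing cells (an ROI absent from some
files) are handled by pairwise-complete deletion; p-values are reported
raw, without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "CorrelationMatrices",
    "pearson",
    "correlation_matrix",
    "aggregate",
    "plot_correlation_heatmap",
]

# aggregation rules: these columns are summed (counts), the rest averaged
_SUM_COLUMNS = {"type1", "type2", "total_errors"}


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson(x, y) -> CorrelationResult | None:
    """Pearson correlation with a two-tailed t-test p-value.

    NaN pairs are dropped (pairwise-complete).  Returns None (recorded as
    missing) when fewer than 3 complete pairs remain or either vector is
    constant, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(n), p=float(p))


@dataclass(frozen=True)
class CorrelationMatrices:
    """Symmetric pairwise r / p / n tables with a unit diagonal in r."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(table: pd.DataFrame, columns=None) -> CorrelationMatrices:
    """All pairwise Pearson correlations between metric columns.

    Entirely-missing or constant columns are excluded.  Missing cells use
    pairwise-complete deletion, so n can differ between pairs.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    usable = []
    for c in columns:
        col = table[c].to_numpy(dtype=float)
        if np.isnan(col).all():
            continue
        usable.append(c)
    k = len(usable)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(table[usable[i]].notna().sum())
        for j in range(i + 1, k):
            res = pearson(table[usable[i]], table[usable[j]])
            if res is not None:
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p
                n[i, j] = n[j, i] = res.n
    idx = pd.Index(usable)
    return CorrelationMatrices(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def aggregate(records: pd.DataFrame, by: str) -> pd.DataFrame:
    """Aggregate tidy per-pair records ROI-wise or filewise.

    ``by="roi"`` groups on ``roi_id``; ``by="file"`` groups on ``scan_id``.
    Numeric metric columns are averaged (error counts summed); an
    ``appearance_frequency`` column counts the distinct files in which the
    grouping unit appears.  Missing cells stay NaN.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    key = {"roi": "roi_id", "file": "scan_id"}.get(by)
    if key is None:
        raise ValueError('by must be "roi" or "file"')
    if key not in records.columns:
        raise ValueError(f"records lack a {key!r} column")
    grouped = records.groupby(key)
    out = {}
    for col in records.columns:
        if col in (key, "scan_id", "roi_id", "aug_index", "comparison"):
            continue
        if not pd.api.types.is_numeric_dtype(records[col]):
            continue
        if col in _SUM_COLUMNS:
            out[col] = grouped[col].sum()
        else:
            out[col] = grouped[col].mean()
    table = pd.DataFrame(out)
    if "scan_id" in records.columns and key != "scan_id":
        table["appearance_frequency"] = grouped["scan_id"].nunique()
    table.index.name = key
    return table


def plot_correlation_heatmap(r: pd.DataFrame, path=None, ax=None,
                             annotate: bool = True):
    """Render an annotated correlation heatmap (matplotlib Axes returned)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(r), 1.0 + 0.8 * len(r)))
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    if annotate:
        for i in range(len(r.index)):
            for j in range(len(r.columns)):
                v = r.iat[i, j]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                            fontsize=8)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
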