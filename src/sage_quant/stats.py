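"""Cohort-level statistics on per-lesion metric tables.

Lesion records hold ROI *medians* of the quantitative maps; the battery
mirrors a typical small-cohort imaging-biomarker analysis: Pearson
correlations (with R^2 and two-sided t-test p-values), Mann-Whitney U group
comparisons (exact for small samples), proliferation-index (Ki67)
binarization at 10 %, and ROC analysis with either a fixed operating cutoff
(e.g. TRATE > 142 mM^-1 s^-1) or the Youden-optimal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

METRIC_COLUMNS = (
    "trate", "delta_r1_ss", "delta_r2star_ss", "psr", "nrcbv", "ktrans", "ve",
)

KI67_CUTOFF = 10.0  # percent; binarized as <= 10 vs > 10
EXACT_MW_LIMIT = 20  # exact U enumeration when n_a + n_b <= this


def extract_roi_medians(
    maps: dict[str, np.ndarray], mask: np.ndarray
) -> dict[str, float]:
    """Median of each map over the mask voxels, NaNs dropped."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    out: dict[str, float] = {}
    for name, vol in maps.items():
        vals = np.asarray(vol, dtype=float)[mask]
        vals = vals[np.isfinite(vals)]
        out[name] = float(np.median(vals)) if vals.size else float("nan")
    return out


def binarize_ki67(ki67: float | np.ndarray, cutoff: float = KI67_CUTOFF):
    """True for Ki67 > cutoff (high proliferation); NaN stays NaN."""
    arr = np.asarray(ki67, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr > cutoff).astype(float))
    return out if out.ndim else bool(out) if not np.isnan(out) else float("nan")


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int


def pairwise_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with R^2 and two-sided p (t-distribution, n-2 df).

    Pairs with any non-finite value are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n=x.size)


@dataclass
class GroupCompareResult:
    u: float
    p: float
    n_a: int
    n_b: int
    method: str  # exact | asymptotic


def group_compare(values_a, values_b) -> GroupCompareResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration for combined n <= 20 (falls back to the
    tie-corrected normal approximation when ties make the exact distribution
    invalid); normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size + b.size <= EXACT_MW_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return GroupCompareResult(
        u=float(res.statistic), p=float(res.pvalue), n_a=a.size, n_b=b.size,
        method="exact" if exact else "asymptotic",
    )


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    cutoff_source: str  # fixed | youden
    curve: pd.DataFrame  # columns: threshold, fpr, tpr


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) statistic, tie-aware."""
    ranks = sps.rankdata(values)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_analysis(values, labels, fixed_cutoff: float | None = None) -> RocResult:
    """ROC of a metric against binary labels; positive when metric > cutoff.

    AUC comes from the rank statistic (equal to the trapezoidal area under
    the empirical ROC). With ``fixed_cutoff`` the operating point is
    evaluated there; otherwise the Youden-optimal cutoff (max TPR - FPR) is
    reported.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    auc = _rank_auc(values, labels)

    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1], [-np.inf]])
    tpr = np.array([(values[labels] > t).mean() for t in thresholds])
    fpr = np.array([(values[~labels] > t).mean() for t in thresholds])
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    if fixed_cutoff is not None:
        c = float(fixed_cutoff)
        source = "fixed"
    else:
        youden = tpr - fpr
        c = float(thresholds[int(np.argmax(youden))])
        source = "youden"
    sens = float((values[labels] > c).mean())
    spec = float((values[~labels] <= c).mean())
    return RocResult(
        auc=auc, cutoff=c, sensitivity=sens, specificity=spec,
        cutoff_source=source, curve=curve,
    )


def cohort_report(
    table: pd.DataFrame,
    metric_pairs: list[tuple[str, str]] | None = None,
    group_column: str | None = None,
    roc_metric: str = "trate",
    roc_label_column: str | None = None,
    fixed_cutoff: float | None = 142.0,
) -> dict:
    """Run the full battery on a lesion-record table.

    Returns a dict with 'correlations', 'group_tests' and 'roc' entries;
    missing columns are skipped silently so partial tables work.
    """
    out: dict = {"correlations": {}, "group_tests": {}, "roc": None}
    metrics = [m for m in METRIC_COLUMNS if m in table.columns]
    if metric_pairs is None:
        metric_pairs = [
            (a, b) for i, a in enumerate(metrics) for b in metrics[i + 1 :]
        ]
    for a, b in metric_pairs:
        try:
            out["correlations"][f"{a}~{b}"] = pairwise_correlation(table[a], table[b])
        except ValueError:
            continue
    if group_column and group_column in table.columns:
        groups = table[group_column].dropna().unique()
        if len(groups) == 2:
            ga = table[table[group_column] == groups[0]]
            gb = table[table[group_column] == groups[1]]
            for m in metrics:
                try:
                    out["group_tests"][m] = group_compare(ga[m], gb[m])
                except ValueError:
                    continue
    if roc_label_column and roc_label_column in table.columns and roc_metric in table.columns:
        sub = table.dropna(subset=[roc_metric, roc_label_column])
        try:
            out["roc"] = roc_analysis(
                sub[roc_metric], sub[roc_label_column].astype(bool),
                fixed_cutoff=fixed_cutoff,
            )
        except ValueError:
            pass
    return out
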