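"""Summaries and comparisons of per-sub-ensemble dissociation constants.

Box-plot statistics follow the common linear-interpolation quantile rule
("type 7"), whiskers extend to the most extreme data within 1.5 IQR of the
box, and between-class significance defaults to Welch's two-sample t-test on
log10-transformed K_D values (dissociation constants are log-scale
quantities and the compared groups are small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["BoxplotSummary", "ComparisonResult", "boxplot_summary", "compare_subensembles"]


@dataclass
class BoxplotSummary:
    """Five-number summary plus mean and outliers, in the input's units."""

    q1: float
    median: float
    q3: float
    mean: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


@dataclass
class ComparisonResult:
    """Two-group comparison: test statistic, p-value and best-K_D fold change."""

    statistic: float
    p_value: float
    fold_change: float   # best_kd(B) / best_kd(A), A the putatively better binder
    n_a: int
    n_b: int
    method: str


def boxplot_summary(values, scale: str = "linear") -> BoxplotSummary:
    """Box-plot statistics of positive values, on a linear or log10 scale.

    With ``scale="log10"`` all statistics are computed and reported in log10
    units.  Quartiles use linear interpolation; points beyond
    ``[q1 - 1.5 IQR, q3 + 1.5 IQR]`` are outliers and whiskers stop at the
    most extreme non-outlying datum.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if scale == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 scale requires strictly positive values")
        x = np.log10(x)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation ("type 7")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    return BoxplotSummary(float(q1), float(med), float(q3), float(x.mean()),
                          float(inside.min()), float(inside.max()), outliers)


def compare_subensembles(kds_a, kds_b, method: str = "welch_t_log10") -> ComparisonResult:
    """Compare two groups of dissociation constants.

    ``kds_a`` is the putatively better binder: the fold change is
    ``min(kds_b) / min(kds_a)``, so values above 1 mean group A achieves the
    lower (tighter) best K_D.

    Methods: ``welch_t_log10`` (Welch's two-sided t-test on log10 K_D,
    default) or ``mann_whitney`` (two-sided rank test).  Two identical
    zero-variance groups return p = 1 by convention.
    """
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("dissociation constants must be positive")
    la, lb = np.log10(a), np.log10(b)
    if method == "welch_t_log10":
        if la.std() == 0 and lb.std() == 0:
            stat, p = (0.0, 1.0) if la.mean() == lb.mean() else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_ind(la, lb, equal_var=False)
    elif method == "mann_whitney":
        if np.array_equal(np.sort(la), np.sort(lb)) and la.std() == 0:
            stat, p = float(len(a) * len(b)) / 2, 1.0
        else:
            stat, p = sps.mannwhitneyu(la, lb, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(float(stat), float(p), float(b.min() / a.min()),
                            len(a), len(b), method)
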