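"""Paired-comparison statistics for excitability features.

Follows the conventional decision rule for small electrophysiology
cohorts: paired t-test when the paired differences look normal and n >= 8,
otherwise the Wilcoxon signed-rank test (exact null for n <= 25).
Normality is assessed on the paired differences by Shapiro-Wilk at
alpha = 0.05.  Percent changes are reported both unrounded and rounded
half-to-even to integers; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
NORMALITY_ALPHA = 0.05
#: below this n the nonparametric test is used regardless of normality
SMALL_N = 8
#: up to this n the Wilcoxon null is computed exactly
WILCOXON_EXACT_N = 25


@dataclass
class ComparisonResult:
    feature: str
    n: int
    control_mean: float
    control_sem: float
    treatment_mean: float
    treatment_sem: float
    percent_change: int          # rounded, signed per the dominant direction
    percent_change_unrounded: float
    test_used: str               # 'paired_t' | 'wilcoxon_signed_rank'
    p_value: float
    significant: bool
    degenerate: bool = False


def select_test(n: int, differences_normal: bool) -> str:
    """Pure test-selection rule: nonparametric for small n or non-normal."""
    if n < SMALL_N or not differences_normal:
        return "wilcoxon_signed_rank"
    return "paired_t"


def paired_compare(control, treatment, feature: str = "",
                  alpha: float = ALPHA) -> ComparisonResult:
    """Compare paired control/treatment values of one feature."""
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if c.shape != t.shape or c.ndim != 1:
        raise ValueError("control and treatment must be equal-length 1-D arrays")
    n = len(c)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = t - c
    direction = "increase" if np.mean(t) >= np.mean(c) else "decrease"
    pc = percent_change(float(np.mean(c)), float(np.mean(t)), direction)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n))
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return ComparisonResult(feature, n, float(np.mean(c)), sem(c),
                                float(np.mean(t)), sem(t), pc.rounded,
                                pc.unrounded, "wilcoxon_signed_rank", 1.0,
                                False, degenerate=True)
    normal = bool(sps.shapiro(d).pvalue >= NORMALITY_ALPHA) if n >= 3 else False
    test = select_test(n, normal)
    if test == "paired_t":
        p = float(sps.ttest_rel(t, c).pvalue)
    else:
        method = "exact" if n <= WILCOXON_EXACT_N else "auto"
        try:
            p = float(sps.wilcoxon(d, method=method).pvalue)
        except ValueError:
            p = float(sps.wilcoxon(d, method="auto").pvalue)
    return ComparisonResult(feature, n, float(np.mean(c)), sem(c),
                            float(np.mean(t)), sem(t), pc.rounded, pc.unrounded,
                            test, p, bool(p < alpha))


class PercentChange(NamedTuple):
    rounded: int
    unrounded: float


def percent_change(control_mean: float, treatment_mean: float,
                   direction: str = "increase") -> PercentChange:
    """Percent change of a group mean, signed per the stated direction.

    ``direction='decrease'`` reports a reduction as a positive percentage.
    The rounded value uses round-half-to-even; the unrounded value is kept.
    """
    if control_mean == 0:
        raise ValueError("control mean must be non-zero")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    raw = 100.0 * (treatment_mean - control_mean) / control_mean
    value = -raw if direction == "decrease" else raw
    return PercentChange(rounded=round(value), unrounded=value)


def effect_age_correlation(effect_sizes, ages) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between effect size and age."""
    x = np.asarray(effect_sizes, dtype=float)
    y = np.asarray(ages, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_cohort(cohort_frame, features=None, alpha: float = ALPHA):
    """Run paired comparisons for every feature of a paired-cohort table.

    Expects columns ``control_<feature>`` / ``treatment_<feature>``;
    returns a table shaped like a group-comparison summary.
    """
    import pandas as pd

    if features is None:
        features = sorted(c[len("control_"):] for c in cohort_frame.columns
                          if c.startswith("control_"))
    rows = []
    for f in features:
        res = paired_compare(cohort_frame[f"control_{f}"],
                             cohort_frame[f"treatment_{f}"], feature=f,
                             alpha=alpha)
        rows.append(vars(res))
    return pd.DataFrame(rows)
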