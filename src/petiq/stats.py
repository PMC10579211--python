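"""Paired comparisons across reconstructions: paired t, RM-ANOVA, Bonferroni.

The design is paired throughout — the same sphere or lesion is measured under
every reconstruction — so the omnibus test is a one-way repeated-measures
ANOVA (subject = lesion/sphere) and post hocs are paired t tests with
Bonferroni correction over all C(k, 2) pairs.  Tests are two-sided;
significance is assessed at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "StatsError", "paired_t", "bonferroni", "repeated_anova_bonferroni"]

ALPHA_DEFAULT = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    p_value: float
    n: int
    adjusted_p: float
    significant: bool
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.adjusted_p <= 1.0):
            raise StatsError("p-values must lie in [0, 1]")


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m); never decreases a p-value."""
    if m < 1:
        raise StatsError("number of comparisons must be >= 1")
    return min(1.0, p * m)


def paired_t(a, b, label: str = "paired", alpha: float = ALPHA_DEFAULT,
             n_comparisons: int = 1) -> TestResult:
    """Two-sided paired Student t test.

    Rejects degenerate input (unequal lengths, n < 2, or zero variance of
    the paired differences, where t is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsError("paired samples must be 1-D of equal length")
    n = a.size
    if n < 2:
        raise StatsError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0) and not np.allclose(d, 0.0):
        raise StatsError("zero variance of non-zero differences; t undefined")
    if np.allclose(d, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    adj = bonferroni(float(p), n_comparisons)
    return TestResult(label, float(t), float(p), n, adj, adj < alpha, alpha)


def repeated_anova_bonferroni(values, alpha: float = ALPHA_DEFAULT):
    """One-way repeated-measures ANOVA plus Bonferroni-adjusted post hocs.

    ``values`` is a complete (subject x condition) matrix — a DataFrame whose
    columns are reconstruction ids, or a 2-D array.  Returns
    ``(anova: TestResult, posthocs: list[TestResult])`` with post hoc paired
    t tests over all C(k, 2) condition pairs, Bonferroni-corrected.
    """
    if isinstance(values, pd.DataFrame):
        cols = [str(c) for c in values.columns]
        mat = values.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
        cols = [f"cond{i}" for i in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise StatsError("need a 2-D matrix with >= 2 conditions")
    if not np.all(np.isfinite(mat)):
        raise StatsError("matrix has missing/non-finite cells")
    n_subj, k = mat.shape

    # one-way RM-ANOVA decomposition (subject-blocked)
    grand = mat.mean()
    subj_means = mat.mean(axis=1, keepdims=True)
    cond_means = mat.mean(axis=0, keepdims=True)
    ss_cond = n_subj * float(((cond_means - grand) ** 2).sum())
    resid = mat - subj_means - cond_means + grand
    ss_err = float((resid**2).sum())
    df_cond = k - 1
    df_err = (n_subj - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        f_stat, p = (0.0, 1.0) if ms_cond == 0 else (np.inf, 0.0)
    else:
        f_stat = ms_cond / ms_err
        p = float(sps.f.sf(f_stat, df_cond, df_err))
    anova = TestResult(
        f"RM-ANOVA({', '.join(cols)})", float(f_stat), p, n_subj,
        bonferroni(p, 1), p < alpha, alpha,
    )

    m = k * (k - 1) // 2
    posthocs = [
        paired_t(
            mat[:, i], mat[:, j],
            label=f"{cols[i]} vs {cols[j]}", alpha=alpha, n_comparisons=m,
        )
        for i, j in combinations(range(k), 2)
    ]
    return anova, posthocs
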