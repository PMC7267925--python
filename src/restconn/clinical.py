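"""Depression-score derivations and small-sample group statistics.

Percent change is stored as a fraction internally (0.5 = 50 % improvement)
and rendered x100 only in reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pct_change",
    "cohens_d_change",
    "two_sample_t_summary",
    "sex_ratio_chisq",
    "paired_t",
    "table_one",
]


def pct_change(baseline: float, post: float) -> float:
    """(baseline - post) / baseline; positive = improvement."""
    if baseline <= 0:
        raise ValueError(f"baseline score must be positive; got {baseline}")
    return (baseline - post) / baseline


def cohens_d_change(changes=None, *, mean: float | None = None, sd: float | None = None) -> float:
    """One-sample Cohen's d: mean / sample SD (n-1 denominator).

    Accepts either a list of per-subject changes or summary statistics
    (``mean=``, ``sd=``).
    """
    if changes is not None:
        x = np.asarray(changes, dtype=np.float64)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
    elif mean is None or sd is None:
        raise ValueError("provide either a list of changes or both mean= and sd=")
    if sd <= 0:
        raise ValueError("standard deviation must be positive")
    return float(mean / sd)


def two_sample_t_summary(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int):
    """Pooled-variance (Student) two-sample t-test from summary statistics.

    Returns (t, df, two-sided p); df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var <= 0:
        raise ValueError("pooled variance is zero")
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def sex_ratio_chisq(n_male: int, n_female: int):
    """Goodness-of-fit chi-squared against a 50:50 split, no continuity correction."""
    n = n_male + n_female
    if n < 1:
        raise ValueError("need at least one subject")
    expected = n / 2.0
    chi2 = (n_male - expected) ** 2 / expected + (n_female - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def paired_t(pre_scores, post_scores):
    """Paired t-test = one-sample t on the differences. Returns (t, df, p)."""
    pre = np.asarray(pre_scores, dtype=np.float64)
    post = np.asarray(post_scores, dtype=np.float64)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("pre/post must be equal-length with n >= 2")
    diff = pre - post
    if np.std(diff, ddof=1) == 0:
        raise ValueError("differences have zero variance")
    res = stats.ttest_1samp(diff, 0.0)
    return float(res.statistic), int(pre.size - 1), float(res.pvalue)


def table_one(subjects: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: overall and by-sex means (SD) with group tests.

    Rows: subject counts (chi-squared vs 50:50), age, baseline score, post
    score and percent change (pooled two-sample t, males vs females).
    Percent change is rendered on the x100 scale.
    """
    df = subjects.copy()
    if "hdrs_pct_change" not in df.columns:
        df["hdrs_pct_change"] = [
            pct_change(b, p) for b, p in zip(df["hdrs_baseline"], df["hdrs_post"])
        ]
    males = df[df["sex"] == 0]
    females = df[df["sex"] == 1]
    chi2, _, p_sex = sex_ratio_chisq(len(males), len(females))

    rows = [{
        "measure": "n_subjects",
        "all": f"{len(df)}",
        "males": f"{len(males)}",
        "females": f"{len(females)}",
        "p_value": round(p_sex, 3),
    }]
    display = {
        "age": ("age", 1.0),
        "hdrs_baseline": ("hdrs_baseline", 1.0),
        "hdrs_post": ("hdrs_post", 1.0),
        "hdrs_pct_change": ("hdrs_pct_change", 100.0),
    }
    for label, (col, scale) in display.items():
        m_all, s_all = df[col].mean() * scale, df[col].std(ddof=1) * scale
        m1, s1 = males[col].mean() * scale, males[col].std(ddof=1) * scale
        m2, s2 = females[col].mean() * scale, females[col].std(ddof=1) * scale
        if len(males) >= 2 and len(females) >= 2:
            try:
                _, _, p = two_sample_t_summary(m1, s1, len(males), m2, s2, len(females))
            except ValueError:
                p = np.nan
        else:
            p = np.nan
        rows.append({
            "measure": label,
            "all": f"{m_all:.2f} ({s_all:.2f})",
            "males": f"{m1:.2f} ({s1:.2f})",
            "females": f"{m2:.2f} ({s2:.2f})",
            "p_value": round(p, 3) if np.isfinite(p) else np.nan,
        })
    return pd.DataFrame(rows)
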