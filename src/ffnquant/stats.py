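"""Inferential statistics used in the slice-imaging comparisons.

Two-tailed t-tests (paired, pooled-variance unpaired, optional Welch),
t-based 95 % confidence intervals, a one-way repeated-measures ANOVA for
within-slice manipulations (e.g. calcium levels), and a mixed
between-region x within-condition ANOVA. The ANOVA sums-of-squares
partitions are computed directly from the (complete) data tables; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "t_test",
    "ci95_mean",
    "rm_anova",
    "mixed_anova",
]


@dataclass(frozen=True)
class TestResult:
    """t statistic, degrees of freedom, two-tailed p, CI95 and group sizes."""

    statistic: float
    df: float
    p_value: float
    ci95: tuple[float, float]
    n: tuple[int, ...]


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def t_test(x, y, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-tailed t-test on two samples.

    Unpaired tests pool the variance (classical Student test) unless
    ``welch=True``. The CI95 is on the mean difference (x - y). Degenerate
    inputs (zero variance of the paired differences, or zero pooled
    variance) raise rather than returning infinities.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate paired test: all differences equal")
        sem = sd / np.sqrt(n)
        t = d.mean() / sem
        df = n - 1.0
        tq = sps.t.ppf(0.975, df)
        ci = (d.mean() - tq * sem, d.mean() + tq * sem)
        return TestResult(float(t), df, _two_tailed_p(t, df), ci, (n,))
    n1, n2 = x.size, y.size
    diff = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            raise ValueError("degenerate test: zero variance in both groups")
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = np.sqrt(se2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValueError("degenerate test: zero pooled variance")
        df = n1 + n2 - 2.0
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    tq = sps.t.ppf(0.975, df)
    ci = (diff - tq * se, diff + tq * se)
    return TestResult(float(t), float(df), _two_tailed_p(t, df), ci, (n1, n2))


def ci95_mean(x) -> tuple[float, float]:
    """t-based 95 % confidence interval on the mean: mean +/- t(0.975) * SEM."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sem = x.std(ddof=1) / np.sqrt(x.size)
    half = sps.t.ppf(0.975, x.size - 1) * sem
    return (float(x.mean() - half), float(x.mean() + half))


def _as_subject_by_condition(data) -> np.ndarray:
    arr = np.asarray(
        data.values if isinstance(data, pd.DataFrame) else data, dtype=float
    )
    if arr.ndim != 2:
        raise ValueError("expect a subjects x conditions table")
    if np.any(~np.isfinite(arr)):
        raise ValueError("table has missing cells")
    return arr


def _gg_epsilon(arr: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the condition covariances."""
    s = np.cov(arr, rowvar=False)
    k = s.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    sc = j @ s @ j  # double-centered covariance
    num = np.trace(sc) ** 2
    den = (k - 1) * np.sum(sc * sc)
    return float(num / den)


def rm_anova(data, greenhouse_geisser: bool = False) -> pd.DataFrame:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Partitions total variability into condition, subject and residual sums
    of squares; F tests the condition effect against the residual. Requires
    a complete balanced table with >= 2 subjects and >= 2 conditions. With
    two conditions F equals the squared paired t statistic. Optional
    Greenhouse-Geisser correction scales the degrees of freedom by the
    sphericity epsilon (the F ratio is unchanged).
    """
    arr = _as_subject_by_condition(data)
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = arr.mean()
    ss_cond = n * np.sum((arr.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((arr.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_subj = k - 1, n - 1
    df_err = df_cond * df_subj
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    f = ms_cond / ms_err if ms_err > 0 else 0.0
    if greenhouse_geisser:
        eps = _gg_epsilon(arr)
        p = float(sps.f.sf(f, eps * df_cond, eps * df_err)) if f > 0 else 1.0
    else:
        p = float(sps.f.sf(f, df_cond, df_err)) if f > 0 else 1.0
    rows = [
        ("condition", ss_cond, df_cond, f, p),
        ("subject", ss_subj, df_subj, np.nan, np.nan),
        ("error", ss_err, df_err, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["effect", "ss", "df", "F", "p"])


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "region",
    subject: str = "subject",
) -> pd.DataFrame:
    """Mixed (split-plot) ANOVA: between-subject group x within-subject condition.

    Each subject must belong to exactly one group, contribute every condition
    exactly once, and every group must have >= 2 subjects. The between effect
    is tested against subjects-within-groups, the within effect and the
    interaction against the condition x subject residual. Group sizes may be
    unequal (weighted sums of squares).
    """
    for col in (dv, within, between, subject):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    groups_per_subject = df.groupby(subject)[between].nunique()
    if (groups_per_subject > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    conditions = sorted(df[within].unique())
    b = len(conditions)
    if b < 2:
        raise ValueError("need >= 2 within-subject conditions")
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any() or df.groupby(subject)[within].nunique().ne(b).any():
        raise ValueError("each subject must have every condition exactly once")
    group_sizes = df.groupby(between)[subject].nunique()
    if (group_sizes < 2).any():
        raise ValueError("every group needs at least 2 subjects")

    grand = df[dv].mean()
    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    group_means = df.groupby(between)[dv].mean()
    cond_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()

    n_g = group_sizes  # subjects per group
    ss_group = float(b * (n_g * (group_means - grand) ** 2).sum())
    ss_subj_within = float(
        b * ((subj_means - subj_group.map(group_means)) ** 2).sum()
    )
    ss_cond = float((df.groupby(within)[dv].count() * (cond_means - grand) ** 2).sum())
    inter = 0.0
    for g in group_means.index:
        for c in conditions:
            dev = cell_means[(g, c)] - group_means[g] - cond_means[c] + grand
            inter += n_g[g] * dev**2
    ss_inter = float(inter)
    resid = df[dv] - df.set_index([between, within]).index.map(cell_means).values
    resid = resid - (df[subject].map(subj_means) - df[between].map(group_means))
    ss_err_within = float((resid**2).sum())

    a = len(group_means)
    df_group = a - 1
    df_subj = int((n_g - 1).sum())
    df_cond = b - 1
    df_inter = df_group * df_cond
    df_err = df_subj * df_cond

    def _row(name, ss, dfn, ms_err, dfe):
        ms = ss / dfn
        f = ms / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, dfn, dfe)) if f > 0 else 1.0
        return (name, ss, dfn, f, p)

    ms_between_err = ss_subj_within / df_subj
    ms_within_err = ss_err_within / df_err
    rows = [
        _row(between, ss_group, df_group, ms_between_err, df_subj),
        _row(within, ss_cond, df_cond, ms_within_err, df_err),
        _row("interaction", ss_inter, df_inter, ms_within_err, df_err),
        (f"subjects within {between}", ss_subj_within, df_subj, np.nan, np.nan),
        ("error (within)", ss_err_within, df_err, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=["effect", "ss", "df", "F", "p"])
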