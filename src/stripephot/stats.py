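"""Statistical layer: t-tests, balanced two-way mixed ANOVA with Šídák
post-hocs, the count log transform, and the colocalization proportion.

The mixed ANOVA is the classical sums-of-squares decomposition for a design
with one between-subjects factor (subjects nested in groups) and one
within-subjects factor, requiring balance (every subject observed at every
within level).  The between effect is tested against the subjects-within-
groups mean square; the within effect and the interaction against the
within-subjects error mean square.  No sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "TestResult",
    "AnovaTable",
    "StatisticsError",
    "one_sample_t",
    "paired_t",
    "mixed_anova",
    "sidak_adjust",
    "log_transform_counts",
    "colocalization_percent",
]


class StatisticsError(ValueError):
    """Inputs do not admit the requested test."""


@dataclass
class TestResult:
    name: str
    t: float
    df: int
    p: float
    n: int


@dataclass
class AnovaTable:
    """Omnibus effects plus Šídák-adjusted pairwise between-group post-hocs.

    ``effects`` rows: between factor, within factor, interaction (Source, SS,
    df_num, df_den, MS, F, p).  ``posthoc`` rows: one per group pair per
    within level, with the pooled-variance two-sample t and both raw and
    Šídák-adjusted p (family size = #levels x #pairs).
    """

    effects: pd.DataFrame
    posthoc: pd.DataFrame


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of mean(values) against mu0."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise StatisticsError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatisticsError("zero sample variance: t undefined")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * st.t.sf(abs(t), df)
    return TestResult("one-sample t", float(t), df, float(p), n)


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-tailed paired t-test: one-sample test of the differences vs 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    res = one_sample_t(a - b, 0.0)
    return TestResult("paired t", res.t, res.df, res.p, res.n)


def sidak_adjust(p: float, m: int) -> float:
    """Šídák multiplicity adjustment: 1 - (1 - p)^m, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def log_transform_counts(values: np.ndarray) -> np.ndarray:
    """log10(x + 1), admitting zero counts; rejects negative input."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log10(x + 1.0)


def colocalization_percent(n_double: int, n_total: int) -> float:
    """Percentage of double-labeled cells, reported to one decimal."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_double <= n_total:
        raise ValueError("n_double must lie in [0, n_total]")
    return round(100.0 * n_double / n_total, 1)


def _check_balance(df: pd.DataFrame, subject: str, between: str, within: str) -> None:
    groups = df.groupby(subject)[between].nunique()
    if (groups > 1).any():
        bad = list(groups.index[groups > 1])
        raise StatisticsError(f"subjects in multiple between levels: {bad}")
    levels = sorted(df[within].unique())
    missing = []
    counts = df.groupby([subject, within]).size()
    for subj in df[subject].unique():
        for lev in levels:
            c = counts.get((subj, lev), 0)
            if c != 1:
                missing.append((subj, lev, int(c)))
    if missing:
        raise StatisticsError(f"unbalanced design; (subject, level, count) cells: {missing}")
    per_group = df.drop_duplicates(subject).groupby(between).size()
    if per_group.nunique() != 1:
        raise StatisticsError(
            f"unequal group sizes: {per_group.to_dict()} (balanced design required)"
        )


def mixed_anova(table: pd.DataFrame, dv: str = "value", subject: str = "subject",
                between: str = "between", within: str = "within") -> AnovaTable:
    """Balanced two-way mixed-design ANOVA with Šídák pairwise post-hocs.

    ``table`` is long format with one row per (subject, within level)
    observation.  Returns omnibus F tests for the between factor, the within
    factor and their interaction, plus pooled-variance two-sample t
    comparisons of the groups at each within level, Šídák-adjusted over the
    whole family.
    """
    df = table[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise StatisticsError("missing values in the dependent variable")
    _check_balance(df, subject, between, within)

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = sorted(df[between].unique())
    b_levels = sorted(df[within].unique())
    subjects = df[subject].unique()
    a, b, s = len(a_levels), len(b_levels), len(subjects) // len(a_levels)

    group_mean = df.groupby(between)[dv].mean()
    time_mean = df.groupby(within)[dv].mean()
    cell_mean = df.groupby([between, within])[dv].mean()
    subj_mean = df.groupby(subject)[dv].mean()
    subj_group = df.drop_duplicates(subject).set_index(subject)[between]

    ss_total = float(((y - grand) ** 2).sum())
    ss_a = s * b * float(((group_mean - grand) ** 2).sum())
    ss_between_subj = b * float(((subj_mean - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_a
    ss_b = a * s * float(((time_mean - grand) ** 2).sum())
    ss_ab = s * sum(
        (cell_mean[(ga, gb)] - group_mean[ga] - time_mean[gb] + grand) ** 2
        for ga in a_levels for gb in b_levels
    )
    ss_err = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = a - 1, a * (s - 1)
    df_b, df_ab = b - 1, (a - 1) * (b - 1)
    df_err = a * (s - 1) * (b - 1)
    if df_subj == 0 or df_err == 0:
        raise StatisticsError("need at least 2 subjects per group and 2 within levels")

    ms = {
        "A": ss_a / df_a, "subj": ss_subj / df_subj,
        "B": ss_b / df_b, "AB": ss_ab / df_ab, "err": ss_err / df_err,
    }
    rows = []
    for name, ss_x, dfn, dfd, ms_num, ms_den in [
        (between, ss_a, df_a, df_subj, ms["A"], ms["subj"]),
        (within, ss_b, df_b, df_err, ms["B"], ms["err"]),
        (f"{between} * {within}", ss_ab, df_ab, df_err, ms["AB"], ms["err"]),
    ]:
        F = ms_num / ms_den if ms_den > 0 else np.nan
        p = float(st.f.sf(F, dfn, dfd)) if np.isfinite(F) else np.nan
        rows.append({"Source": name, "SS": ss_x, "df_num": dfn, "df_den": dfd,
                     "MS": ms_num, "F": F, "p": p})
    effects = pd.DataFrame(rows)

    pairs = list(combinations(a_levels, 2))
    m = len(pairs) * len(b_levels)
    ph_rows = []
    for lev in b_levels:
        sub = df[df[within] == lev]
        for g1, g2 in pairs:
            x1 = sub.loc[sub[between] == g1, dv].to_numpy(dtype=float)
            x2 = sub.loc[sub[between] == g2, dv].to_numpy(dtype=float)
            t, p = st.ttest_ind(x1, x2, equal_var=True)
            ph_rows.append({
                "within_level": lev, "group_a": g1, "group_b": g2,
                "t": float(t), "df": len(x1) + len(x2) - 2,
                "p_raw": float(p), "p_sidak": sidak_adjust(float(p), m),
            })
    return AnovaTable(effects, pd.DataFrame(ph_rows))
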