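"""Demographic matching statistics for a multi-group study table.

One-way ANOVA for continuous covariates — reconstructable exactly from
printed per-group means, sample standard deviations and sizes — and the
Pearson chi-squared test of independence for categorical ones (sex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ParameterError


@dataclass
class GroupSummary:
    """Per-group summary of one continuous variable.

    ``sd`` is the sample standard deviation (n - 1 divisor), the standard
    reporting convention for demographic tables.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("group size must be >= 2")
        if self.sd is None or self.sd < 0:
            raise ParameterError("sample SD must be a non-negative number")


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False   # zero within-group variance with mean spread

    def __iter__(self):
        return iter((self.F, self.p, (self.df_between, self.df_within)))


def anova_from_summary(summaries: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed exactly from group moments.

    SSB = sum n_g (m_g - m)^2, SSW = sum (n_g - 1) s_g^2,
    F = (SSB / (k-1)) / (SSW / (N-k)), p from the F(k-1, N-k) tail.
    """
    if len(summaries) < 2:
        raise ParameterError("need at least 2 groups")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    s = np.array([s.sd for s in summaries], dtype=float)
    N = n.sum()
    k = len(summaries)
    grand = (n * m).sum() / N
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * s ** 2).sum()
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, 1.0, df_b, df_w, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_b, df_w, degenerate=True)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(st.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w)


def anova_from_raw(groups: list) -> AnovaResult:
    """One-way ANOVA from raw per-group values (agrees with
    :func:`anova_from_summary` on the exact moments to 1e-10)."""
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in cleaned):
        raise ParameterError("every group needs at least 2 values")
    summaries = [GroupSummary(mean=float(g.mean()), sd=float(g.std(ddof=1)),
                              n=len(g)) for g in cleaned]
    return anova_from_summary(summaries)


def chi_square_independence(table) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence, no continuity correction.

    Returns (chi2, p, df) for a groups x categories count table.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ParameterError("need a 2-D table with >= 2 rows and columns")
    if np.any(t < 0):
        raise ParameterError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ParameterError("zero marginal: the test is undefined")
    res = st.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


CONTINUOUS_VARS = ("age", "education", "mmse", "avlt_ltm")


def demographics_table(df: pd.DataFrame, group_col: str = "group",
                       sex_col: str = "sex") -> pd.DataFrame:
    """Study-table-style summary: per-group mean (SD) and the matching
    test statistic per covariate (ANOVA for continuous, chi-squared for
    sex)."""
    groups = sorted(df[group_col].unique(),
                    key=lambda g: {"NC": 0, "HT": 1, "HM": 2}.get(g, 99))
    rows = []
    for var in [c for c in CONTINUOUS_VARS if c in df.columns]:
        cells = {}
        summaries = []
        for g in groups:
            vals = df.loc[df[group_col] == g, var].dropna()
            cells[g] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})"
            summaries.append(GroupSummary(float(vals.mean()),
                                          float(vals.std(ddof=1)), len(vals)))
        res = anova_from_summary(summaries)
        cells["statistic"] = f"F = {res.F:.1f}; p = {res.p:.2f}"
        cells["variable"] = var
        rows.append(cells)
    if sex_col in df.columns:
        cats = sorted(df[sex_col].unique())
        counts = [[int(((df[group_col] == g) & (df[sex_col] == c)).sum())
                   for c in cats] for g in groups]
        chi2, p, _ = chi_square_independence(counts)
        cells = {g: "/".join(str(c) for c in row)
                 for g, row in zip(groups, counts)}
        cells["statistic"] = f"chi2 = {chi2:.1f}; p = {p:.2f}"
        cells["variable"] = sex_col
        rows.append(cells)
    return pd.DataFrame(rows).set_index("variable")
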