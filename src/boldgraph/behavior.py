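"""Demographic and psychometric group statistics and brain-behavior correlation.

Welch two-sample t from summary statistics or raw data, Pearson chi-square for
2x2 contingency tables, and Spearman rank correlation between covariate-
residualized brain measures and behavioral scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_inference import residualize_scores

__all__ = [
    "SummaryStats",
    "TestReport",
    "welch_t_from_summary",
    "two_sample_t_raw",
    "chi2_independence",
    "spearman_with_residualization",
    "group_summary_table",
]


@dataclass
class SummaryStats:
    mean: float
    sd: float
    n: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class TestReport:
    statistic: float
    df: float
    p: float
    test: str

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p outside [0, 1]")


def welch_t_from_summary(s1: SummaryStats, s2: SummaryStats) -> TestReport:
    """Welch's unequal-variance two-sample two-tailed t-test from summaries.

    t = (m1 - m2) / sqrt(sd1^2/n1 + sd2^2/n2) with Welch-Satterthwaite df.
    """
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("zero variance in both groups")
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    se2 = v1 + v2
    t = (s1.mean - s2.mean) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return TestReport(statistic=float(t), df=float(df), p=p, test="welch_t")


def _pooled_t_from_summary(s1: SummaryStats, s2: SummaryStats) -> TestReport:
    sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / (s1.n + s2.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (s1.mean - s2.mean) / np.sqrt(sp2 * (1 / s1.n + 1 / s2.n))
    df = s1.n + s2.n - 2
    p = float(2 * stats.t.sf(abs(t), df))
    return TestReport(statistic=float(t), df=float(df), p=p, test="pooled_t")


def two_sample_t_raw(values: np.ndarray, group: np.ndarray,
                     variant: str = "welch") -> TestReport:
    """Two-sample two-tailed t on raw data; consistent with the summary path.

    ``group`` marks membership (1/True = first group). ``variant`` selects the
    Welch (default) or pooled-variance statistic.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group).astype(bool)
    x1, x2 = values[group], values[~group]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need >= 2 observations per group")
    s1 = SummaryStats(float(x1.mean()), float(x1.std(ddof=1)), len(x1))
    s2 = SummaryStats(float(x2.mean()), float(x2.std(ddof=1)), len(x2))
    if variant == "welch":
        return welch_t_from_summary(s1, s2)
    if variant == "pooled":
        return _pooled_t_from_summary(s1, s2)
    raise ValueError("variant must be 'welch' or 'pooled'")


def chi2_independence(table: np.ndarray) -> TestReport:
    """Pearson chi-square for a 2x2 table, no continuity correction, df = 1."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected count <= 0")
    return TestReport(statistic=float(chi2), df=float(dof), p=float(p), test="chi2")


def spearman_with_residualization(brain_values: np.ndarray, covariates: np.ndarray,
                                  scores: np.ndarray) -> tuple[float, float]:
    """Spearman correlation of covariate-adjusted brain values with scores.

    Brain values are first residualized on (intercept, covariates); the
    two-sided p uses the t approximation with n - 2 df.
    """
    brain_values = np.asarray(brain_values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(brain_values) < 4:
        raise ValueError("need >= 4 subjects")
    resid = residualize_scores(brain_values, covariates)
    if np.ptp(resid) == 0 or np.ptp(scores) == 0:
        raise ValueError("constant residuals or scores")
    rho, p = stats.spearmanr(resid, scores)
    return float(rho), float(p)


def group_summary_table(pheno: pd.DataFrame,
                        score_columns: tuple = ("adhd_asrs", "adhd_rs4", "bdi", "age"),
                        patient_label: str = "patient") -> pd.DataFrame:
    """Demographics-style report: per-group mean (sd), Welch p per score, chi2 p for gender."""
    if pheno[list(score_columns) + ["group", "gender"]].isna().any().any():
        raise ValueError("phenotype table contains missing values")
    is_p = pheno["group"] == patient_label
    rows = []
    f_p = int((pheno.loc[is_p, "gender"] == "f").sum())
    m_p = int((pheno.loc[is_p, "gender"] == "m").sum())
    f_c = int((pheno.loc[~is_p, "gender"] == "f").sum())
    m_c = int((pheno.loc[~is_p, "gender"] == "m").sum())
    rep = chi2_independence([[f_p, m_p], [f_c, m_c]])
    rows.append({"variable": "gender_female_male",
                 "patient": f"{f_p}/{m_p}", "control": f"{f_c}/{m_c}",
                 "statistic": rep.statistic, "df": rep.df, "p": rep.p, "test": rep.test})
    for col in score_columns:
        rep = two_sample_t_raw(pheno[col].to_numpy(), is_p.to_numpy(), "welch")
        x1, x2 = pheno.loc[is_p, col], pheno.loc[~is_p, col]
        rows.append({"variable": col,
                     "patient": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
                     "control": f"{x2.mean():.2f} ({x2.std(ddof=1):.2f})",
                     "statistic": rep.statistic, "df": rep.df, "p": rep.p, "test": rep.test})
    return pd.DataFrame(rows)
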