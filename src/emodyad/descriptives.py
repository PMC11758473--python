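"""Descriptive tables, correlations and the screening t-tests.

Mirrors the pre-modelling results workflow of a dyadic diary study:
means/SDs/ranges and a starred pairwise Pearson correlation matrix;
two-tailed paired t-tests contrasting the two dyad roles on emotion
features; Welch t-tests comparing outcome values between cases with and
without missing data; a multicollinearity screen at |r| > .80; and an
advisory normality screen (|skew| > 2 or excess kurtosis > 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Table-1 variable order for the canonical merged per-person table
TABLE1_ORDER = (
    "cg_mean_pos", "cg_mean_neg", "cg_gini_pos", "cg_gini_neg",
    "cg_depressive", "cg_anxious",
    "adol_mean_pos", "adol_mean_neg", "adol_gini_pos", "adol_gini_neg",
    "adol_depressive", "adol_anxious",
)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    mean_difference: float
    kind: str


@dataclass
class DescriptivesTable:
    stats: pd.DataFrame        # mean, sd, min, max per variable
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        """Publication-style frame: starred r cells plus a "mean (SD)" column."""
        out = self.r.round(digits).astype(object)
        for i, vi in enumerate(self.r.index):
            for j, vj in enumerate(self.r.columns):
                if i < j:
                    out.loc[vi, vj] = ""
                elif i == j:
                    out.loc[vi, vj] = "-"
                else:
                    out.loc[vi, vj] = f"{self.r.loc[vi, vj]:.{digits}f}" + \
                        self.stars.loc[vi, vj]
        out["mean_sd"] = [
            f"{self.stats.loc[v, 'mean']:.{digits}f} ({self.stats.loc[v, 'sd']:.{digits}f})"
            for v in self.r.index]
        return out


def _star(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def descriptives(table: pd.DataFrame, order: tuple[str, ...] | None = None
                 ) -> DescriptivesTable:
    """Means/SDs/ranges plus the pairwise-complete Pearson matrix with stars."""
    cols = [c for c in (order or table.columns) if c in table.columns]
    data = table[cols]
    desc = pd.DataFrame({
        "mean": data.mean(), "sd": data.std(ddof=1),
        "min": data.min(), "max": data.max(),
    })
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = data[cols[i]].notna().sum()
        for j in range(i):
            pair = data[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    stars = pdf.map(_star)
    np.fill_diagonal(stars.values, "")
    return DescriptivesTable(desc, rdf, pdf, pd.DataFrame(n, index=cols, columns=cols), stars)


def paired_ttest(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-tailed paired t-test on complete pairs; sign follows (x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x[mask] - y[mask]
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return TestResult(0.0, len(d) - 1, 1.0, 0.0, "paired")
        raise ValueError("zero variance of nonzero differences")
    res = stats.ttest_rel(x[mask], y[mask])
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      float(d.mean()), "paired")


def missingness_ttest(outcome: np.ndarray, has_missing: np.ndarray) -> TestResult:
    """Welch t-test of an outcome between cases with/without missing data."""
    outcome = np.asarray(outcome, dtype=float)
    has_missing = np.asarray(has_missing, dtype=bool)
    a = outcome[has_missing & ~np.isnan(outcome)]
    b = outcome[~has_missing & ~np.isnan(outcome)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observed values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      float(a.mean() - b.mean()), "independent-Welch")


def collinearity_screen(predictors: pd.DataFrame, threshold: float = 0.80
                        ) -> list[tuple[str, str, float]]:
    """Pairs of predictors whose |Pearson r| exceeds the threshold."""
    cols = list(predictors.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors")
    flagged = []
    for i in range(len(cols)):
        for j in range(i):
            pair = predictors[[cols[i], cols[j]]].dropna()
            r = float(pair.corr().iloc[0, 1])
            if abs(r) > threshold:
                flagged.append((cols[j], cols[i], r))
    return flagged


def normality_screen(table: pd.DataFrame, skew_flag: float = 2.0,
                     kurtosis_flag: float = 7.0) -> pd.DataFrame:
    """Advisory skewness / excess-kurtosis screen per variable."""
    rows = []
    for col in table.columns:
        x = table[col].dropna()
        sk = float(stats.skew(x))
        ku = float(stats.kurtosis(x))
        rows.append({"variable": col, "skewness": sk, "excess_kurtosis": ku,
                     "flagged": abs(sk) > skew_flag or abs(ku) > kurtosis_flag})
    return pd.DataFrame(rows)


def person_table(summaries: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Merge summaries and baselines into the wide Table-1-ordered frame."""
    s = summaries.pivot(index="dyad_id", columns="role",
                        values=["mean_pos", "mean_neg", "gini_pos", "gini_neg"])
    b = baselines.pivot(index="dyad_id", columns="role",
                        values=["anxious_mean", "depressive_mean"])
    prefix = {"adolescent": "adol", "caregiver": "cg"}
    out = pd.DataFrame(index=s.index)
    for role in ("caregiver", "adolescent"):
        pre = prefix[role]
        for value in ("mean_pos", "mean_neg", "gini_pos", "gini_neg"):
            out[f"{pre}_{value}"] = s.get((value, role))
        out[f"{pre}_depressive"] = b.get(("depressive_mean", role))
        out[f"{pre}_anxious"] = b.get(("anxious_mean", role))
    return out[[c for c in TABLE1_ORDER if c in out.columns]]
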