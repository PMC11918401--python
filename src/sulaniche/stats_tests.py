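"""Generic statistical machinery used across the pipeline.

Thin, uniformly-shaped wrappers (everything returns a :class:`TestResult`)
around the standard routines: Spearman rank correlation matrices,
Mann-Whitney U (exact by enumeration for small untied samples, otherwise
normal approximation with continuity correction), Welch's t, one-/two-way
ANOVA with sequential (Type I) sums of squares, Tukey-Kramer pairwise
comparisons, and the Brown-Forsythe (median-centered) Levene test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "spearman_matrix",
    "mann_whitney_u",
    "welch_t",
    "anova",
    "tukey_hsd",
    "levene_test",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | tuple | None
    p: float
    groups: list = field(default_factory=list)
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "groups": self.groups,
            "notes": self.notes,
        }


def spearman_matrix(columns: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations (average ranks for ties).

    Returns (rho, p) DataFrames; pairs involving a constant column are NaN.
    """
    names = list(columns.columns)
    k = len(names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    pval = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            a = columns[names[i]].to_numpy(dtype=float)
            b = columns[names[j]].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(a[ok], b[ok])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U with tie-corrected p.

    Exact p by enumeration when n_a * n_b <= 400 and the pooled sample has
    no ties, otherwise the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= 400) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic", use_continuity=True
    )
    return TestResult(
        test="mann-whitney-u",
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        notes="exact enumeration" if exact else "normal approximation, continuity + tie correction",
    )


def welch_t(a, b) -> TestResult:
    """Welch's t with Welch-Satterthwaite df (no equal-variance assumption)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult("welch-t", 0.0, float(len(a) + len(b) - 2), 1.0, notes="degenerate: zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch-t", float(res.statistic), float(res.df), float(res.pvalue))


def anova(values, factors: dict, typ: int = 1) -> list[TestResult]:
    """One- or two-way ANOVA (with interaction for two factors).

    ``factors`` maps factor name -> level array; term order in the
    sequential (Type I) decomposition follows the dict order, matching the
    convention of fitting sex before year before their interaction.
    Two-way designs with an empty cell raise with the cell named.
    """
    names = list(factors)
    if not 1 <= len(names) <= 2:
        raise ValueError("1 or 2 factors supported")
    df = pd.DataFrame({"y": np.asarray(values, dtype=float)})
    for name in names:
        df[name] = pd.Categorical(factors[name])
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    if len(names) == 2:
        counts = df.groupby(names, observed=False).size()
        empty = counts[counts == 0]
        if len(empty):
            raise ValueError(f"empty design cell: {empty.index[0]}")
        formula = f"y ~ C({names[0]}) * C({names[1]})"
    else:
        formula = f"y ~ C({names[0]})"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=typ)
    results = []
    for term, row in table.iterrows():
        if term.strip() == "Residual":
            continue
        label = term.replace("C(", "").replace(")", "").replace(":", " x ")
        results.append(
            TestResult(
                test=f"anova[{label}]",
                statistic=float(row["F"]),
                df=(float(row["df"]), float(table.loc["Residual", "df"])),
                p=float(row["PR(>F)"]),
                notes=f"type {typ} sequential SS" if typ == 1 else f"type {typ} SS",
            )
        )
    return results


def tukey_hsd(values, groups) -> list[TestResult]:
    """Tukey-Kramer pairwise comparisons (studentized range, unbalanced-safe)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 cells")
    res = pairwise_tukeyhsd(values, groups)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj, lower, upper, reject = row
        out.append(
            TestResult(
                test="tukey-hsd",
                statistic=float(meandiff),
                df=None,
                p=float(p_adj),
                groups=[str(g1), str(g2)],
                notes="Tukey-Kramer adjusted",
            )
        )
    return out


def levene_test(*groups) -> TestResult:
    """Brown-Forsythe Levene test (absolute deviations from group medians)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    stat, p = stats.levene(*groups, center="median")
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult("levene", float(stat), (float(k - 1), float(n - k)), float(p), notes="median-centered")
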