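"""Group-comparison statistics for the clinical covariate table.

One-way ANOVA (from raw data or from printed M/SD/n summaries), Welch
ANOVA for unequal variances, Pearson chi-square for categorical
associations, Mann-Whitney U for skewed covariates, Kendall tau-b
correlation, and one-way ANCOVA with a single covariate.  No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "one_way_anova",
    "anova_from_summary",
    "welch_anova",
    "welch_anova_from_summary",
    "chi_square",
    "mann_whitney_u",
    "kendall_tau",
    "ancova",
    "group_comparison_table",
]


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with degrees of freedom and p-value."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float


def one_way_anova(groups) -> TestResult:
    """Classic one-way ANOVA over >= 2 groups of raw values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    msw = ssw / df2
    if msw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df1) / msw
    p = 1.0 if f == 0 else float(stats.f.sf(f, df1, df2))
    return TestResult("F", float(f), (df1, df2), p)


def anova_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TestResult:
    """Two-group one-way ANOVA recomputed from printed means, SDs and ns."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    n = n1 + n2
    grand = (n1 * m1 + n2 * m2) / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    msw = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n - 2)
    if msw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = ssb / msw
    p = 1.0 if f == 0 else float(stats.f.sf(f, 1, n - 2))
    return TestResult("F", float(f), (1, n - 2), p)


def welch_anova_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TestResult:
    """Two-group Welch ANOVA from summaries (squared Welch t)."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variances")
    f = (m1 - m2) ** 2 / (v1 + v2)
    df2 = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(stats.f.sf(f, 1, df2)) if f > 0 else 1.0
    return TestResult("Welch F", float(f), (1, float(df2)), p)


def welch_anova(x, y) -> TestResult:
    """Two-group Welch ANOVA (unequal variances) from raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    return welch_anova_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or (observed < 0).any():
        raise ValueError("table must be a 2D array of non-negative counts")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(observed, correction=False)
    if chi2 == 0:
        p = 1.0
    return TestResult("chi2", float(chi2), (int(df),), float(p))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U, reported as U = min(U_x, U_y).

    Without ties and with small samples the p-value is exact (full
    enumeration of rank assignments); otherwise a tie-corrected normal
    approximation without continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return TestResult("U", len(x) * len(y) / 2.0, (float(len(x)), float(len(y))), 1.0)
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    small = len(x) + len(y) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    u_x = float(res.statistic)
    u = min(u_x, len(x) * len(y) - u_x)
    return TestResult("U", u, (float(len(x)), float(len(y))), float(res.pvalue))


def kendall_tau(x, y) -> TestResult:
    """Kendall tau-b with tie correction, normal-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for a constant vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TestResult("tau", float(res.statistic), (float(len(x)),), float(res.pvalue))


def ancova(y, group, covariate) -> tuple[TestResult, TestResult]:
    """One-way ANCOVA: y ~ intercept + group + covariate, partial F per term.

    The partial (type-III) F of each single-df term equals the square of
    its coefficient t-statistic in the full linear model, with
    (1, n - 3) degrees of freedom.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError("group must be binary")
    indicator = (group == levels[1]).astype(float)
    if np.all(covariate == covariate[0]):
        raise ValueError("covariate is constant")
    if len(y) < 5:
        raise ValueError("need n >= k + 2 observations")
    if np.all(y == y[0]):  # degenerate response: nothing to explain
        df2 = len(y) - 3
        zero = TestResult("F_group", 0.0, (1, df2), 1.0)
        return zero, TestResult("F_covariate", 0.0, (1, df2), 1.0)
    design = sm.add_constant(np.column_stack([indicator, covariate]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate collinear with group indicator")
    fit = sm.OLS(y, design).fit()
    df2 = len(y) - 3

    def term(i: int, name: str) -> TestResult:
        t = fit.tvalues[i]
        f = float(t * t) if np.isfinite(t) else 0.0
        p = float(stats.f.sf(f, 1, df2)) if f > 0 else 1.0
        return TestResult(name, f, (1, df2), p)

    return term(1, "F_group"), term(2, "F_covariate")


DEFAULT_TEST_MAP = {
    "age": "anova",
    "duration_of_illness": "anova",
    "hospitalizations": "welch",
    "panss_total": "anova",
    "panss_positive": "anova",
    "panss_negative": "anova",
    "panss_general": "welch",
    "cpz": "mannwhitney",
    "age_of_onset": "mannwhitney",
    "educational_years": "mannwhitney",
    "sex": "chisq",
    "clozapine": "chisq",
    "language": "chisq",
    "handedness": "chisq",
}


def group_comparison_table(
    clin: pd.DataFrame,
    positive_mask: pd.Series,
    test_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Covariate-by-covariate comparison of marker-positive vs -negative.

    ``positive_mask`` flags the marker-positive subjects.  ``test_map``
    assigns each covariate its test (anova, welch, mannwhitney, chisq);
    covariates absent from the map are skipped, as are covariates with an
    entirely-missing group.  Continuous rows report M(SD) (or medians for
    rank tests), categorical rows the level counts.
    """
    test_map = dict(DEFAULT_TEST_MAP if test_map is None else test_map)
    positive_mask = positive_mask.reindex(clin.index).fillna(False).astype(bool)
    pos, neg = clin[positive_mask], clin[~positive_mask]
    rows = []
    for cov, test in test_map.items():
        if cov not in clin.columns:
            continue
        a, b = neg[cov].dropna(), pos[cov].dropna()
        if a.empty or b.empty:
            continue
        if test in ("anova", "welch", "mannwhitney"):
            a = a.astype(float)
            b = b.astype(float)
            if test == "anova":
                res = one_way_anova([a, b])
                desc_neg = f"{a.mean():.2f}({a.std(ddof=1):.2f})"
                desc_pos = f"{b.mean():.2f}({b.std(ddof=1):.2f})"
            elif test == "welch":
                res = welch_anova(a, b)
                desc_neg = f"{a.mean():.2f}({a.std(ddof=1):.2f})"
                desc_pos = f"{b.mean():.2f}({b.std(ddof=1):.2f})"
            else:
                res = mann_whitney_u(a, b)
                desc_neg = f"Mdn {a.median():.2f}"
                desc_pos = f"Mdn {b.median():.2f}"
        elif test == "chisq":
            levels = sorted(set(a) | set(b))
            counts = np.array(
                [[int((a == l).sum()) for l in levels], [int((b == l).sum()) for l in levels]]
            )
            counts = counts[:, counts.sum(axis=0) > 0]
            res = chi_square(counts)
            desc_neg = ":".join(str(int((a == l).sum())) for l in levels)
            desc_pos = ":".join(str(int((b == l).sum())) for l in levels)
        else:
            raise ValueError(f"unknown test {test!r} for covariate {cov!r}")
        rows.append(
            {
                "covariate": cov,
                "test": res.name,
                "marker_negative": desc_neg,
                "marker_positive": desc_pos,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
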