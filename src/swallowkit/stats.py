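"""Group-comparison statistics: two-sample t-tests and two-way ANOVA.

Mirrors the study's statistical workflow: classic equal-variance independent
two-sample t-tests per metric (Welch available via flag), variability
reported as mean +/- SEM, two-sided p with significance at alpha = 0.05,
normality screened (reported, never auto-switched), outliers flagged by the
1.5 IQR rule but retained. Mandible cardinal-point distances are assessed by
a two-way genotype x side ANOVA with interaction (type-II sums of squares on
the balanced layout). No multiple-testing correction is applied by default,
matching the original analysis; Benjamini-Hochberg is available explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def sem(values) -> float:
    """Standard error of the mean: sample SD (ddof=1) / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SEM requires n >= 2")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def _iqr_outliers(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


@dataclass
class GroupComparison:
    """A two-group comparison of one metric."""

    metric: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    p: float
    significant: bool
    outliers_a: np.ndarray = field(repr=False, default=None)
    outliers_b: np.ndarray = field(repr=False, default=None)
    normality_p_a: float = float("nan")
    normality_p_b: float = float("nan")


def compare_groups(
    values_a,
    values_b,
    metric_name: str = "",
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Independent two-sample t-test with SEMs, outlier and normality report.

    Equal-variance (Student) by default; ``welch=True`` drops the pooled
    variance assumption. Outliers (beyond 1.5 IQR) are flagged but retained;
    Shapiro-Wilk p-values screen normality without switching the test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    norm_a = sps.shapiro(a).pvalue if a.size >= 3 and np.ptp(a) > 0 else float("nan")
    norm_b = sps.shapiro(b).pvalue if b.size >= 3 and np.ptp(b) > 0 else float("nan")
    return GroupComparison(
        metric=metric_name,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sem_a=sem(a),
        sem_b=sem(b),
        n_a=int(a.size),
        n_b=int(b.size),
        t=float(t),
        p=float(p),
        significant=bool(p <= alpha),
        outliers_a=_iqr_outliers(a),
        outliers_b=_iqr_outliers(b),
        normality_p_a=float(norm_a),
        normality_p_b=float(norm_b),
    )


@dataclass
class AnovaResult:
    """F and p per factor of a two-way layout with interaction."""

    f_genotype: float
    p_genotype: float
    f_side: float
    p_side: float
    f_interaction: float
    p_interaction: float
    table: pd.DataFrame = field(repr=False, default=None)


def two_way_anova(values, genotype, side) -> AnovaResult:
    """Two-way genotype x side ANOVA (type-II sums of squares).

    Each (genotype, side) cell needs >= 2 observations; an empty cell is an
    argument error.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": np.asarray(genotype),
            "side": np.asarray(side),
        }
    )
    cells = df.groupby(["genotype", "side"], observed=True).size()
    n_geno = df["genotype"].nunique()
    n_side = df["side"].nunique()
    if len(cells) < n_geno * n_side or (cells < 2).any():
        raise ValueError("every genotype x side cell needs >= 2 observations")

    model = smf.ols("value ~ C(genotype) * C(side)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return AnovaResult(
        f_genotype=float(table.loc["C(genotype)", "F"]),
        p_genotype=float(table.loc["C(genotype)", "PR(>F)"]),
        f_side=float(table.loc["C(side)", "F"]),
        p_side=float(table.loc["C(side)", "PR(>F)"]),
        f_interaction=float(table.loc["C(genotype):C(side)", "F"]),
        p_interaction=float(table.loc["C(genotype):C(side)", "PR(>F)"]),
        table=table,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (off by default in the group tables)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def group_table(
    per_mouse: pd.DataFrame,
    genotypes: pd.Series,
    group_a: str = "wt",
    group_b: str = "lgdel",
    welch: bool = False,
) -> pd.DataFrame:
    """Tidy per-metric comparison table.

    ``per_mouse`` holds one row per mouse and one column per metric;
    ``genotypes`` maps the same index to group labels (kept in a separate
    structure so genotype can stay blinded until this final stage). Output
    columns: metric, WT_mean, WT_sem, LgDel_mean, LgDel_sem, p.
    """
    rows = []
    for metric in per_mouse.columns:
        a = per_mouse.loc[genotypes == group_a, metric].dropna()
        b = per_mouse.loc[genotypes == group_b, metric].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        cmp = compare_groups(a, b, metric_name=metric, welch=welch)
        rows.append(
            {
                "metric": metric,
                "WT_mean": cmp.mean_a,
                "WT_sem": cmp.sem_a,
                "LgDel_mean": cmp.mean_b,
                "LgDel_sem": cmp.sem_b,
                "p": cmp.p,
            }
        )
    return pd.DataFrame(rows)
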