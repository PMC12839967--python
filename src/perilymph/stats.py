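"""Statistical reporting layer.

Reproduces the comparisons used on the pipeline's outputs: two-tailed
Student t tests (paired when samples come from the same animal), one-way
ANOVA with Tukey HSD post-hoc, and two-way ANOVA (condition × distance)
for profile data. The unit of analysis is the per-mouse average —
image-level values never enter a test directly. Normality is assumed, not
tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_two", "anova", "anova_oneway", "anova_twoway"]


@dataclass
class ComparisonResult:
    """One statistical comparison, tidy enough for a results table."""

    test: str
    grouping: str
    effect: float  # difference of means (x - y)
    statistic: float
    df: float
    pvalue: float
    n: tuple[int, ...]
    paired: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "grouping": self.grouping,
            "effect": self.effect,
            "statistic": self.statistic,
            "df": self.df,
            "pvalue": self.pvalue,
            "n": "/".join(str(k) for k in self.n),
            "paired": self.paired,
        }


def compare_two(x, y, paired: bool = False, grouping: str = "") -> ComparisonResult:
    """Two-tailed Student t test between two groups of per-unit values.

    Unpaired uses the pooled-variance statistic; paired operates on
    within-unit differences (values must be aligned by unit). Zero
    variance where the statistic is undefined raises instead of returning
    a misleading p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    effect = float(np.mean(x) - np.mean(y))
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal group sizes aligned by unit")
        d = x - y
        sd = float(np.std(d, ddof=1))
        if sd == 0:
            raise ValueError("degenerate paired test: all within-unit differences equal")
        n = len(d)
        t = float(np.mean(d)) / (sd / np.sqrt(n))
        df = n - 1
    else:
        nx, ny = len(x), len(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if pooled == 0:
            raise ValueError("degenerate unpaired test: zero variance in both groups")
        t = effect / np.sqrt(pooled * (1 / nx + 1 / ny))
        df = nx + ny - 2
    p = float(2 * sps.t.sf(abs(t), df))
    return ComparisonResult(
        test="paired t" if paired else "unpaired t",
        grouping=grouping,
        effect=effect,
        statistic=float(t),
        df=float(df),
        pvalue=p,
        n=(len(x), len(y)),
        paired=paired,
    )


@dataclass
class AnovaResult:
    """F test plus optional Tukey HSD pairwise table."""

    design: str
    table: pd.DataFrame  # one row per F test (effect, F, df, p)
    posthoc: pd.DataFrame | None = None

    @property
    def pvalue(self) -> float:
        return float(self.table["pvalue"].iloc[0])

    @property
    def statistic(self) -> float:
        return float(self.table["F"].iloc[0])


def anova_oneway(groups: dict[str, np.ndarray], posthoc: bool = False) -> AnovaResult:
    """Ordinary one-way ANOVA across ≥2 groups, optional Tukey HSD."""
    names = list(groups)
    arrs = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrs) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    f, p = sps.f_oneway(*arrs)
    df_b = len(arrs) - 1
    df_w = sum(len(a) for a in arrs) - len(arrs)
    table = pd.DataFrame(
        [{"effect": "group", "F": float(f), "df1": df_b, "df2": df_w, "pvalue": float(p)}]
    )
    post = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrs)
        labels = np.concatenate([[k] * len(a) for k, a in zip(names, arrs)])
        res = pairwise_tukeyhsd(values, labels)
        post = pd.DataFrame(
            res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        )
    return AnovaResult(design="one-way", table=table, posthoc=post)


def anova_twoway(
    data: pd.DataFrame,
    value: str = "value",
    factors: tuple[str, str] = ("condition", "distance"),
    posthoc: bool = False,
) -> AnovaResult:
    """Two-way ANOVA with interaction on a tidy per-unit table.

    Intended for per-mouse profile values with factors condition and
    distance bin; every cell of the design must contain ≥1 unit.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    data = data.dropna(subset=[value]).copy()
    cells = data.groupby([fa, fb], observed=True).size()
    n_a, n_b = data[fa].nunique(), data[fb].nunique()
    if len(cells) < n_a * n_b or (cells < 1).any():
        raise ValueError("two-way design has empty cells")
    data = data.rename(columns={value: "_y", fa: "_a", fb: "_b"})
    fit = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    rows = []
    rename = {"C(_a)": fa, "C(_b)": fb, "C(_a):C(_b)": f"{fa}:{fb}"}
    df_resid = float(tab.loc["Residual", "df"])
    for key, label in rename.items():
        rows.append(
            {
                "effect": label,
                "F": float(tab.loc[key, "F"]),
                "df1": float(tab.loc[key, "df"]),
                "df2": df_resid,
                "pvalue": float(tab.loc[key, "PR(>F)"]),
            }
        )
    post = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = data["_a"].astype(str) + ":" + data["_b"].astype(str)
        res = pairwise_tukeyhsd(data["_y"].to_numpy(), labels.to_numpy())
        post = pd.DataFrame(
            res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        )
    return AnovaResult(design="two-way", table=pd.DataFrame(rows), posthoc=post)


def anova(
    groups=None,
    design: str = "one-way",
    data: pd.DataFrame | None = None,
    value: str = "value",
    factors: tuple[str, str] = ("condition", "distance"),
    posthoc: bool = False,
) -> AnovaResult:
    """Dispatch to :func:`anova_oneway` (dict of groups) or :func:`anova_twoway`."""
    if design == "one-way":
        if groups is None:
            raise ValueError("one-way design needs groups={name: values}")
        return anova_oneway(groups, posthoc=posthoc)
    if design == "two-way":
        if data is None:
            raise ValueError("two-way design needs a tidy data frame")
        return anova_twoway(data, value=value, factors=factors, posthoc=posthoc)
    raise ValueError(f"unknown design {design!r}")
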