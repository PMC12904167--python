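"""Group-comparison statistics used by the morphometry pipeline.

Supported designs mirror the study's analysis battery: Student's and paired
t tests, one-way ANOVA with Tukey HSD post hocs, two-way ANOVA (Type II sums
of squares for unbalanced layouts) and two-way repeated-measures ANOVA, both
with Fisher's LSD post hoc comparisons within each factor level.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM


class TestResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    test: str
    statistic: float
    df: tuple[float, ...]  # (df,) for t tests, (df1, df2) per effect for ANOVA
    p_value: float
    direction: Optional[str] = None  # sign of the leading effect, when defined
    effects: Optional[dict[str, dict[str, float]]] = None  # per-effect F/df/p
    posthoc: Optional[list[dict]] = None


def _check_variance(*groups: np.ndarray) -> None:
    for g in groups:
        if len(g) > 1 and np.allclose(np.var(g), 0.0) and all(
            np.allclose(np.var(h), 0.0) for h in groups
        ):
            raise ValueError(
                "all groups have zero within-group variance; the t statistic "
                "is undefined"
            )


def t_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    _check_variance(a, b)
    res = sps.ttest_ind(a, b, equal_var=True)
    direction = "increase" if b.mean() > a.mean() else (
        "decrease" if b.mean() < a.mean() else "none"
    )
    return TestResult(
        test="t",
        statistic=float(res.statistic),
        df=(float(len(a) + len(b) - 2),),
        p_value=float(res.pvalue),
        direction=direction,
    )


def paired_t_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b):
        raise ValueError("paired t test requires complete pairs")
    d = b - a
    if np.allclose(d.var(), 0.0) and not np.allclose(d.mean(), 0.0):
        raise ValueError("zero variance of the paired differences")
    res = sps.ttest_rel(a, b)
    stat = 0.0 if np.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    direction = "increase" if d.mean() > 0 else ("decrease" if d.mean() < 0 else "none")
    return TestResult(
        test="paired_t",
        statistic=stat,
        df=(float(len(a) - 1),),
        p_value=p,
        direction=direction,
    )


def one_way_anova(data: pd.DataFrame, value: str, group: str) -> TestResult:
    groups = [g[value].to_numpy(float) for _, g in data.groupby(group, observed=True)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA requires at least two groups")
    res = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    tukey = sps.tukey_hsd(*groups)
    names = [str(name) for name, _ in data.groupby(group, observed=True)]
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            posthoc.append(
                {
                    "comparison": f"{names[i]} vs {names[j]}",
                    "method": "tukey_hsd",
                    "statistic": float(tukey.statistic[i, j]),
                    "p_value": float(tukey.pvalue[i, j]),
                }
            )
    return TestResult(
        test="anova1",
        statistic=float(res.statistic),
        df=(float(k - 1), float(n - k)),
        p_value=float(res.pvalue),
        posthoc=posthoc,
    )


def _fisher_lsd(
    data: pd.DataFrame,
    value: str,
    compare: str,
    within: str,
    mse: float,
    df_resid: float,
) -> list[dict]:
    """Fisher's LSD: pooled-MSE t tests between levels of ``compare``,
    separately within each level of ``within``."""
    out = []
    for w, sub in data.groupby(within, observed=True):
        levels = [(str(lv), g[value].to_numpy(float)) for lv, g in sub.groupby(compare, observed=True)]
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                (na, a), (nb, b) = levels[i], levels[j]
                se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
                t = (a.mean() - b.mean()) / se
                p = 2 * sps.t.sf(abs(t), df_resid)
                out.append(
                    {
                        "comparison": f"{na} vs {nb} within {within}={w}",
                        "method": "fisher_lsd",
                        "statistic": float(t),
                        "p_value": float(p),
                    }
                )
    return out


def two_way_anova(
    data: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> TestResult:
    """Two-way ANOVA with interaction; Type II sums of squares.

    Type II is used so unbalanced layouts test each main effect adjusted for
    the other (but not for the interaction).  Post hocs are Fisher's LSD for
    each factor within the levels of the other, using the model's MSE.
    """
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    effects = {}
    name_map = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    df_resid = float(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / df_resid)
    for key, pretty in name_map.items():
        effects[pretty] = {
            "F": float(table.loc[key, "F"]),
            "df1": float(table.loc[key, "df"]),
            "df2": df_resid,
            "p_value": float(table.loc[key, "PR(>F)"]),
        }
    posthoc = _fisher_lsd(data, value, factor_a, factor_b, mse, df_resid)
    posthoc += _fisher_lsd(data, value, factor_b, factor_a, mse, df_resid)
    lead = effects[factor_a]
    return TestResult(
        test="anova2",
        statistic=lead["F"],
        df=(lead["df1"], lead["df2"]),
        p_value=lead["p_value"],
        effects=effects,
        posthoc=posthoc,
    )


def two_way_rm_anova(
    data: pd.DataFrame,
    value: str,
    subject: str,
    within: str,
    between: str | None = None,
) -> TestResult:
    """Two-way repeated-measures ANOVA (complete within-subject layouts).

    With ``between=None`` both factors are within-subject and the model is a
    standard two-way RM ANOVA.  Fisher's LSD post hocs compare the levels of
    ``within`` inside each level of the other factor.
    """
    if between is None:
        factors = [within]
    else:
        factors = [within, between]
    counts = data.groupby([subject], observed=True).size()
    if counts.nunique() > 1:
        raise ValueError("repeated-measures ANOVA requires complete pairs")
    res = AnovaRM(
        data, depvar=value, subject=subject, within=factors
    ).fit()
    table = res.anova_table
    effects = {
        str(ix): {
            "F": float(row["F Value"]),
            "df1": float(row["Num DF"]),
            "df2": float(row["Den DF"]),
            "p_value": float(row["Pr > F"]),
        }
        for ix, row in table.iterrows()
    }
    lead = effects[within]
    resid_df = lead["df2"]
    # pooled error from the within-factor stratum for LSD comparisons
    sub_means = data.groupby([subject, within], observed=True)[value].mean().unstack()
    diffs = sub_means.to_numpy()
    mse = float(np.nanvar(diffs - diffs.mean(axis=1, keepdims=True), ddof=1))
    posthoc = None
    if between is not None:
        posthoc = _fisher_lsd(data, value, within, between, mse, resid_df)
    return TestResult(
        test="anova2_rm",
        statistic=lead["F"],
        df=(lead["df1"], lead["df2"]),
        p_value=lead["p_value"],
        effects=effects,
        posthoc=posthoc,
    )


def compare_groups(design: str, data: pd.DataFrame, **kwargs) -> TestResult:
    """Dispatch a group comparison by design name.

    ``design`` is one of ``t``, ``paired_t``, ``anova1``, ``anova2``,
    ``anova2_rm``.  Column names are passed as keyword arguments
    (``value``, ``group``, ``factor_a``, ``factor_b``, ``subject``,
    ``within``, ``between``); ``t``/``paired_t`` expect ``value`` plus
    ``group`` with exactly two levels.
    """
    if design in ("t", "paired_t"):
        value = kwargs.get("value", "value")
        group = kwargs.get("group", "group")
        names = [str(n) for n, _ in data.groupby(group, observed=True)]
        levels = [g for _, g in data.groupby(group, observed=True)]
        if len(levels) != 2:
            raise ValueError(f"{design} requires exactly two groups")
        a, b = (lv[value].to_numpy(float) for lv in levels)
        res = t_test(a, b) if design == "t" else paired_t_test(a, b)
        if res.direction == "increase":
            res.direction = f"{names[1]} > {names[0]}"
        elif res.direction == "decrease":
            res.direction = f"{names[1]} < {names[0]}"
        return res
    if design == "anova1":
        return one_way_anova(
            data, kwargs.get("value", "value"), kwargs.get("group", "group")
        )
    if design == "anova2":
        return two_way_anova(
            data,
            kwargs.get("value", "value"),
            kwargs.get("factor_a", "group"),
            kwargs.get("factor_b", "rapamycin"),
        )
    if design == "anova2_rm":
        return two_way_rm_anova(
            data,
            kwargs.get("value", "value"),
            kwargs.get("subject", "subject"),
            kwargs.get("within", "roi_class"),
            kwargs.get("between"),
        )
    raise ValueError(f"unknown design {design!r}")
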