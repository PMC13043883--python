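"""Clinical comparisons and stage-adjusted models.

Group comparisons use Mann-Whitney U for continuous variables and Pearson
chi-square for categorical ones; subtype differences are additionally
checked with a stage-adjusted ANCOVA (outcome ~ subtype + stage +
subtype:stage, type-II sums of squares), and within-subtype stage-clinical
gradients with OLS adjusting for age and sex.  Missing values are dropped
row-wise per variable and the analysed n always accompanies the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "ancova_stage_adjusted",
    "stage_clinical_regression",
]


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    n: int
    group_summary: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        # parametric p-values may underflow to exactly 0.0
        if not (0 <= self.p_value <= 1) and not np.isnan(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _two_groups(values: pd.Series, labels: pd.Series):
    df = pd.DataFrame({"v": values, "g": labels}).dropna()
    groups = df["g"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, found {len(groups)}")
    a = df.loc[df["g"] == groups[0], "v"]
    b = df.loc[df["g"] == groups[1], "v"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group is empty after removing missing rows")
    return groups, a, b, len(df)


def compare_groups(
    values, labels, variable: str = "", categorical: bool | None = None,
    exact_max_n: int = 12, yates: bool = False,
) -> ComparisonResult:
    """Two-group comparison: Mann-Whitney U (continuous) or chi-square (categorical).

    The U test uses the normal approximation with tie correction, switching
    to the exact null when both groups have <= ``exact_max_n`` observations
    and no ties.  Chi-square is Pearson's without Yates correction unless
    requested.  Categorical inputs are auto-detected from dtype when
    ``categorical`` is None.
    """
    values = pd.Series(values)
    labels = pd.Series(labels)
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(values)
    if categorical:
        df = pd.DataFrame({"v": values, "g": labels}).dropna()
        table = pd.crosstab(df["v"], df["g"])
        if table.shape[1] != 2 or (table.sum(axis=0) == 0).any():
            raise ValueError("need two non-empty groups")
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=yates)
        summary = {str(g): table[g].to_dict() for g in table.columns}
        return ComparisonResult(variable, "chi-square", float(chi2), float(p),
                                int(table.to_numpy().sum()), summary)
    groups, a, b, n = _two_groups(values, labels)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    summary = {
        str(groups[0]): {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1)) if len(a) > 1 else np.nan},
        str(groups[1]): {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1)) if len(b) > 1 else np.nan},
    }
    return ComparisonResult(variable, f"mann-whitney-u ({method})",
                            float(res.statistic), float(res.pvalue), n, summary)


def ancova_stage_adjusted(
    outcome, subtype, stage, variable: str = ""
) -> ComparisonResult:
    """ANCOVA: outcome ~ subtype + stage + subtype:stage, type-II SS.

    Reports the subtype main effect together with the stage main effect and
    the stage-by-subtype interaction, used to rule out stage as a confound
    of a subtype difference.
    """
    df = pd.DataFrame({
        "y": np.asarray(outcome, dtype=float),
        "subtype": pd.Categorical(subtype),
        "stage": np.asarray(stage, dtype=float),
    }).dropna()
    if df["subtype"].nunique() < 2:
        raise ValueError("need at least two subtypes for ANCOVA")
    n_params = 2 * df["subtype"].nunique()
    if len(df) <= 5 + n_params:
        raise ValueError(f"too few rows ({len(df)}) for stage-adjusted ANCOVA")
    fit = smf.ols("y ~ C(subtype) * stage", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    extra = {
        "stage_F": float(table.loc["stage", "F"]),
        "stage_p": float(table.loc["stage", "PR(>F)"]),
        "interaction_F": float(table.loc["C(subtype):stage", "F"]),
        "interaction_p": float(table.loc["C(subtype):stage", "PR(>F)"]),
    }
    return ComparisonResult(
        variable, "ancova (type II)",
        float(table.loc["C(subtype)", "F"]), float(table.loc["C(subtype)", "PR(>F)"]),
        len(df), {}, extra,
    )


def stage_clinical_regression(
    outcome, stage, age, sex, variable: str = ""
) -> ComparisonResult:
    """OLS of a clinical score on stage, adjusting for age and sex.

    Returns the stage coefficient (score units per stage) with its
    two-sided p; sex enters as a female indicator.
    """
    sex = pd.Series(sex)
    female = (sex == "female").astype(float) if sex.dtype == object else sex.astype(float)
    df = pd.DataFrame({
        "y": np.asarray(outcome, dtype=float),
        "stage": np.asarray(stage, dtype=float),
        "age": np.asarray(age, dtype=float),
        "female": female.to_numpy(),
    }).dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete rows, got {len(df)}")
    if df["stage"].nunique() < 2:
        raise ValueError("stage is constant; regression undefined")
    X = sm.add_constant(df[["stage", "age", "female"]])
    fit = sm.OLS(df["y"], X).fit()
    return ComparisonResult(
        variable, "ols stage regression",
        float(fit.params["stage"]), float(fit.pvalues["stage"]), len(df),
        {}, {"beta_stage": float(fit.params["stage"]),
             "se_stage": float(fit.bse["stage"]),
             "r_squared": float(fit.rsquared)},
    )
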