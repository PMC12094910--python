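"""Group-comparison statistics on per-trial and per-animal metrics.

Trial-level metrics are compared across disease groups with a linear mixed
model carrying a random intercept per animal (trials are nested within
animals, and the grouping factor varies between animals).  Because the group
factor varies only between animals, its correct error stratum is the animal
level: the overall group test uses the between-animal mean square with
``n_animals - n_groups`` denominator degrees of freedom — for balanced
designs this is exactly the test a Satterthwaite or containment df rule
yields from the mixed model, and it stays exactly calibrated at small animal
counts where REML variance truncation makes naive Wald tests conservative.
Pairwise group contrasts on the marginal means are Tukey-adjusted with the
studentized range at the same df.  Variance components are reported from the
REML fit.

Per-animal behavioral metrics go through a Shapiro–Wilk normality gate:
one-way ANOVA (plus Tukey post hoc when significant) if residuals look
normal, Kruskal–Wallis otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import InputError

__all__ = ["LmmResult", "fit_group_lmm", "compare_trial_trends", "behavior_anova"]

ALPHA = 0.05  # study-wide significance threshold


@dataclass
class LmmResult:
    """Fitted mixed-model comparison of a trial metric across groups."""

    response: str
    group_means: pd.Series
    overall: Dict[str, float]  # f_stat, df_num, df_den, p_value
    contrasts: pd.DataFrame  # pair, estimate, se, q, p_tukey
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_animals: int
    converged: bool = True
    degenerate: bool = False
    notes: List[str] = field(default_factory=list)

    @property
    def p_value(self) -> float:
        return self.overall["p_value"]

    def summary(self) -> str:
        lines = [
            f"Linear mixed model: {self.response} ~ group + (1 | animal)",
            f"  observations: {self.n_obs}, animals: {self.n_animals}",
            f"  random-intercept variance: {self.random_intercept_var:.4g}, "
            f"residual variance: {self.residual_var:.4g}",
            "  group marginal means:",
        ]
        for g, m in self.group_means.items():
            lines.append(f"    {g}: {m:.4g}")
        o = self.overall
        lines.append(
            f"  overall group effect: F({o['df_num']:.0f}, {o['df_den']:.0f}) = "
            f"{o['f_stat']:.3f}, p = {o['p_value']:.4g}"
        )
        lines.append("  Tukey-adjusted pairwise contrasts:")
        for _, row in self.contrasts.iterrows():
            lines.append(
                f"    {row['pair']}: diff = {row['estimate']:.4g} "
                f"(SE {row['se']:.4g}), p = {row['p_tukey']:.4g}"
            )
        if self.degenerate:
            lines.append("  [degenerate fit] " + "; ".join(self.notes))
        elif not self.converged:
            lines.append("  [did not converge] " + "; ".join(self.notes))
        return "\n".join(lines)


def fit_group_lmm(
    table: pd.DataFrame,
    response: str,
    group_col: str = "group",
    animal_col: str = "animal_id",
    reml: bool = True,
) -> LmmResult:
    """Fit ``response ~ group`` with a random intercept per animal.

    The REML mixed-model fit supplies the variance components; the overall
    group test and Tukey contrasts are carried out in the animal stratum
    (between-animal mean square, ``n_animals - n_groups`` df), which for this
    between-animal factor is the exact small-sample test the mixed model's
    Satterthwaite df reduce to on balanced data.

    Requires at least two groups and two animals per group, and a finite
    response.  A constant response yields a flagged degenerate result rather
    than an exception.
    """
    df = table[[response, group_col, animal_col]].dropna().copy()
    if not np.all(np.isfinite(df[response])):
        raise InputError(f"{response} contains non-finite values")
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise InputError("group comparison needs at least two groups")
    per_group = df.groupby(group_col)[animal_col].nunique()
    if (per_group < 2).any():
        raise InputError("each group needs at least two animals")
    n_animals = df[animal_col].nunique()
    k = len(groups)
    if n_animals - k < 1:
        raise InputError("not enough animals for the between-animal group test")

    group_means = df.groupby(group_col)[response].mean()
    if df[response].std() < 1e-12:
        return LmmResult(
            response=response,
            group_means=group_means,
            overall={
                "f_stat": 0.0,
                "df_num": k - 1,
                "df_den": n_animals - k,
                "p_value": 1.0,
            },
            contrasts=pd.DataFrame(
                columns=["pair", "estimate", "se", "q", "p_tukey"]
            ),
            random_intercept_var=0.0,
            residual_var=0.0,
            n_obs=len(df),
            n_animals=n_animals,
            converged=True,
            degenerate=True,
            notes=["response is constant; zero variance, no test performed"],
        )

    notes: List[str] = []
    re_var = res_var = np.nan
    converged = True
    try:
        with warnings.catch_warnings():
            # boundary warnings (random-intercept variance -> 0) are expected
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(
                f"{response} ~ C({group_col})", df, groups=df[animal_col]
            )
            fit = model.fit(reml=reml)
        converged = bool(getattr(fit, "converged", True))
        re_var = float(fit.cov_re.iloc[0, 0])
        res_var = float(fit.scale)
        if not converged:
            notes.append("optimizer did not report convergence")
    except np.linalg.LinAlgError as exc:
        converged = False
        notes.append(f"REML variance estimation failed ({exc}); "
                     "variance components unavailable")

    # animal-stratum test: the group factor varies between animals, so the
    # between-animal mean square is its error term (see module docstring)
    animal_means = (
        df.groupby([group_col, animal_col])[response].mean().reset_index()
    )
    gm = animal_means.groupby(group_col)[response]
    means = gm.mean().reindex(groups).to_numpy()
    sizes = gm.size().reindex(groups).to_numpy()
    grand = animal_means[response].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(
        ((animal_means[response] - gm.transform("mean")) ** 2).sum()
    )
    df_den = n_animals - k
    ms_within = ss_within / df_den
    degenerate = False
    if ms_within < 1e-14:
        degenerate = True
        notes.append("zero between-animal variance; stratum test degenerate")
        f_stat, p_overall = 0.0, 1.0
    else:
        f_stat = (ss_between / (k - 1)) / ms_within
        p_overall = float(sps.f.sf(f_stat, k - 1, df_den))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = float(np.sqrt(ms_within * (1 / sizes[i] + 1 / sizes[j])))
            q = abs(diff) / (se / np.sqrt(2)) if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_den))
            rows.append(
                {
                    "pair": f"{groups[j]} - {groups[i]}",
                    "estimate": float(diff),
                    "se": se,
                    "q": q,
                    "p_tukey": min(1.0, p),
                }
            )

    return LmmResult(
        response=response,
        group_means=pd.Series(means, index=groups),
        degenerate=degenerate,
        overall={
            "f_stat": f_stat,
            "df_num": k - 1,
            "df_den": df_den,
            "p_value": p_overall,
        },
        contrasts=pd.DataFrame(rows),
        random_intercept_var=re_var,
        residual_var=res_var,
        n_obs=len(df),
        n_animals=n_animals,
        converged=converged,
        notes=notes,
    )


def compare_trial_trends(
    table: pd.DataFrame,
    y: str,
    x: str = "trial_id",
    group_col: str = "group",
) -> dict:
    """Per-group Pearson correlation of a metric with trial number, plus
    slope/intercept homogeneity tests across groups.

    Fits ``y ~ x * group`` by OLS; the interaction F test assesses common
    slope, and — when slopes are homogeneous at alpha — a second fit
    ``y ~ x + group`` tests intercept differences.
    """
    df = table[[y, x, group_col]].dropna().copy()
    out = {"per_group": {}, "slope_test": None, "intercept_test": None}
    for g, sub in df.groupby(group_col):
        if sub[x].nunique() < 3:
            raise InputError(f"group {g!r} has fewer than 3 distinct {x} values")
        if sub[x].std() == 0:
            raise InputError(f"group {g!r} has zero variance in {x}")
        r, p = sps.pearsonr(sub[x], sub[y])
        slope, intercept = np.polyfit(sub[x], sub[y], 1)
        out["per_group"][g] = {
            "r": float(r),
            "p": float(p),
            "slope": float(slope),
            "intercept": float(intercept),
            "n": len(sub),
        }

    full = smf.ols(f"{y} ~ {x} * C({group_col})", df).fit()
    no_int = smf.ols(f"{y} ~ {x} + C({group_col})", df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp_slopes = sm.stats.anova_lm(no_int, full)
    f_sl = float(cmp_slopes["F"].iloc[1])
    p_sl = float(cmp_slopes["Pr(>F)"].iloc[1])
    out["slope_test"] = {"f_stat": f_sl, "p_value": p_sl}

    if p_sl > ALPHA:
        common = smf.ols(f"{y} ~ {x}", df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_int = sm.stats.anova_lm(common, no_int)
        out["intercept_test"] = {
            "f_stat": float(cmp_int["F"].iloc[1]),
            "p_value": float(cmp_int["Pr(>F)"].iloc[1]),
        }
    return out


def behavior_anova(
    per_animal: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
) -> dict:
    """Shapiro-gated group comparison of one-value-per-animal metrics.

    Residuals from the group means pass through a Shapiro–Wilk test at
    alpha = 0.05: one-way ANOVA if normal (Tukey post hoc when significant),
    Kruskal–Wallis otherwise.  Constant data yield a flagged degenerate
    result with no rejection.
    """
    df = per_animal[[value_col, group_col]].dropna()
    counts = df.groupby(group_col).size()
    if len(counts) < 2:
        raise InputError("need at least two groups")
    if (counts < 2).any():
        raise InputError("every group needs at least two animals")

    samples = [sub[value_col].to_numpy() for _, sub in df.groupby(group_col)]
    if df[value_col].std() < 1e-12:
        return {
            "test": "degenerate",
            "p_value": 1.0,
            "significant": False,
            "normality_p": None,
            "posthoc": None,
            "notes": ["all values equal; no test performed"],
        }

    resid = np.concatenate(
        [s - s.mean() for s in samples]
    )
    try:
        sw_stat, sw_p = sps.shapiro(resid)
    except ValueError:
        sw_p = 0.0  # unusable residuals: fall through to the rank test
    result: dict
    if sw_p > ALPHA:
        f_stat, p = sps.f_oneway(*samples)
        result = {
            "test": "anova",
            "statistic": float(f_stat),
            "p_value": float(p),
            "normality_p": float(sw_p),
        }
        if p <= ALPHA:
            tk = pairwise_tukeyhsd(
                df[value_col].to_numpy(), df[group_col].to_numpy(), alpha=ALPHA
            )
            result["posthoc"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
        else:
            result["posthoc"] = None
    else:
        h_stat, p = sps.kruskal(*samples)
        result = {
            "test": "kruskal",
            "statistic": float(h_stat),
            "p_value": float(p),
            "normality_p": float(sw_p),
            "posthoc": None,
        }
    result["significant"] = result["p_value"] <= ALPHA
    return result
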