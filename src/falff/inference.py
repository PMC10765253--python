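"""Two-way ANCOVA on regional fALFF z-scores and noncentral-F power analysis.

The group-level model is an ordinary least-squares ANCOVA

    mean_z ~ group + region + group:region + age + bmi + sex

with blood-pressure group (2 levels) and brain region (R levels) as factors
and age, BMI and sex as continuous covariates.  Participant-by-region rows
are treated as independent observations, reproducing the classical
regional-ANCOVA design (within-participant correlation is acknowledged, not
modelled; a mixed-effects extension is out of scope here).  Type-II sums of
squares are the default because they are invariant to term order and the
designs of interest are near-balanced; Type I and III are available as a
switch.

Effect sizes are reported as partial eta-squared,
``SS_term / (SS_term + SS_residual)``.  Prospective power for an F test of a
term with numerator df ``df1`` and Cohen's effect size f uses the noncentral
F distribution with noncentrality ``lambda = f^2 * N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DesignError, ParameterError

__all__ = [
    "AncovaResult",
    "PowerQuery",
    "bonferroni_alpha",
    "fit_ancova",
    "partial_eta_squared",
    "power_f_test",
    "required_n",
]

ANCOVA_FORMULA = "mean_z ~ C(group) * C(region) + age + bmi + sex"

#: Pretty names for the model terms, in reporting order.
TERM_LABELS = {
    "C(group)": "group",
    "C(region)": "region",
    "C(group):C(region)": "group:region",
    "age": "age",
    "bmi": "bmi",
    "sex": "sex",
}


@dataclass
class AncovaResult:
    """Per-term F statistics from a fitted ANCOVA.

    ``table`` has one row per model term with columns
    ``term, ss, df1, df2, F, p_value, partial_eta2``; the residual sum of
    squares and df are kept for reuse in effect-size computations.
    """

    table: pd.DataFrame
    ss_residual: float
    df_residual: float
    n_obs: int

    def term(self, name: str) -> pd.Series:
        hit = self.table[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r}; have {list(self.table['term'])}")
        return hit.iloc[0]

    def report(self) -> str:
        """Format each term as ``F(df1) = x, p = y, partial eta^2 = z``."""
        lines = []
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['term']:<14} F({int(row.df1)}) = {row.F:.2f}, "
                f"p = {row.p_value:.3g}, partial eta^2 = {row.partial_eta2:.4g}"
            )
        return "\n".join(lines)


def _check_full_rank(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns whose removal does not drop the rank (aliased)
        aliased = []
        for j, name in enumerate(model.exog_names):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(name)
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} of {exog.shape[1]}); "
            f"aliased columns: {aliased}",
            aliased=aliased,
        )


def fit_ancova(
    data: pd.DataFrame,
    formula: str = ANCOVA_FORMULA,
    ss_type: int = 2,
) -> AncovaResult:
    """Fit the two-way ANCOVA and tabulate F, p and partial eta-squared.

    ``data`` holds one row per participant-region observation with columns
    ``mean_z, group, region, age, bmi, sex`` (sex numeric, male = 1).
    ``ss_type`` selects the sums-of-squares decomposition (1, 2 or 3);
    Type II is the default.
    """
    if ss_type not in (1, 2, 3):
        raise ParameterError(f"ss_type must be 1, 2 or 3, got {ss_type}")
    data = data.copy()
    if data["sex"].dtype == object:
        from .cohort import _sex_numeric

        data["sex"] = _sex_numeric(data["sex"])
    model = smf.ols(formula, data=data)
    _check_full_rank(model)
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=ss_type)
    ss_col = "sum_sq" if "sum_sq" in anova else "ss"
    ss_resid = float(anova.loc["Residual", ss_col])
    df_resid = float(anova.loc["Residual", "df"])
    rows = []
    for raw_name, label in TERM_LABELS.items():
        if raw_name not in anova.index:
            continue
        ss = float(anova.loc[raw_name, ss_col])
        df1 = float(anova.loc[raw_name, "df"])
        f_stat = float(anova.loc[raw_name, "F"])
        p = float(anova.loc[raw_name, "PR(>F)"])
        rows.append(
            {
                "term": label,
                "ss": ss,
                "df1": df1,
                "df2": df_resid,
                "F": f_stat,
                "p_value": p,
                "partial_eta2": partial_eta_squared(ss, ss_resid),
            }
        )
    return AncovaResult(pd.DataFrame(rows), ss_resid, df_resid, int(fit.nobs))


def partial_eta_squared(ss_term: float, ss_residual: float) -> float:
    """Effect size ``SS_term / (SS_term + SS_residual)``."""
    if ss_term < 0 or ss_residual < 0:
        raise ParameterError("sums of squares must be nonnegative")
    if ss_term == 0 and ss_residual == 0:
        raise ParameterError("SS_term and SS_residual cannot both be zero")
    return ss_term / (ss_term + ss_residual)


def bonferroni_alpha(family_alpha: float, m_tests: int) -> float:
    """Per-test significance level controlling family-wise error over m tests.

    0.05 over a family of three tests gives 0.05/3 = 0.0167.
    """
    if not 0 < family_alpha < 1:
        raise ParameterError("family_alpha must be in (0, 1)")
    if m_tests < 1:
        raise ParameterError("m_tests must be at least 1")
    return family_alpha / m_tests


@dataclass(frozen=True)
class PowerQuery:
    """Inputs for prospective power of an F test in a 2 x R ANCOVA.

    ``effect_size_f`` is Cohen's f for the term of interest; ``df1`` its
    numerator degrees of freedom (R - 1 for the region main effect and the
    group-by-region interaction); ``n_covariates`` counts the continuous
    covariates in the model.
    """

    effect_size_f: float
    df1: int
    alpha: float = 0.05
    target_power: float = 0.8
    n_covariates: int = 3

    def __post_init__(self):
        if not self.effect_size_f > 0:
            raise ParameterError("effect size f must be positive")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ParameterError("target power must be in (0, 1)")
        if self.df1 < 1:
            raise ParameterError("df1 must be at least 1")


def _df2(q: PowerQuery, n_total: int) -> int:
    # model df spent besides the tested term: intercept (1) + group (1) +
    # region (df1, since both region and interaction carry R-1 df in the
    # 2 x R design) + covariates
    other = 2 + q.df1 + q.n_covariates
    return int(n_total) - q.df1 - other


def power_f_test(q: PowerQuery, n_total: int) -> float:
    """Power of the F test at total sample size ``n_total``.

    Noncentrality ``lambda = f^2 * n_total``; denominator df subtract the
    full model (intercept, both main effects, interaction, covariates).
    Power is P(F' > F_crit) under the noncentral F.
    """
    df2 = _df2(q, n_total)
    if df2 <= 0:
        raise ParameterError(
            f"n_total = {n_total} leaves no residual df (df2 = {df2})"
        )
    lam = q.effect_size_f**2 * n_total
    f_crit = stats.f.ppf(1 - q.alpha, q.df1, df2)
    return float(stats.ncf.sf(f_crit, q.df1, df2, lam))


def required_n(q: PowerQuery, n_cap: int = 10_000_000) -> int:
    """Smallest total N reaching the target power, by bracketed search.

    Doubles an upper bracket until the target is reached (error if not
    reached below ``n_cap``), then bisects to the minimal integer N.
    """
    lo = q.df1 + q.n_covariates + q.df1 + 3  # smallest N with df2 >= 1
    if power_f_test(q, lo) >= q.target_power:
        return lo
    hi = max(2 * lo, 16)
    while power_f_test(q, hi) < q.target_power:
        hi *= 2
        if hi > n_cap:
            raise ParameterError(
                f"target power {q.target_power} not reached below N = {n_cap}"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_f_test(q, mid) >= q.target_power:
            hi = mid
        else:
            lo = mid
    return hi
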