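"""Propensity-score matching of hypertensive and normotensive cohorts.

Age, sex and BMI all covary with blood pressure, so an observational contrast
of hypertensive against normotensive participants must first balance those
confounders.  The propensity score — the modelled probability of being
hypertensive given age, sex and BMI — is estimated by logistic regression;
greedy 1:1 nearest-neighbour matching on the logit of the score (without
replacement, treated units in descending propensity order, ties broken by id)
then selects a balanced normotensive control for each hypertensive where one
is available.  This mirrors the documented default behaviour of the R
``MatchIt`` package.

Balance diagnostics report, per covariate, group means, Welch t / chi-square
tests and the standardised mean difference (SMD) on the matched subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, SeparationError

__all__ = ["balance_table", "fit_propensity", "match", "smd"]

TREATED = "hypertensive"
CONTROL = "normotensive"
MATCH_COVARIATES = ("age", "sex", "bmi")

#: Sex coding used throughout: male = 1, female = 0.
SEX_CODES = {"male": 1.0, "female": 0.0}


def _sex_numeric(col: pd.Series) -> pd.Series:
    if col.dtype == object:
        unknown = set(col.unique()) - set(SEX_CODES)
        if unknown:
            raise DataError(f"unrecognised sex values: {sorted(unknown)}")
        return col.map(SEX_CODES).astype(float)
    return col.astype(float)


def _check_groups(table: pd.DataFrame) -> None:
    groups = set(table["group"].unique())
    if not groups <= {TREATED, CONTROL}:
        raise DataError(f"unrecognised group labels: {sorted(groups)}")
    if groups != {TREATED, CONTROL}:
        raise DataError("both hypertensive and normotensive groups are required")


def fit_propensity(
    table: pd.DataFrame, covariates: tuple[str, ...] = MATCH_COVARIATES
) -> pd.DataFrame:
    """Fit the propensity model and store fitted probabilities.

    Logistic regression (maximum likelihood) of the hypertension indicator on
    the covariates, with an intercept.  Returns a copy of the table with a
    ``propensity`` column.
    """
    _check_groups(table)
    if table[list(covariates)].isna().any().any():
        raise DataError("covariates must be complete for propensity fitting")
    exog = table[list(covariates)].copy()
    if "sex" in exog:
        exog["sex"] = _sex_numeric(exog["sex"])
    exog = exog.astype(float)
    # constant covariates are aliased with the intercept; drop them so the
    # model degrades gracefully to (at the limit) the intercept-only fit
    constant = [c for c in exog.columns if exog[c].nunique() == 1]
    exog = exog.drop(columns=constant)
    exog = sm.add_constant(exog, has_constant="add")
    endog = (table["group"] == TREATED).astype(float)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(endog, exog).fit(disp=False)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"propensity model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise SeparationError(
            "propensity model diverged (perfect separation suspected); "
            f"coefficients: {fit.params.to_dict()}"
        )
    out = table.copy()
    out["propensity"] = np.clip(fit.predict(exog), 1e-12, 1 - 1e-12)
    out.attrs["propensity_params"] = fit.params.to_dict()
    return out


def match(table: pd.DataFrame, caliper: float | None = None) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching on logit(propensity).

    Treated (hypertensive) units are processed in descending propensity
    order, each taking its nearest unused control; ties on distance or
    propensity are broken by id.  ``caliper`` is expressed as a multiple of
    the standard deviation of the logit propensity across the sample; pairs
    farther apart than the caliper are left unmatched.  Exhausting the donor
    pool leaves remaining treated units unmatched (flagged, not an error).

    Returns a copy with ``matched`` (bool) and ``pair_id`` (shared integer
    per matched pair, <NA> otherwise).
    """
    if "propensity" not in table:
        raise DataError("run fit_propensity before matching")
    out = table.copy().reset_index(drop=True)
    logit = np.log(out["propensity"] / (1 - out["propensity"])).to_numpy()
    max_dist = np.inf
    if caliper is not None:
        max_dist = caliper * float(np.std(logit, ddof=1))

    ids = out["id"].astype(str).to_numpy()
    treated_idx = np.flatnonzero((out["group"] == TREATED).to_numpy())
    control_idx = np.flatnonzero((out["group"] == CONTROL).to_numpy())
    # descending propensity, id as the deterministic tie-break
    treated_idx = sorted(
        treated_idx, key=lambda i: (-out["propensity"].iat[i], ids[i])
    )
    # controls sorted by id so argmin's first-hit rule breaks ties by id
    control_idx = np.array(sorted(control_idx, key=lambda i: ids[i]))
    control_logit = logit[control_idx]
    used = np.zeros(len(control_idx), dtype=bool)

    matched = np.zeros(len(out), dtype=bool)
    pair_id = np.full(len(out), -1)
    pair = 0
    for t in treated_idx:
        if used.all():
            break
        dist = np.abs(control_logit - logit[t])
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] > max_dist:
            continue
        used[j] = True
        c = control_idx[j]
        matched[[t, c]] = True
        pair_id[[t, c]] = pair
        pair += 1
    out["matched"] = matched
    out["pair_id"] = pd.array(
        [p if p >= 0 else pd.NA for p in pair_id], dtype="Int64"
    )
    return out


def smd(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardised mean difference with the pooled (average-variance) sd.

    For binary covariates the variances are the usual Bernoulli p(1-p)
    sample variances, so the same formula applies.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    pooled = np.sqrt((x1.var(ddof=1) + x2.var(ddof=1)) / 2.0)
    diff = x1.mean() - x2.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf
    return float(diff / pooled)


def balance_table(
    table: pd.DataFrame, matched_only: bool = True
) -> pd.DataFrame:
    """Covariate balance diagnostics in the style of a baseline table.

    Welch two-sample t-tests for age, BMI and blood pressures; a Pearson
    chi-square test without continuity correction for the sex proportion
    (the correction is omitted so the statistic equals the textbook
    contingency formula at these sample sizes).  One row per covariate with
    group mean +/- sd (proportion for sex), the test statistic, p-value and
    SMD.
    """
    data = table[table["matched"]] if matched_only else table
    rows = []
    for grp in (TREATED, CONTROL):
        if (data["group"] == grp).sum() == 0:
            raise DataError(f"no matched participants in group {grp!r}")
    continuous = [
        c for c in ("age", "bmi", "systolic", "diastolic") if c in data
    ]
    g1 = data[data["group"] == TREATED]
    g2 = data[data["group"] == CONTROL]
    for cov in continuous:
        t, p = stats.ttest_ind(g1[cov], g2[cov], equal_var=False)
        rows.append(
            {
                "covariate": cov,
                "hypertensive_mean": g1[cov].mean(),
                "hypertensive_sd": g1[cov].std(ddof=1),
                "normotensive_mean": g2[cov].mean(),
                "normotensive_sd": g2[cov].std(ddof=1),
                "statistic": float(t),
                "test": "welch_t",
                "p_value": float(p),
                "smd": smd(g1[cov], g2[cov]),
            }
        )
    if "sex" in data:
        s1 = _sex_numeric(g1["sex"])
        s2 = _sex_numeric(g2["sex"])
        contingency = np.array(
            [
                [s1.sum(), len(s1) - s1.sum()],
                [s2.sum(), len(s2) - s2.sum()],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
        rows.append(
            {
                "covariate": "sex",
                "hypertensive_mean": s1.mean(),
                "hypertensive_sd": s1.std(ddof=1),
                "normotensive_mean": s2.mean(),
                "normotensive_sd": s2.std(ddof=1),
                "statistic": float(chi2),
                "test": "chi_square",
                "p_value": float(p),
                "smd": smd(s1, s2),
            }
        )
    return pd.DataFrame(rows)


def render_balance_report(balance: pd.DataFrame) -> str:
    """Plain-text baseline-characteristics table."""
    lines = [
        f"{'covariate':<12}{'hypertensive':>20}{'normotensive':>20}"
        f"{'p-value':>12}{'SMD':>9}"
    ]
    for _, row in balance.iterrows():
        h = f"{row.hypertensive_mean:.2f} ± {row.hypertensive_sd:.2f}"
        n = f"{row.normotensive_mean:.2f} ± {row.normotensive_sd:.2f}"
        lines.append(
            f"{row.covariate:<12}{h:>20}{n:>20}{row.p_value:>12.3g}{row.smd:>9.3f}"
        )
    return "\n".join(lines)
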