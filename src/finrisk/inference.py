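"""Determinants of CHE, group comparison of OOP, and the design sample size.

The determinants model is a multivariate logistic regression of the CHE
indicator (by default at 10% of total consumption) on care and household
covariates: hospitalisation, wealth quintile (richest quintile as reference),
residence outside the capital, and care-seeking at a private facility.
Adjusted odds ratios are exponentiated maximum-likelihood coefficients with
Wald 95% confidence intervals.  Fits that fail to converge — perfect
separation, a single-class outcome — are reported as such, never silently
returned.

The one-way ANOVA compares total OOP between government and private care
(any private involvement counts as private).  The two-proportion sample-size
formula is

    n = (z_{alpha/2} + z_beta)^2 [p1(1-p1) + p2(1-p2)] / (p1 - p2)^2

per group, rounded up; critical values come from the normal quantile
function, with an option to use the conventional two-decimal roundings
(1.96, 0.84) instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .catastrophic import CheThreshold, che_summary
from .equity import assign_quintiles
from .survey import SurveyDataset

__all__ = [
    "DeterminantsResult",
    "AnovaResult",
    "SampleSizeSpec",
    "DEFAULT_COVARIATES",
    "fit_che_determinants",
    "oop_anova",
    "two_proportion_sample_size",
    "total_recruitment",
]

DEFAULT_COVARIATES = (
    "hospitalized",
    "quintile",
    "residence_outside",
    "private_facility",
)

#: Covariates the design matrix knows how to derive from a dataset.
_DERIVED_COVARIATES = {
    "hospitalized",
    "quintile",
    "residence_outside",
    "private_facility",
    "household_size",
}


@dataclass(frozen=True)
class DeterminantsResult:
    """Adjusted odds ratios with Wald 95% CIs from the logistic fit."""

    terms: list[dict]
    n_used: int
    converged: bool

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"terms": self.terms, "n_used": self.n_used, "converged": self.converged}


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class SampleSizeSpec:
    p1: float
    p2: float
    alpha: float
    power: float
    raw: float
    n_per_group: int

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "alpha": self.alpha,
            "power": self.power,
            "raw": self.raw,
            "n_per_group": self.n_per_group,
        }


def design_matrix(
    ds: SurveyDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Derive the covariate frame used by the determinants model.

    ``hospitalized``: any inpatient admission; ``private_facility``: any care
    at a private facility (private or mixed); ``residence_outside``: resident
    outside the capital; ``quintile``: wealth quintile indicators Q1..Q4 with
    Q5 (richest) as reference; ``household_size``: persons.
    """
    unknown = set(covariates) - _DERIVED_COVARIATES
    if unknown:
        raise ValueError(f"unknown covariate(s): {sorted(unknown)}")
    t = ds.table
    cols = {}
    if "hospitalized" in covariates:
        cols["hospitalized"] = (t["n_inpatient"] > 0).astype(float)
    if "residence_outside" in covariates:
        cols["residence_outside"] = (t["residence"] == "outside").astype(float)
    if "private_facility" in covariates:
        cols["private_facility"] = (t["facility_type"] != "public").astype(float)
    if "household_size" in covariates:
        cols["household_size"] = t["size"].astype(float)
    X = pd.DataFrame(cols, index=t.index)
    if "quintile" in covariates:
        q = assign_quintiles(ds).set_index("household_id")["quintile"]
        qvals = t["household_id"].map(q)
        for k in range(1, 5):
            X[f"quintile_{k}"] = (qvals == k).astype(float)
    return X


def fit_che_determinants(
    ds: SurveyDataset,
    threshold: CheThreshold = CheThreshold(0.10, "total_expenditure"),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> DeterminantsResult:
    """Fit the logistic determinants model for the CHE indicator."""
    summary = che_summary(ds, threshold)
    y = summary.indicators.set_index("household_id")["e"]
    X = design_matrix(ds, covariates)
    X.index = ds.table["household_id"]
    X = X.loc[y.index]
    n_used = len(y)
    if y.nunique() < 2:
        return DeterminantsResult(terms=[], n_used=n_used, converged=False)
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["intercept"] + list(X.columns)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y.to_numpy(dtype=float), Xc).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        bse = np.asarray(res.bse)
        if not np.all(np.isfinite(bse)):
            converged = False
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return DeterminantsResult(terms=[], n_used=n_used, converged=False)
    params = np.asarray(res.params)
    ci = np.asarray(res.conf_int(alpha=0.05))
    terms = [
        {
            "name": names[j],
            "aor": float(np.exp(params[j])),
            "ci_low": float(np.exp(ci[j, 0])),
            "ci_high": float(np.exp(ci[j, 1])),
            "coef": float(params[j]),
        }
        for j in range(len(names))
    ]
    return DeterminantsResult(terms=terms, n_used=n_used, converged=converged)


def oop_anova(ds: SurveyDataset, grouping: str = "facility_type_binary") -> AnovaResult:
    """One-way ANOVA of total OOP by place of care (government vs private)."""
    if grouping != "facility_type_binary":
        raise ValueError(f"unknown grouping {grouping!r}")
    from .costing import oop_totals

    t = ds.table
    oop = oop_totals(ds)["total_oop"].to_numpy(dtype=float)
    private = (t["facility_type"] != "public").to_numpy()
    groups = [oop[~private], oop[private]]
    return anova_oneway(groups)


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Standard one-way decomposition over ``k`` groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("each of >= 2 groups needs >= 2 observations")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    f, p = stats.f_oneway(*groups)
    return AnovaResult(
        f_statistic=float(f),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
    )


def two_proportion_sample_size(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    rounded_z: bool = False,
) -> SampleSizeSpec:
    """Per-group sample size to detect a difference between two proportions.

    With ``rounded_z`` the critical values are rounded to two decimals
    (1.96 and 0.84 at the defaults), reproducing textbook arithmetic.
    """
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(stats.norm.ppf(power))
    if rounded_z:
        z_a, z_b = round(z_a, 2), round(z_b, 2)
    raw = (z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
    return SampleSizeSpec(
        p1=p1, p2=p2, alpha=alpha, power=power, raw=raw, n_per_group=math.ceil(raw)
    )


def total_recruitment(n_per_group: int, n_strata: int, nonresponse_rate: float) -> int:
    """Total recruitment target: per-group n across strata, inflated for
    anticipated non-response."""
    if n_per_group < 1 or n_strata < 1:
        raise ValueError("counts must be positive")
    if not 0.0 <= nonresponse_rate < 1.0:
        raise ValueError("nonresponse_rate must lie in [0, 1)")
    return math.ceil(n_per_group * n_strata * (1.0 + nonresponse_rate))
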