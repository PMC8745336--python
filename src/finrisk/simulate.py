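"""Synthetic household-survey generator.

The study's microdata were never deposited, so every pipeline stage is
exercised on simulated surveys whose marginals reproduce the published
summary tables: household size a rounded, truncated-at-one normal (mean 4.5,
SD 2.1); annual household expenditure log-normal fitted to the published
mean ($2,520) and median ($2,050), which pins mu = ln(median) and
sigma = sqrt(2 ln(mean/median)); a Beta food share with mean 0.46; 59% of
patients resident outside the capital; 70% male; facility-type and
visit-pattern frequencies at their published counts.

Out-of-pocket costs are built per care episode: log-cost = log(base scale)
+ inpatient shift + private-facility shift + noise, summed over the
household's outpatient visits and inpatient admissions, scaled up for
out-of-town residence, and split across the seven expense categories by a
Dirichlet composition whose expectations follow the published category
means.  Multipliers act on the log scale, so e.g. the default private shift
of ln 6 makes private episode costs six times public ones in expectation.

Household size and log-expenditure share a Gaussian copula (default
correlation 0.5): consumption scales with household size, while both
marginals stay exactly as configured.  The joint dependence is not
identifiable from printed tables; see the methods note.

:func:`generate_with_known_truth` plants a known quantity — a target CHE
rate, or logistic coefficients on the CHE outcome — and returns the truth
record alongside the data, for parameter-recovery testing.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from . import published
from .catastrophic import CheThreshold, che_summary
from .costing import oop_totals
from .survey import COST_COLUMNS, HOUSEHOLD_COLUMNS, OOP_COLUMNS, SurveyDataset

__all__ = ["SyntheticParams", "default_params", "generate", "generate_with_known_truth"]

_N = published.N_ANALYSED


def _normed(counts: dict[str, float]) -> dict[str, float]:
    tot = sum(counts.values())
    return {k: v / tot for k, v in counts.items()}


class SyntheticParams(BaseModel):
    """All distributional knobs of the generator.

    Defaults reproduce the published marginals of the Addis Ababa survey
    (sample size 452); probabilities within a family must sum to one.
    """

    n_households: int = Field(default=_N, ge=1)
    seed: int = 0

    household_size_mean: float = Field(default=published.HOUSEHOLD_SIZE_MEAN, gt=0)
    household_size_sd: float = Field(default=published.HOUSEHOLD_SIZE_SD, gt=0)
    expenditure_mean: float = Field(default=published.EXPENDITURE_MEAN, gt=0)
    expenditure_median: float = Field(default=published.EXPENDITURE_MEDIAN, gt=0)
    size_expenditure_corr: float = Field(default=0.5, ge=-0.99, le=0.99)
    food_share_mean: float = Field(default=0.46, gt=0, lt=1)
    food_share_concentration: float = Field(default=20.0, gt=0)
    residence_outside_prob: float = Field(default=268 / _N, ge=0, le=1)
    male_prob: float = Field(default=published.MALE_N / _N, ge=0, le=1)

    facility_probs: dict[str, float] = Field(
        default_factory=lambda: _normed(published.FACILITY_COUNTS)
    )
    visit_type_probs: dict[str, float] = Field(
        default_factory=lambda: _normed(published.VISIT_TYPE_COUNTS)
    )
    diagnosis_probs: dict[str, float] = Field(
        default_factory=lambda: _normed(published.DIAGNOSIS_COUNTS)
    )

    extra_outpatient_rate: float = Field(default=1.5, ge=0)
    extra_inpatient_rate: float = Field(default=0.3, ge=0)

    oop_base_scale: float = Field(default=60.0, gt=0)
    oop_sigma: float = Field(default=1.0, gt=0)
    log_mult_inpatient: float = math.log(250.0 / 60.0)
    log_mult_private: float = math.log(6.0)
    log_mult_outside: float = math.log(
        published.OOP_BY_RESIDENCE["outside"] / published.OOP_BY_RESIDENCE["addis_ababa"]
    )

    category_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "procedure_cost": published.CATEGORY_MEANS["procedure_cost"],
            "drug_cost": published.CATEGORY_MEANS["drug_cost"],
            "bed_cost": published.CATEGORY_MEANS["bed_cost"],
            "lab_imaging_cost": published.CATEGORY_MEANS["lab_imaging_cost"],
            "transport_cost": published.CATEGORY_MEANS["transport_cost"],
            "attendant_cost": published.CATEGORY_MEANS["attendant_cost"],
            "other_cost": published.CATEGORY_MEANS["other_cost"],
        }
    )
    dirichlet_concentration: float = Field(default=4.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticParams":
        if self.expenditure_mean < self.expenditure_median:
            raise ValueError("log-normal expenditure requires mean >= median")
        for name, probs, keys in [
            ("facility_probs", self.facility_probs, {"public", "private", "mixed"}),
            (
                "visit_type_probs",
                self.visit_type_probs,
                {"outpatient_only", "inpatient_only", "mixed"},
            ),
        ]:
            if set(probs) != keys:
                raise ValueError(f"{name} must have keys {sorted(keys)}")
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1")
            if any(not 0.0 <= v <= 1.0 for v in probs.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not math.isclose(sum(self.diagnosis_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("diagnosis_probs must sum to 1")
        if any(v < 0 for v in self.diagnosis_probs.values()):
            raise ValueError("diagnosis_probs must be non-negative")
        if set(self.category_weights) != set(COST_COLUMNS):
            raise ValueError(f"category_weights must have keys {COST_COLUMNS}")
        if any(w <= 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be positive")
        return self

    # Log-normal parameters implied by the (mean, median) pair:
    # median = exp(mu), mean = exp(mu + sigma^2 / 2).
    @property
    def expenditure_mu(self) -> float:
        return math.log(self.expenditure_median)

    @property
    def expenditure_sigma(self) -> float:
        return math.sqrt(2.0 * math.log(self.expenditure_mean / self.expenditure_median))


def default_params(**overrides: Any) -> SyntheticParams:
    """Parameters matching the published survey marginals."""
    return SyntheticParams(**overrides)


def _episode_costs(
    rng: np.random.Generator,
    counts: np.ndarray,
    log_mu: np.ndarray,
    sigma: float,
    facility: np.ndarray,
    log_mult_private: float,
) -> np.ndarray:
    """Sum per-episode log-normal costs for each household.

    ``log_mu`` is the per-household log location before the facility shift;
    mixed-facility households flip a fair coin per episode.
    """
    n = counts.size
    idx = np.repeat(np.arange(n), counts)
    if idx.size == 0:
        return np.zeros(n)
    fac = facility[idx]
    private = np.where(
        fac == "private", 1.0, np.where(fac == "mixed", (rng.random(idx.size) < 0.5) * 1.0, 0.0)
    )
    log_cost = log_mu[idx] + log_mult_private * private + sigma * rng.standard_normal(idx.size)
    return np.bincount(idx, weights=np.exp(log_cost), minlength=n)


def generate(params: SyntheticParams, seed: int | None = None) -> SurveyDataset:
    """Draw a synthetic survey dataset; deterministic given the seed.

    Draw order: household economics (size and expenditure via the copula,
    food share, residence, sex), then visit structure (facility, visit
    pattern, counts, diagnosis), then per-episode costs and their category
    split.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_households

    # Household economics.
    rho = params.size_expenditure_corr
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    size = np.maximum(
        np.rint(params.household_size_mean + params.household_size_sd * z1), 1
    ).astype(int)
    total_exp = np.exp(params.expenditure_mu + params.expenditure_sigma * z2)
    a = params.food_share_mean * params.food_share_concentration
    b = (1.0 - params.food_share_mean) * params.food_share_concentration
    food_exp = rng.beta(a, b, size=n) * total_exp
    residence = np.where(rng.random(n) < params.residence_outside_prob, "outside", "addis_ababa")
    sex = np.where(rng.random(n) < params.male_prob, "male", "female")

    # Visit structure.
    fac_keys = ["public", "private", "mixed"]
    facility = rng.choice(fac_keys, size=n, p=[params.facility_probs[k] for k in fac_keys])
    vt_keys = ["outpatient_only", "inpatient_only", "mixed"]
    visit_type = rng.choice(vt_keys, size=n, p=[params.visit_type_probs[k] for k in vt_keys])
    extra_out = rng.poisson(params.extra_outpatient_rate, size=n)
    extra_in = rng.poisson(params.extra_inpatient_rate, size=n)
    has_out = np.isin(visit_type, ["outpatient_only", "mixed"])
    has_in = np.isin(visit_type, ["inpatient_only", "mixed"])
    n_out = np.where(has_out, 1 + extra_out, 0)
    n_in = np.where(has_in, 1 + extra_in, 0)
    dx_keys = sorted(params.diagnosis_probs)
    diagnosis = rng.choice(dx_keys, size=n, p=[params.diagnosis_probs[k] for k in dx_keys])

    # Costs per episode, then the category split.
    base = math.log(params.oop_base_scale)
    log_mu_out = np.full(n, base)
    log_mu_in = np.full(n, base + params.log_mult_inpatient)
    cost_out = _episode_costs(
        rng, n_out, log_mu_out, params.oop_sigma, facility, params.log_mult_private
    )
    cost_in = _episode_costs(
        rng, n_in, log_mu_in, params.oop_sigma, facility, params.log_mult_private
    )
    total_cost = (cost_out + cost_in) * np.where(
        residence == "outside", math.exp(params.log_mult_outside), 1.0
    )
    shares = _category_shares(rng, params, n)
    costs = total_cost[:, None] * shares

    return _assemble(
        size, total_exp, food_exp, residence, sex, facility, visit_type, n_out, n_in,
        diagnosis, costs, params,
    )


def _category_shares(
    rng: np.random.Generator, params: SyntheticParams, n: int
) -> np.ndarray:
    w = np.array([params.category_weights[c] for c in COST_COLUMNS])
    alpha = params.dirichlet_concentration * w / w.sum()
    return rng.dirichlet(alpha, size=n)


def _assemble(
    size, total_exp, food_exp, residence, sex, facility, visit_type, n_out, n_in,
    diagnosis, costs, params: SyntheticParams,
) -> SurveyDataset:
    n = size.size
    ids = np.array([f"HH{i + 1:05d}" for i in range(n)])
    households = pd.DataFrame(
        {
            "household_id": ids,
            "size": size,
            "annual_total_exp": total_exp,
            "annual_food_exp": food_exp,
            "residence": residence,
            "sex": sex,
        }
    )
    oop = pd.DataFrame({"household_id": ids})
    for j, col in enumerate(COST_COLUMNS):
        oop[col] = costs[:, j]
    oop["n_outpatient"] = n_out
    oop["n_inpatient"] = n_in
    oop["facility_type"] = facility
    oop["visit_type"] = visit_type
    oop["diagnosis"] = diagnosis
    return SurveyDataset(
        households=households[HOUSEHOLD_COLUMNS + ["sex"]],
        oop_records=oop[OOP_COLUMNS],
        currency="USD",
        metadata={"generator": "finrisk.simulate", "params": params.model_dump()},
    )


def _che_ratios(ds: SurveyDataset, threshold: CheThreshold) -> np.ndarray:
    return che_summary(ds, threshold).indicators["ratio"].to_numpy()


def generate_with_known_truth(
    params: SyntheticParams,
    truth: dict,
    seed: int | None = None,
    calibration_size: int = 20_000,
) -> tuple[SurveyDataset, dict]:
    """Generate data with a planted, recoverable quantity.

    ``truth`` may request:

    ``{"che_rate": r}``
        The per-episode cost scale is calibrated so the expected CHE
        headcount at the 10%-of-total threshold equals ``r``.  With common
        random draws the expected headcount as a function of a multiplicative
        cost scale is the empirical survival function of the baseline OOP
        ratios, so the calibrating scale is obtained by quantile inversion on
        a large calibration sample (an exact root of the Monte-Carlo rate
        equation, well within 1e-3 for the default calibration size).

    ``{"logistic": {covariate: coefficient, ...}}``
        The CHE outcome at the threshold is drawn from the stated logistic
        model on the generated covariates, and household OOP is set so the
        pipeline's CHE indicator reproduces that outcome exactly (the OOP
        ratio straddles the threshold on the correct side).  An
        ``"intercept"`` key is honoured; otherwise, if ``"che_rate"`` is also
        given, the intercept is solved so the marginal CHE probability equals
        it, else it defaults to 0.

    Returns the dataset and a truth record describing what was planted.
    """
    threshold = truth.get("threshold", CheThreshold(0.10, "total_expenditure"))
    base_seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    s_calib, s_data = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))

    if "logistic" in truth:
        return _generate_logistic_truth(params, truth, threshold, s_data)

    if "che_rate" not in truth:
        raise ValueError("truth must contain 'che_rate' and/or 'logistic'")
    rate = float(truth["che_rate"])
    if not 0.0 < rate < 1.0:
        raise ValueError("requested CHE rate must lie strictly in (0, 1)")

    calib_params = params.model_copy(update={"n_households": calibration_size})
    calib = generate(calib_params, seed=s_calib)
    ratios = _che_ratios(calib, threshold)
    q = float(np.quantile(ratios, 1.0 - rate))
    if q <= 0:
        raise ValueError("requested rate infeasible for these parameters")
    scale = threshold.z / q
    expected = float(np.mean(ratios * scale > threshold.z))
    final_params = params.model_copy(
        update={"oop_base_scale": params.oop_base_scale * scale}
    )
    ds = generate(final_params, seed=s_data)
    record = {
        "kind": "che_rate",
        "target_che_rate": rate,
        "threshold": threshold.z,
        "denominator": threshold.denominator,
        "cost_scale_factor": scale,
        "expected_rate": expected,
        "calibration_size": calibration_size,
    }
    return ds, record


def _generate_logistic_truth(
    params: SyntheticParams, truth: dict, threshold: CheThreshold, seed: int
) -> tuple[SurveyDataset, dict]:
    from .inference import design_matrix  # deferred: inference imports equity

    coeffs = dict(truth["logistic"])
    intercept = coeffs.pop("intercept", None)
    ds = generate(params, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    X = design_matrix(ds, tuple(coeffs)) if coeffs else pd.DataFrame(index=ds.table.index)
    eta0 = np.zeros(ds.n)
    for name, coef in coeffs.items():
        col = name if name in X.columns else None
        if col is None:
            raise ValueError(f"cannot derive covariate {name!r}")
        eta0 += float(coef) * X[col].to_numpy(dtype=float)
    if intercept is None:
        if "che_rate" in truth:
            rate = float(truth["che_rate"])
            if not 0.0 < rate < 1.0:
                raise ValueError("requested CHE rate must lie strictly in (0, 1)")
            intercept = brentq(
                lambda b0: float(np.mean(expit(b0 + eta0))) - rate, -30.0, 30.0
            )
        else:
            intercept = 0.0
    eta = float(intercept) + eta0
    y = rng.random(ds.n) < expit(eta)

    # Place each household's OOP ratio on the correct side of the threshold.
    u = np.abs(rng.normal(0.0, 0.6, size=ds.n)) + 0.05
    ratio = threshold.z * np.exp(np.where(y, u, -u))
    denom = (
        ds.households["annual_total_exp"]
        if threshold.denominator == "total_expenditure"
        else ds.households["annual_total_exp"] - ds.households["annual_food_exp"]
    ).to_numpy(dtype=float)
    total_cost = ratio * denom
    shares = _category_shares(rng, params, ds.n)
    costs = total_cost[:, None] * shares
    for j, col in enumerate(COST_COLUMNS):
        ds.oop_records[col] = costs[:, j]
    realized = float(np.mean(oop_totals(ds)["total_oop"].to_numpy() / denom > threshold.z))
    record = {
        "kind": "logistic",
        "coefficients": {**coeffs, "intercept": float(intercept)},
        "threshold": threshold.z,
        "denominator": threshold.denominator,
        "marginal_che_rate": realized,
    }
    return ds, record
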