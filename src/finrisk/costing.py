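"""Out-of-pocket cost aggregation, currency handling, and the cost table.

Total OOP for a household is the sum of four direct-medical components
(procedure, drug, bed, laboratory/imaging) and three direct-non-medical
components (transport, attendant, other); "other" sits with the non-medical
block, matching its placement in the study's cost table.  Projection from
visit counts multiplies per-event mean costs by the number of outpatient
visits and inpatient admissions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import (
    COST_COLUMNS,
    DIRECT_MEDICAL_COLUMNS,
    DIRECT_NONMEDICAL_COLUMNS,
    HouseholdEconomy,
    OOPRecord,
    SurveyDataset,
)

__all__ = [
    "CostBreakdown",
    "convert_currency",
    "annualize",
    "total_oop",
    "oop_totals",
    "per_event_means",
    "project_total_oop",
    "food_share",
    "table2",
]


@dataclass(frozen=True)
class CostBreakdown:
    """OOP total split into direct medical and direct non-medical parts."""

    direct_medical: float
    direct_nonmedical: float

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_nonmedical


def convert_currency(amount, rate: float = 28.574):
    """Convert ETB to USD at ``rate`` ETB per USD; unrounded.

    Accepts scalars or array-likes.  Rounding is a presentation concern.
    """
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return np.asarray(amount) / rate if np.ndim(amount) else float(amount) / rate


def annualize(amount: float, period: str) -> float:
    """Scale an expenditure to a yearly figure (monthly amounts times 12)."""
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if period == "monthly":
        return amount * 12.0
    if period == "annual":
        return float(amount)
    raise ValueError(f"unknown period {period!r}")


def total_oop(rec: OOPRecord) -> CostBreakdown:
    """Sum a record's seven cost components into a :class:`CostBreakdown`."""
    medical = rec.procedure_cost + rec.drug_cost + rec.bed_cost + rec.lab_imaging_cost
    nonmedical = rec.transport_cost + rec.attendant_cost + rec.other_cost
    return CostBreakdown(direct_medical=medical, direct_nonmedical=nonmedical)


def oop_totals(ds: SurveyDataset) -> pd.DataFrame:
    """Per-household cost aggregation, vectorised over the whole dataset.

    Returns a frame indexed like ``ds.oop_records`` with columns
    ``household_id, direct_medical, direct_nonmedical, total_oop``.
    """
    oop = ds.oop_records
    out = pd.DataFrame({"household_id": oop["household_id"]})
    out["direct_medical"] = oop[DIRECT_MEDICAL_COLUMNS].sum(axis=1)
    out["direct_nonmedical"] = oop[DIRECT_NONMEDICAL_COLUMNS].sum(axis=1)
    out["total_oop"] = out["direct_medical"] + out["direct_nonmedical"]
    return out


def per_event_means(ds: SurveyDataset) -> tuple[float, float]:
    """Sample mean OOP per outpatient visit and per inpatient admission.

    Each household's observed total is attributed to its events in
    proportion; households with zero events contribute nothing.  These means
    are the fallback imputation source for :func:`project_total_oop` when a
    household has no observed events of a type.
    """
    t = oop_totals(ds)["total_oop"].to_numpy()
    n_out = ds.oop_records["n_outpatient"].to_numpy()
    n_in = ds.oop_records["n_inpatient"].to_numpy()
    events = n_out + n_in
    has = events > 0
    per_event = np.zeros_like(t, dtype=float)
    per_event[has] = t[has] / events[has]
    w_out = n_out[has].sum()
    w_in = n_in[has].sum()
    mean_out = float((per_event[has] * n_out[has]).sum() / w_out) if w_out else 0.0
    mean_in = float((per_event[has] * n_in[has]).sum() / w_in) if w_in else 0.0
    return mean_out, mean_in


def project_total_oop(
    outpatient_mean: float,
    inpatient_mean: float,
    n_outpatient: int,
    n_inpatient: int,
) -> float:
    """Project a household total from per-event mean costs and visit counts."""
    if n_outpatient < 0 or n_inpatient < 0:
        raise ValueError("visit counts must be non-negative")
    if outpatient_mean < 0 or inpatient_mean < 0:
        raise ValueError("per-event means must be non-negative")
    return outpatient_mean * n_outpatient + inpatient_mean * n_inpatient


def food_share(h: HouseholdEconomy) -> float:
    """Food expenditure as a fraction of total household expenditure."""
    if h.annual_total_expenditure <= 0:
        raise ValueError("total expenditure must be positive")
    return h.annual_food_expenditure / h.annual_total_expenditure


def _summary_row(values: pd.Series) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(values.median()),
    }


def table2(ds: SurveyDataset) -> pd.DataFrame:
    """Cost summary table: mean (SD) and median of OOP by stratifier.

    Tidy output with columns ``section, group, n, mean, sd, median``;
    sections are total, facility type, visit type, residence, expense
    category, and diagnosis.
    """
    t = ds.table.copy()
    totals = oop_totals(ds)
    t["total_oop"] = totals["total_oop"].to_numpy()
    rows: list[dict] = []
    rows.append({"section": "total", "group": "all", **_summary_row(t["total_oop"])})
    for section, col in [
        ("facility_type", "facility_type"),
        ("visit_type", "visit_type"),
        ("residence", "residence"),
        ("diagnosis", "diagnosis"),
    ]:
        for grp, sub in t.groupby(col, sort=True, observed=True):
            rows.append({"section": section, "group": str(grp), **_summary_row(sub["total_oop"])})
    for col in COST_COLUMNS:
        rows.append({"section": "expense_category", "group": col, **_summary_row(t[col])})
    return pd.DataFrame(rows, columns=["section", "group", "n", "mean", "sd", "median"])
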