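"""Wealth-quintile ranking and the quintile-by-threshold equity table.

Households are ranked by annual per-capita total consumption expenditure and
split into five groups of (as near as possible) equal size: the poorest 20%
form quintile 1 and the richest 20% quintile 5.  Cuts are made on ranks, not
values, so quintile sizes differ by at most one even with tied expenditures;
ties are broken by household id for determinism, and when N is not divisible
by five the lower quintiles absorb the remainder.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catastrophic import CheThreshold, DEFAULT_THRESHOLDS, che_summary
from .costing import oop_totals
from .survey import SurveyDataset

__all__ = ["assign_quintiles", "quintile_report", "oop_by_quintile_and_facility"]


def assign_quintiles(ds: SurveyDataset) -> pd.DataFrame:
    """Rank households into wealth quintiles (1 = poorest) by per-capita expenditure.

    Returns columns ``household_id, per_capita_expenditure, quintile``.
    """
    n = ds.n
    if n < 5:
        raise ValueError("need at least 5 households to form quintiles")
    hh = ds.households
    pce = hh["annual_total_exp"].to_numpy(dtype=float) / hh["size"].to_numpy(dtype=float)
    out = pd.DataFrame({"household_id": hh["household_id"].to_numpy(), "per_capita_expenditure": pce})
    out = out.sort_values(
        ["per_capita_expenditure", "household_id"], kind="mergesort"
    ).reset_index(drop=True)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    out["quintile"] = np.repeat(np.arange(1, 6), sizes)
    return out


def _subset(ds: SurveyDataset, ids: pd.Series) -> SurveyDataset:
    mask_h = ds.households["household_id"].isin(ids)
    mask_o = ds.oop_records["household_id"].isin(ids)
    return SurveyDataset(
        households=ds.households.loc[mask_h].reset_index(drop=True),
        oop_records=ds.oop_records.loc[mask_o].reset_index(drop=True),
        currency=ds.currency,
    )


def _metrics(ds: SurveyDataset, thresholds: tuple[CheThreshold, ...]) -> dict:
    row: dict = {"n": ds.n}
    for thr in thresholds:
        s = che_summary(ds, thr)
        row[f"che_headcount_{thr.label}"] = s.headcount
        row[f"overshoot_{thr.label}"] = s.overshoot
    row["mean_total_expenditure"] = float(ds.households["annual_total_exp"].mean())
    row["mean_oop"] = float(oop_totals(ds)["total_oop"].mean())
    return row


def quintile_report(
    ds: SurveyDataset, thresholds: tuple[CheThreshold, ...] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Equity table: CHE headcount and overshoot per threshold, mean
    expenditure and mean OOP, by wealth quintile plus an all-households row.

    The pooled row is computed on the full dataset, not by averaging the
    quintile rows.
    """
    if not thresholds:
        raise ValueError("at least one threshold is required")
    assign = assign_quintiles(ds)
    rows = []
    for q in range(1, 6):
        ids = assign.loc[assign["quintile"] == q, "household_id"]
        rows.append({"quintile": f"Q{q}", **_metrics(_subset(ds, ids), tuple(thresholds))})
    rows.append({"quintile": "all", **_metrics(ds, tuple(thresholds))})
    return pd.DataFrame(rows)


def oop_by_quintile_and_facility(ds: SurveyDataset) -> pd.DataFrame:
    """Mean OOP by wealth quintile and facility type (the bar-chart table)."""
    assign = assign_quintiles(ds)
    t = ds.table.merge(assign[["household_id", "quintile"]], on="household_id")
    totals = oop_totals(ds).rename(columns={"total_oop": "oop"})
    t = t.merge(totals[["household_id", "oop"]], on="household_id")
    out = (
        t.groupby(["quintile", "facility_type"], observed=True)["oop"]
        .agg(n="size", mean_oop="mean")
        .reset_index()
    )
    return out
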