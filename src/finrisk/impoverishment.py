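"""Impoverishment due to out-of-pocket health spending, and Pen's parade.

A household is impoverished by OOP spending when its per-person consumption
is above the poverty line before health payments but falls below it after
deducting them; the classification applies only to households above the
line to begin with.  The default line is the international poverty line of
$1.90 (PPP) per person per day, annualised and converted into the dataset's
currency via a purchasing-power-parity factor.

Household composition is adjusted by dividing by ``size**theta``; theta = 1
is plain per-capita division, the default.  Net (post-payment) consumption
is floored at zero before the division — OOP can exceed annual consumption
and a negative consumption level is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costing import oop_totals
from .survey import HouseholdEconomy, SurveyDataset

__all__ = [
    "PovertyLine",
    "PovertySummary",
    "annual_poverty_threshold",
    "poverty_status",
    "impoverishment_headcount",
    "pen_parade",
    "plot_pen_parade",
]


@dataclass(frozen=True)
class PovertyLine:
    """A per-person per-day PPP poverty line and its conversion to the data's currency.

    ``ppp_factor`` is the dataset-currency cost of one international dollar.
    It has no safe universal default for real data; synthetic data generated
    by this package is denominated in international dollars, where 1 applies.
    """

    per_day_ppp: float = 1.90
    ppp_factor: float = 1.0
    days_per_year: int = 365

    def __post_init__(self) -> None:
        if self.per_day_ppp <= 0 or self.ppp_factor <= 0 or self.days_per_year <= 0:
            raise ValueError("poverty-line parameters must be positive")

    @property
    def annual_per_person(self) -> float:
        return self.per_day_ppp * self.days_per_year * self.ppp_factor


@dataclass(frozen=True)
class PovertySummary:
    """Pre-payment poor, impoverished, and post-payment poor fractions."""

    n: int
    pre_poor_fraction: float
    impoverished_fraction: float
    post_poor_fraction: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pre_poor_fraction": self.pre_poor_fraction,
            "impoverished_fraction": self.impoverished_fraction,
            "post_poor_fraction": self.post_poor_fraction,
        }


def annual_poverty_threshold(line: PovertyLine) -> float:
    """Annualised per-person poverty line in the dataset's currency."""
    return line.annual_per_person


def poverty_status(
    h: HouseholdEconomy,
    t: float,
    line: float,
    basis: str = "gross",
    theta: float = 1.0,
) -> bool:
    """Whether a household is below the per-person line, before or after OOP.

    ``basis="gross"`` compares X / size**theta to the line; ``"net"``
    compares max(X - T, 0) / size**theta.
    """
    if t < 0:
        raise ValueError("OOP spending must be non-negative")
    if basis == "gross":
        x = h.annual_total_expenditure
    elif basis == "net":
        x = max(h.annual_total_expenditure - t, 0.0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return x / h.size**theta < line


def _per_person(ds: SurveyDataset, theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hh = ds.households
    totals = oop_totals(ds)
    merged = hh[["household_id"]].merge(totals, on="household_id", how="left")
    t = merged["total_oop"].fillna(0.0).to_numpy(dtype=float)
    x = hh["annual_total_exp"].to_numpy(dtype=float)
    size = hh["size"].to_numpy(dtype=float)
    adj = size**theta
    gross = x / adj
    net = np.maximum(x - t, 0.0) / adj
    return gross, net, t


def impoverishment_headcount(
    ds: SurveyDataset, line: PovertyLine, theta: float = 1.0
) -> PovertySummary:
    """Fractions poor before payment, pushed below the line, and poor after."""
    if ds.n == 0:
        raise ValueError("empty dataset")
    gross, net, _ = _per_person(ds, theta)
    z = line.annual_per_person
    pre = gross < z
    imp = (~pre) & (net < z)
    n = ds.n
    pre_f = float(pre.sum() / n)
    imp_f = float(imp.sum() / n)
    return PovertySummary(
        n=n,
        pre_poor_fraction=pre_f,
        impoverished_fraction=imp_f,
        post_poor_fraction=pre_f + imp_f,
    )


def pen_parade(ds: SurveyDataset, line: PovertyLine, theta: float = 1.0) -> pd.DataFrame:
    """Households ranked by pre-payment per-person consumption, with post-payment drips.

    Returns a frame with columns ``rank`` (1..N, ascending gross per-person
    expenditure, ties broken by household id), ``household_id``,
    ``gross_per_person``, ``net_per_person`` and ``poverty_line``.  Plotting
    gross as a curve and dropping bars to net shows which households OOP
    payments push below the line.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    gross, net, _ = _per_person(ds, theta)
    out = pd.DataFrame(
        {
            "household_id": ds.households["household_id"].to_numpy(),
            "gross_per_person": gross,
            "net_per_person": net,
        }
    )
    out = out.sort_values(
        ["gross_per_person", "household_id"], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["poverty_line"] = line.annual_per_person
    return out


def plot_pen_parade(parade: pd.DataFrame, ax=None):
    """Convenience matplotlib rendering of a :func:`pen_parade` frame."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.vlines(
        parade["rank"],
        parade["net_per_person"],
        parade["gross_per_person"],
        color="0.6",
        lw=0.6,
        label="drop due to OOP",
    )
    ax.plot(parade["rank"], parade["gross_per_person"], color="C0", lw=1.2,
            label="pre-payment")
    ax.axhline(parade["poverty_line"].iloc[0], color="C3", ls="--", label="poverty line")
    ax.set_xlabel("households ranked by per-person expenditure")
    ax.set_ylabel("annual per-person expenditure (USD)")
    ax.set_yscale("log")
    ax.legend(frameon=False)
    return ax
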