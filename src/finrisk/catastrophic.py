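"""Catastrophic health expenditure (CHE) incidence and intensity.

A household incurs CHE when its OOP health spending T exceeds a threshold
share Z of its resources X (total consumption, or non-food consumption as
"capacity to pay").  The per-household indicator is

    E_i = 1 if T_i / X_i > Z else 0,

the headcount is H = (1/N) sum E_i, the per-household overshoot is
O_i = E_i ((T_i / X_i) - Z), and the mean overshoot O = (1/N) sum O_i
measures intensity: the average excess of the payment share over the
threshold, counting non-catastrophic households as zero.

The strict inequality follows the defining equation; a weak variant
(ratio >= Z) is available via ``inequality="weak"`` for sensitivity checks.
Households whose denominator is zero or negative are excluded from N, with
the count reported, rather than being classified either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import oop_totals
from .survey import SurveyDataset

__all__ = [
    "CheThreshold",
    "CheIndicator",
    "CheSummary",
    "DEFAULT_THRESHOLDS",
    "che_indicator",
    "che_summary",
    "che_headcount",
    "che_overshoot",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CheThreshold:
    """A threshold share Z paired with the resource denominator it applies to."""

    z: float
    denominator: str = "total_expenditure"  # or "nonfood_expenditure"
    inequality: str = "strict"  # "strict": ratio > z; "weak": ratio >= z

    def __post_init__(self) -> None:
        if not 0.0 < self.z < 1.0:
            raise ValueError("threshold z must lie in (0, 1)")
        if self.denominator not in ("total_expenditure", "nonfood_expenditure"):
            raise ValueError(f"unknown denominator {self.denominator!r}")
        if self.inequality not in ("strict", "weak"):
            raise ValueError(f"unknown inequality {self.inequality!r}")

    @property
    def label(self) -> str:
        kind = "total" if self.denominator == "total_expenditure" else "nonfood"
        return f"{self.z:g}:{kind}"


#: The three threshold/denominator pairs of the headline analysis.
DEFAULT_THRESHOLDS = (
    CheThreshold(0.10, "total_expenditure"),
    CheThreshold(0.25, "total_expenditure"),
    CheThreshold(0.40, "nonfood_expenditure"),
)


@dataclass(frozen=True)
class CheIndicator:
    """Per-household CHE classification at one threshold."""

    household_id: str
    ratio: float
    e: int
    overshoot_i: float


@dataclass
class CheSummary:
    """Headcount and overshoot over the households with a defined denominator."""

    n: int
    headcount: float
    overshoot: float
    threshold: CheThreshold
    indicators: pd.DataFrame = field(repr=False)
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_excluded": self.n_excluded,
            "threshold": self.threshold.z,
            "denominator": self.threshold.denominator,
            "inequality": self.threshold.inequality,
            "headcount": self.headcount,
            "overshoot": self.overshoot,
        }


def che_indicator(t: float, x: float, threshold: CheThreshold) -> CheIndicator:
    """Classify a single household: ratio, indicator E_i, overshoot O_i."""
    if t < 0:
        raise ValueError("OOP spending must be non-negative")
    if x <= 0:
        raise ValueError("denominator must be positive; exclude the household instead")
    ratio = t / x
    if threshold.inequality == "strict":
        e = int(ratio > threshold.z)
    else:
        e = int(ratio >= threshold.z)
    return CheIndicator(
        household_id="", ratio=ratio, e=e, overshoot_i=e * (ratio - threshold.z)
    )


def _denominator(ds: SurveyDataset, threshold: CheThreshold) -> np.ndarray:
    hh = ds.households
    if threshold.denominator == "total_expenditure":
        return hh["annual_total_exp"].to_numpy(dtype=float)
    return (hh["annual_total_exp"] - hh["annual_food_exp"]).to_numpy(dtype=float)


def che_summary(ds: SurveyDataset, threshold: CheThreshold) -> CheSummary:
    """Headcount and overshoot for one threshold over a whole dataset.

    Households with a non-positive denominator are excluded from N and
    logged; the summary's ``n_excluded`` carries the count.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    totals = oop_totals(ds)
    merged = ds.households[["household_id"]].merge(totals, on="household_id", how="left")
    t = merged["total_oop"].fillna(0.0).to_numpy(dtype=float)
    x = _denominator(ds, threshold)
    defined = x > 0
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.warning(
            "excluding %d household(s) with non-positive %s denominator",
            n_excluded,
            threshold.denominator,
        )
    if not defined.any():
        raise ValueError("no household has a defined denominator")
    ratio = t[defined] / x[defined]
    if threshold.inequality == "strict":
        e = (ratio > threshold.z).astype(int)
    else:
        e = (ratio >= threshold.z).astype(int)
    overshoot_i = e * (ratio - threshold.z)
    indicators = pd.DataFrame(
        {
            "household_id": ds.households.loc[defined, "household_id"].to_numpy(),
            "ratio": ratio,
            "e": e,
            "overshoot_i": overshoot_i,
        }
    )
    n = int(defined.sum())
    return CheSummary(
        n=n,
        headcount=float(e.sum() / n),
        overshoot=float(overshoot_i.sum() / n),
        threshold=threshold,
        indicators=indicators,
        n_excluded=n_excluded,
    )


def che_headcount(ds: SurveyDataset, threshold: CheThreshold) -> CheSummary:
    """Incidence of CHE: the proportion of households over the threshold."""
    return che_summary(ds, threshold)


def che_overshoot(ds: SurveyDataset, threshold: CheThreshold) -> CheSummary:
    """Intensity of CHE: the mean excess payment share over all N households."""
    return che_summary(ds, threshold)
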