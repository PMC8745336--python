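"""Survey data model and tabular I/O.

One row of the canonical survey table describes one trauma patient and their
household: household economics (annual total and food expenditure in USD,
household size, residence), visit structure (outpatient visits, inpatient
admissions, facility type), and itemised out-of-pocket (OOP) costs split into
four direct-medical and three direct-non-medical categories.

A :class:`SurveyDataset` keeps households and OOP records as two aligned
pandas frames joined on ``household_id``; :func:`read_survey` screens rows
against the type invariants and records every exclusion with a reason in a
:class:`ValidationReport`, mirroring how incomplete questionnaires are dropped
from an analysis denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Residence",
    "FacilityType",
    "VisitType",
    "Diagnosis",
    "HouseholdEconomy",
    "OOPRecord",
    "SurveyDataset",
    "ValidationReport",
    "SchemaError",
    "CANONICAL_COLUMNS",
    "COST_COLUMNS",
    "read_survey",
    "write_survey",
    "validate_dataset",
]


class Residence(str, enum.Enum):
    ADDIS_ABABA = "addis_ababa"
    OUTSIDE = "outside"


class FacilityType(str, enum.Enum):
    PUBLIC = "public"
    PRIVATE = "private"
    MIXED = "mixed"


class VisitType(str, enum.Enum):
    OUTPATIENT_ONLY = "outpatient_only"
    INPATIENT_ONLY = "inpatient_only"
    MIXED = "mixed"


class Diagnosis(str, enum.Enum):
    HEAD = "head"
    UPPER_LIMB = "upper_limb"
    LOWER_LIMB = "lower_limb"
    SPINAL = "spinal"
    PELVIC = "pelvic"
    CHEST = "chest"
    ABDOMINAL = "abdominal"
    MULTIPLE = "multiple"
    OTHER = "other"


DIRECT_MEDICAL_COLUMNS = ["procedure_cost", "drug_cost", "bed_cost", "lab_imaging_cost"]
DIRECT_NONMEDICAL_COLUMNS = ["transport_cost", "attendant_cost", "other_cost"]
COST_COLUMNS = DIRECT_MEDICAL_COLUMNS + DIRECT_NONMEDICAL_COLUMNS

HOUSEHOLD_COLUMNS = [
    "household_id",
    "size",
    "annual_total_exp",
    "annual_food_exp",
    "residence",
]
OOP_COLUMNS = (
    ["household_id"]
    + COST_COLUMNS
    + ["n_outpatient", "n_inpatient", "facility_type", "visit_type", "diagnosis"]
)
#: Column order of the canonical CSV dialect.
CANONICAL_COLUMNS = HOUSEHOLD_COLUMNS + OOP_COLUMNS[1:]

MONETARY_COLUMNS = ["annual_total_exp", "annual_food_exp"] + COST_COLUMNS


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class HouseholdEconomy(BaseModel):
    """A household's annual consumption expenditures (the X_i of the CHE math)."""

    household_id: str
    size: int = Field(ge=1)
    annual_total_expenditure: float = Field(ge=0.0)
    annual_food_expenditure: float = Field(ge=0.0)
    residence: Residence

    @model_validator(mode="after")
    def _food_within_total(self) -> "HouseholdEconomy":
        if self.annual_food_expenditure > self.annual_total_expenditure:
            raise ValueError("annual food expenditure exceeds total expenditure")
        return self

    @property
    def nonfood_expenditure(self) -> float:
        """Capacity to pay: total minus food consumption."""
        return self.annual_total_expenditure - self.annual_food_expenditure


class OOPRecord(BaseModel):
    """Itemised out-of-pocket costs and visit structure for one patient (T_i)."""

    household_id: str
    procedure_cost: float = Field(ge=0.0)
    drug_cost: float = Field(ge=0.0)
    bed_cost: float = Field(ge=0.0)
    lab_imaging_cost: float = Field(ge=0.0)
    transport_cost: float = Field(ge=0.0)
    attendant_cost: float = Field(ge=0.0)
    other_cost: float = Field(ge=0.0)
    n_outpatient_visits: int = Field(ge=0)
    n_inpatient_admissions: int = Field(ge=0)
    facility_type: FacilityType
    visit_type: VisitType
    diagnosis: Diagnosis

    @model_validator(mode="after")
    def _visit_type_consistent(self) -> "OOPRecord":
        vt = self.visit_type
        if vt is VisitType.OUTPATIENT_ONLY and self.n_inpatient_admissions != 0:
            raise ValueError("outpatient_only record has inpatient admissions")
        if vt is VisitType.INPATIENT_ONLY and self.n_outpatient_visits != 0:
            raise ValueError("inpatient_only record has outpatient visits")
        if vt is VisitType.MIXED and (
            self.n_outpatient_visits == 0 or self.n_inpatient_admissions == 0
        ):
            raise ValueError("mixed record needs both visit kinds")
        return self


@dataclass
class ValidationReport:
    """Outcome of screening rows against the data-model invariants."""

    n_rows_read: int
    n_rows_excluded: int
    exclusion_reasons: list[tuple[str, int]]
    passed: bool

    def reason_count(self, rule: str) -> int:
        return dict(self.exclusion_reasons).get(rule, 0)

    def to_dict(self) -> dict:
        return {
            "n_rows_read": self.n_rows_read,
            "n_rows_excluded": self.n_rows_excluded,
            "exclusion_reasons": [list(t) for t in self.exclusion_reasons],
            "passed": self.passed,
        }


def _report(n_read: int, reasons: dict[str, int]) -> ValidationReport:
    items = sorted(reasons.items())
    n_excl = sum(reasons.values())
    return ValidationReport(
        n_rows_read=n_read,
        n_rows_excluded=n_excl,
        exclusion_reasons=items,
        passed=n_excl == 0,
    )


@dataclass
class SurveyDataset:
    """The analysis sample: households and their OOP records, joined on id.

    Monetary columns are USD throughout once constructed (``currency`` records
    the unit; ETB inputs are converted at read time).
    """

    households: pd.DataFrame
    oop_records: pd.DataFrame
    currency: str = "USD"
    metadata: dict = field(default_factory=dict)
    read_report: ValidationReport | None = None

    @property
    def n(self) -> int:
        return len(self.households)

    @property
    def table(self) -> pd.DataFrame:
        """Inner join of households and OOP records, one row per household."""
        return self.households.merge(self.oop_records, on="household_id", how="inner")

    def iter_households(self) -> Iterable[HouseholdEconomy]:
        for row in self.households.itertuples(index=False):
            yield HouseholdEconomy(
                household_id=row.household_id,
                size=int(row.size),
                annual_total_expenditure=float(row.annual_total_exp),
                annual_food_expenditure=float(row.annual_food_exp),
                residence=Residence(row.residence),
            )

    def iter_oop_records(self) -> Iterable[OOPRecord]:
        for row in self.oop_records.itertuples(index=False):
            yield OOPRecord(
                household_id=row.household_id,
                procedure_cost=row.procedure_cost,
                drug_cost=row.drug_cost,
                bed_cost=row.bed_cost,
                lab_imaging_cost=row.lab_imaging_cost,
                transport_cost=row.transport_cost,
                attendant_cost=row.attendant_cost,
                other_cost=row.other_cost,
                n_outpatient_visits=int(row.n_outpatient),
                n_inpatient_admissions=int(row.n_inpatient),
                facility_type=FacilityType(row.facility_type),
                visit_type=VisitType(row.visit_type),
                diagnosis=Diagnosis(row.diagnosis),
            )


def _row_violation(row: pd.Series) -> str | None:
    """Return the first invariant a canonical-format row violates, else None.

    Rule names are stable identifiers used in exclusion tallies.
    """
    if pd.isna(row["household_id"]) or str(row["household_id"]).strip() == "":
        return "missing_id"
    required = [c for c in CANONICAL_COLUMNS if c != "household_id"]
    if any(pd.isna(row[c]) for c in required):
        return "missing_value"
    try:
        size = int(row["size"])
        total = float(row["annual_total_exp"])
        food = float(row["annual_food_exp"])
        costs = [float(row[c]) for c in COST_COLUMNS]
        n_out = int(row["n_outpatient"])
        n_in = int(row["n_inpatient"])
    except (TypeError, ValueError):
        return "unparseable_value"
    if size < 1:
        return "bad_household_size"
    if total < 0 or food < 0:
        return "nonnegative_expenditure"
    if food > total:
        return "food_exceeds_total"
    if any(c < 0 for c in costs):
        return "nonnegative_cost"
    if n_out < 0 or n_in < 0:
        return "nonnegative_visits"
    try:
        Residence(row["residence"])
        FacilityType(row["facility_type"])
        vt = VisitType(row["visit_type"])
        Diagnosis(row["diagnosis"])
    except ValueError:
        return "invalid_category"
    if vt is VisitType.OUTPATIENT_ONLY and n_in != 0:
        return "visit_type_inconsistent"
    if vt is VisitType.INPATIENT_ONLY and n_out != 0:
        return "visit_type_inconsistent"
    if vt is VisitType.MIXED and (n_out == 0 or n_in == 0):
        return "visit_type_inconsistent"
    return None


def read_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    currency: str = "USD",
    exchange_rate_etb_per_usd: float = 28.574,
) -> SurveyDataset:
    """Read a delimited survey table into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``{canonical_field: source_column}`` remapping
        non-canonical headers.  Unknown extra columns are ignored.
    currency
        ``"USD"`` (no conversion) or ``"ETB"`` (monetary columns divided by
        ``exchange_rate_etb_per_usd`` at read time; the returned dataset is
        always USD).

    Rows violating any invariant are excluded, with per-rule counts in the
    returned dataset's ``read_report``; nothing is dropped silently.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    if schema:
        missing_src = [src for src in schema.values() if src not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema maps missing column(s): {missing_src}")
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    raw = raw[CANONICAL_COLUMNS]
    return dataset_from_frame(
        raw, currency=currency, exchange_rate_etb_per_usd=exchange_rate_etb_per_usd
    )


def dataset_from_frame(
    frame: pd.DataFrame,
    *,
    currency: str = "USD",
    exchange_rate_etb_per_usd: float = 28.574,
) -> SurveyDataset:
    """Screen a canonical-format frame row by row and build the dataset."""
    if currency not in ("USD", "ETB"):
        raise ValueError(f"unknown currency {currency!r}")
    reasons: dict[str, int] = {}
    keep_idx = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        rule = _row_violation(row)
        if rule is None:
            hid = str(row["household_id"]).strip()
            if hid in seen:
                rule = "duplicate_id"
            else:
                seen.add(hid)
        if rule is None:
            keep_idx.append(idx)
        else:
            reasons[rule] = reasons.get(rule, 0) + 1
    clean = frame.loc[keep_idx].copy()
    clean["household_id"] = clean["household_id"].astype(str).str.strip()
    for col in ("size", "n_outpatient", "n_inpatient"):
        clean[col] = clean[col].astype(float).astype(int)
    for col in MONETARY_COLUMNS:
        clean[col] = clean[col].astype(float)
    if currency == "ETB":
        if exchange_rate_etb_per_usd <= 0:
            raise ValueError("exchange rate must be positive")
        clean[MONETARY_COLUMNS] = clean[MONETARY_COLUMNS] / exchange_rate_etb_per_usd
    clean = clean.reset_index(drop=True)
    ds = SurveyDataset(
        households=clean[HOUSEHOLD_COLUMNS].copy(),
        oop_records=clean[OOP_COLUMNS].copy(),
        currency="USD",
        read_report=_report(len(frame), reasons),
    )
    return ds


def write_survey(ds: SurveyDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect (USD monetary values)."""
    table = ds.table[CANONICAL_COLUMNS]
    table.to_csv(path, index=False)


def validate_dataset(ds: SurveyDataset) -> ValidationReport:
    """Check an in-memory dataset against all invariants and join integrity.

    Violations are reported, never raised; ``passed`` is true iff there are
    zero violations.
    """
    reasons: dict[str, int] = {}

    def tally(rule: str, count: int) -> None:
        if count:
            reasons[rule] = reasons.get(rule, 0) + int(count)

    hh = ds.households
    oop = ds.oop_records
    tally("duplicate_id", hh["household_id"].duplicated().sum())
    tally("orphan_record", (~oop["household_id"].isin(hh["household_id"])).sum())
    tally("missing_record", (~hh["household_id"].isin(oop["household_id"])).sum())
    tally("bad_household_size", (hh["size"] < 1).sum())
    tally(
        "nonnegative_expenditure",
        ((hh["annual_total_exp"] < 0) | (hh["annual_food_exp"] < 0)).sum(),
    )
    tally("food_exceeds_total", (hh["annual_food_exp"] > hh["annual_total_exp"]).sum())
    tally("nonnegative_cost", (oop[COST_COLUMNS] < 0).any(axis=1).sum())
    tally("nonnegative_visits", ((oop["n_outpatient"] < 0) | (oop["n_inpatient"] < 0)).sum())
    bad_res = ~hh["residence"].isin([r.value for r in Residence])
    bad_fac = ~oop["facility_type"].isin([f.value for f in FacilityType])
    bad_vt = ~oop["visit_type"].isin([v.value for v in VisitType])
    bad_dx = ~oop["diagnosis"].isin([d.value for d in Diagnosis])
    tally("invalid_category", (bad_res.sum() + bad_fac.sum() + bad_vt.sum() + bad_dx.sum()))
    vt = oop["visit_type"]
    inconsistent = (
        ((vt == VisitType.OUTPATIENT_ONLY.value) & (oop["n_inpatient"] != 0))
        | ((vt == VisitType.INPATIENT_ONLY.value) & (oop["n_outpatient"] != 0))
        | ((vt == VisitType.MIXED.value) & ((oop["n_outpatient"] == 0) | (oop["n_inpatient"] == 0)))
    )
    tally("visit_type_inconsistent", inconsistent.sum())
    return _report(len(hh), reasons)
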