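"""Published summary statistics of the Addis Ababa road-traffic-injury cost survey.

The study's microdata were never deposited; what is public are the printed
summary tables.  These constants serve two roles: they are the calibration
targets for the synthetic-data generator (:mod:`finrisk.simulate`) and the
inputs to the in-paper arithmetic identities (currency cap, cost ratios,
shares) that the package recomputes.

All monetary values are 2018 USD unless noted.  ``ETB_PER_USD_2018`` is the
average 2018 exchange rate used to convert Ethiopian Birr.
"""

from __future__ import annotations

ETB_PER_USD_2018 = 28.574

# Study accrual: 478 recruited, 5 refused, 21 incomplete, 452 analysed.
N_RECRUITED = 478
N_REFUSED = 5
N_INCOMPLETE = 21
N_ANALYSED = 452

# Third-party vehicle insurance cap, in ETB.
INSURANCE_CAP_ETB = 2000.0

# Household economics (Table 1 marginals).
HOUSEHOLD_SIZE_MEAN = 4.5
HOUSEHOLD_SIZE_SD = 2.1
EXPENDITURE_MEAN = 2520.0
EXPENDITURE_SD = 1896.0
EXPENDITURE_MEDIAN = 2050.0
NONFOOD_EXPENDITURE_MEAN = 1368.0
NONFOOD_EXPENDITURE_MEDIAN = 956.0

RESIDENCE_OUTSIDE_N = 268
MALE_N = 318

# Injury-site counts.  The "other" bucket of 26 is split in the cost table
# into chest (2), abdominal (1) and a remainder; we carry the split.
DIAGNOSIS_COUNTS = {
    "lower_limb": 194,
    "multiple": 76,
    "upper_limb": 63,
    "head": 52,
    "pelvic": 30,
    "spinal": 11,
    "chest": 2,
    "abdominal": 1,
    "other": 23,
}

# Facility and visit-pattern counts.  The outpatient-only / inpatient-only
# labels are swapped between the running text and the table; the text
# (67 outpatient-only, 217 inpatient-only) is followed.
FACILITY_COUNTS = {"public": 391, "private": 34, "mixed": 27}
VISIT_TYPE_COUNTS = {"outpatient_only": 67, "inpatient_only": 217, "mixed": 168}

# Mean (SD) / median of total OOP, overall and by facility type (USD).
OOP_TOTAL = {"mean": 947.0, "sd": 1843.0, "median": 395.0}
OOP_BY_FACILITY = {
    "public": {"n": 391, "mean": 625.0, "sd": 961.0, "median": 350.0},
    "private": {"n": 34, "mean": 3430.0, "sd": 3716.0, "median": 2100.0},
    "mixed": {"n": 27, "mean": 2474.0, "sd": 3935.0, "median": 1190.0},
}
OOP_OUTPATIENT_BY_FACILITY = {
    "public": {"n": 198, "mean": 282.0, "sd": 609.0, "median": 87.0},
    "private": {"n": 19, "mean": 932.0, "sd": 1397.0, "median": 129.0},
    "mixed": {"n": 27, "mean": 1281.0, "sd": 3264.0, "median": 63.0},
}
OOP_INPATIENT_BY_FACILITY = {
    "public": {"n": 351, "mean": 527.0, "sd": 758.0, "median": 333.0},
    "private": {"n": 57, "mean": 2989.0, "sd": 3066.0, "median": 3000.0},
    "mixed": {"n": 27, "mean": 1192.0, "sd": 1519.0, "median": 385.0},
}

# Mean cost per expense category (USD); drives the generator's category split.
CATEGORY_MEANS = {
    "procedure_cost": 102.0,
    "drug_cost": 91.0,
    "bed_cost": 55.0,
    "lab_imaging_cost": 24.0,
    "transport_cost": 68.0,
    "attendant_cost": 96.0,
    "other_cost": 73.0,
}

# Mean total OOP by patient residence (USD).
OOP_BY_RESIDENCE = {"addis_ababa": 881.0, "outside": 992.0}

# Headline equity results (quintile-by-threshold table), percentages.
CHE_HEADCOUNT_10PCT_BY_QUINTILE = [80, 70, 64, 59, 62]
CHE_HEADCOUNT_10PCT_ALL = 67
CHE_HEADCOUNT_40PCT_ALL = 55
PRE_POOR_PCT = 36
IMPOVERISHED_PCT = 24

POVERTY_LINE_PPP_PER_DAY = 1.90
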