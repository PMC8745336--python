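import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from finrisk.survey import COST_COLUMNS, HOUSEHOLD_COLUMNS, OOP_COLUMNS, SurveyDataset

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


def make_dataset(
    total_exp,
    food_exp,
    oop_total,
    size=None,
    residence=None,
    facility=None,
    visit_type=None,
    n_outpatient=None,
    n_inpatient=None,
    diagnosis=None,
    ids=None,
) -> SurveyDataset:
    """Build a valid dataset from plain arrays; the OOP total lands in drug_cost."""
    total_exp = np.asarray(total_exp, dtype=float)
    n = total_exp.size
    food_exp = np.asarray(food_exp, dtype=float)
    oop_total = np.asarray(oop_total, dtype=float)
    size = np.ones(n, dtype=int) if size is None else np.asarray(size, dtype=int)
    if ids is None:
        ids = [f"H{i:04d}" for i in range(n)]
    households = pd.DataFrame(
        {
            "household_id": ids,
            "size": size,
            "annual_total_exp": total_exp,
            "annual_food_exp": food_exp,
            "residence": residence if residence is not None else ["addis_ababa"] * n,
        }
    )
    oop = pd.DataFrame({"household_id": ids})
    for c in COST_COLUMNS:
        oop[c] = 0.0
    oop["drug_cost"] = oop_total
    oop["n_outpatient"] = 0 if n_outpatient is None else n_outpatient
    oop["n_inpatient"] = 1 if n_inpatient is None else n_inpatient
    oop["facility_type"] = facility if facility is not None else "public"
    oop["visit_type"] = visit_type if visit_type is not None else "inpatient_only"
    oop["diagnosis"] = diagnosis if diagnosis is not None else "lower_limb"
    return SurveyDataset(
        households=households[HOUSEHOLD_COLUMNS], oop_records=oop[OOP_COLUMNS]
    )


def random_dataset(rng: np.random.Generator, n: int | None = None) -> SurveyDataset:
    """Small random dataset for oracle-equivalence checks."""
    if n is None:
        n = int(rng.integers(3, 21))
    total = rng.lognormal(np.log(2000.0), 0.7, size=n)
    food = total * rng.uniform(0.2, 0.8, size=n)
    oop = rng.lognormal(np.log(300.0), 1.2, size=n)
    oop[rng.random(n) < 0.15] = 0.0  # some zero-spending households
    size = rng.integers(1, 9, size=n)
    return make_dataset(total, food, oop, size=size)


@pytest.fixture(scope="session")
def default_synth():
    """One default-parameter synthetic survey, shared across tests."""
    from finrisk import default_params, generate

    return generate(default_params(), seed=123)
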