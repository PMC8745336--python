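"""Cost aggregation, currency conversion, and the cost summary table."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from finrisk import annualize, convert_currency, food_share, project_total_oop, total_oop
from finrisk.costing import CostBreakdown, oop_totals, per_event_means, table2
from finrisk.survey import COST_COLUMNS, HouseholdEconomy, OOPRecord

from conftest import make_dataset

money = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


def _record(**costs) -> OOPRecord:
    base = dict.fromkeys(COST_COLUMNS, 0.0)
    base.update(costs)
    return OOPRecord(
        household_id="H1",
        **base,
        n_outpatient_visits=1,
        n_inpatient_admissions=0,
        facility_type="public",
        visit_type="outpatient_only",
        diagnosis="head",
    )


class TestConvertCurrency:
    def test_insurance_cap_is_seventy_dollars(self):
        assert round(convert_currency(2000.0, 28.574)) == 70

    @pytest.mark.parametrize("amount,expected", [(0.0, 0.0), (28.574, 1.0)])
    def test_fixed_points(self, amount, expected):
        assert convert_currency(amount, 28.574) == pytest.approx(expected)

    @given(a=money, b=money)
    def test_linearity(self, a, b):
        f = lambda x: convert_currency(x, 28.574)
        assert f(a + b) == pytest.approx(f(a) + f(b), rel=1e-12, abs=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(10.0, 0.0)

    def test_vectorised_over_arrays(self):
        out = convert_currency(np.array([0.0, 28.574]), 28.574)
        np.testing.assert_allclose(out, [0.0, 1.0])


class TestAnnualize:
    @pytest.mark.parametrize(
        "amount,period,expected",
        [(100.0, "monthly", 1200.0), (1200.0, "annual", 1200.0), (0.0, "monthly", 0.0)],
    )
    def test_scaling(self, amount, period, expected):
        assert annualize(amount, period) == expected

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError):
            annualize(10.0, "weekly")


class TestTotalOop:
    def test_all_zero(self):
        bd = total_oop(_record())
        assert (bd.direct_medical, bd.direct_nonmedical, bd.total) == (0.0, 0.0, 0.0)

    def test_component_sum(self):
        bd = total_oop(
            _record(
                procedure_cost=100.0,
                drug_cost=50.0,
                bed_cost=25.0,
                lab_imaging_cost=10.0,
                transport_cost=20.0,
                attendant_cost=30.0,
                other_cost=15.0,
            )
        )
        assert (bd.direct_medical, bd.direct_nonmedical, bd.total) == (185.0, 65.0, 250.0)

    @given(vals=st.lists(st.floats(min_value=0, max_value=1e5), min_size=7, max_size=7))
    def test_equals_seven_term_sum_and_is_permutation_invariant(self, vals):
        med, nonmed = vals[:4], vals[4:]
        bd = total_oop(_record(**dict(zip(COST_COLUMNS, vals))))
        assert bd.total == pytest.approx(sum(vals), rel=1e-12)
        # permuting within each block leaves the breakdown unchanged
        perm = med[::-1] + nonmed[::-1]
        bd2 = total_oop(_record(**dict(zip(COST_COLUMNS, perm))))
        assert bd2.direct_medical == pytest.approx(bd.direct_medical, rel=1e-12)
        assert bd2.direct_nonmedical == pytest.approx(bd.direct_nonmedical, rel=1e-12)

    def test_dataset_totals_match_per_record_loop(self, default_synth):
        totals = oop_totals(default_synth)
        for i, rec in enumerate(default_synth.iter_oop_records()):
            assert totals.loc[i, "total_oop"] == pytest.approx(total_oop(rec).total)


class TestProjection:
    def test_forced_arithmetic(self):
        assert project_total_oop(50.0, 300.0, 2, 1) == 400.0

    def test_zero_visits(self):
        assert project_total_oop(50.0, 300.0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            project_total_oop(50.0, 300.0, -1, 0)

    @given(
        n_out=st.integers(min_value=0, max_value=50),
        n_in=st.integers(min_value=0, max_value=50),
    )
    def test_monotone_in_each_count(self, n_out, n_in):
        base = project_total_oop(40.0, 250.0, n_out, n_in)
        assert project_total_oop(40.0, 250.0, n_out + 1, n_in) >= base
        assert project_total_oop(40.0, 250.0, n_out, n_in + 1) >= base

    def test_projection_from_enumerated_visit_records(self):
        # three households with known per-event costs: the sample means feed
        # the projection, which must equal the enumerated sum
        ds = make_dataset(
            [2000.0] * 3,
            [800.0] * 3,
            [100.0, 200.0, 300.0],
            n_outpatient=[1, 2, 3],
            n_inpatient=[0, 0, 0],
            visit_type="outpatient_only",
        )
        mean_out, mean_in = per_event_means(ds)
        # per-event costs: 100/1, 200/2, 300/3 -> all 100; weights 1,2,3
        assert mean_out == pytest.approx(100.0)
        assert mean_in == 0.0
        assert project_total_oop(mean_out, mean_in, 4, 0) == pytest.approx(400.0)


class TestFoodShare:
    def test_published_means_give_46_percent(self):
        h = HouseholdEconomy(
            household_id="x",
            size=4,
            annual_total_expenditure=2520.0,
            annual_food_expenditure=2520.0 - 1368.0,
            residence="outside",
        )
        assert food_share(h) == pytest.approx(0.4571, abs=5e-4)
        assert round(100 * food_share(h)) == 46

    @pytest.mark.parametrize("food,expected", [(0.0, 0.0), (1000.0, 1.0)])
    def test_boundaries(self, food, expected):
        h = HouseholdEconomy(
            household_id="x",
            size=1,
            annual_total_expenditure=1000.0,
            annual_food_expenditure=food,
            residence="addis_ababa",
        )
        assert food_share(h) == expected

    def test_zero_total_rejected(self):
        h = HouseholdEconomy(
            household_id="x",
            size=1,
            annual_total_expenditure=0.0,
            annual_food_expenditure=0.0,
            residence="addis_ababa",
        )
        with pytest.raises(ValueError):
            food_share(h)


class TestTable2:
    def test_group_cells_match_brute_force(self, default_synth):
        tbl = table2(default_synth)
        t = default_synth.table
        tot = oop_totals(default_synth)["total_oop"]
        pub = tot[(t["facility_type"] == "public").to_numpy()]
        row = tbl[(tbl.section == "facility_type") & (tbl.group == "public")].iloc[0]
        assert row["n"] == len(pub)
        assert row["mean"] == pytest.approx(pub.mean())
        assert row["median"] == pytest.approx(pub.median())
        drug = tbl[(tbl.section == "expense_category") & (tbl.group == "drug_cost")].iloc[0]
        assert drug["mean"] == pytest.approx(t["drug_cost"].mean())

    def test_total_row_covers_everyone(self, default_synth):
        tbl = table2(default_synth)
        assert int(tbl[tbl.section == "total"].iloc[0]["n"]) == default_synth.n


def test_cost_breakdown_total_identity():
    bd = CostBreakdown(direct_medical=3.5, direct_nonmedical=1.25)
    assert bd.total == 4.75
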