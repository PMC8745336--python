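"""Determinants model, one-way ANOVA, and the sample-size formula."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from finrisk import (
    fit_che_determinants,
    oop_anova,
    total_recruitment,
    two_proportion_sample_size,
)
from finrisk.inference import anova_oneway
from finrisk.simulate import default_params, generate, generate_with_known_truth

from conftest import make_dataset


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([np.array([5.0, 6.0, 7.0]), np.array([5.0, 6.0, 7.0])])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_group_example(self):
        # SSB = 54 with df 1, SSW = 4 with df 4 -> F = 54/1 / (4/4) = 54
        res = anova_oneway([np.array([1.0, 2.0, 3.0]), np.array([7.0, 8.0, 9.0])])
        assert res.f_statistic == pytest.approx(54.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_shift_invariance(self):
        g1, g2 = np.array([1.0, 2.0, 3.0]), np.array([7.0, 8.0, 9.0])
        a = anova_oneway([g1, g2])
        b = anova_oneway([g1 + 100.0, g2 + 100.0])
        assert b.f_statistic == pytest.approx(a.f_statistic, rel=1e-12)

    def test_two_group_f_is_squared_pooled_t(self):
        rng = np.random.default_rng(3)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.7, 1, 9)
        res = anova_oneway([g1, g2])
        t, _ = stats.ttest_ind(g1, g2, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([2.0, 3.0])])

    def test_dataset_grouping_government_vs_private(self, default_synth):
        res = oop_anova(default_synth)
        t = default_synth.table
        n = len(t)
        assert res.df_between == 1
        assert res.df_within == n - 2
        assert res.f_statistic > 0
        assert 0 <= res.p_value <= 1


class TestSampleSize:
    def test_design_calculation_with_rounded_critical_values(self):
        spec = two_proportion_sample_size(0.50, 0.30, rounded_z=True)
        assert spec.raw == pytest.approx(90.16, abs=1e-9)
        assert spec.n_per_group == 91

    def test_exact_quantiles_give_slightly_larger_raw(self):
        spec = two_proportion_sample_size(0.50, 0.30)
        # z_beta = 0.8416... > 0.84, so the exact raw value exceeds 90.16
        assert spec.raw > 90.16
        assert spec.n_per_group == 91

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_sample_size(0.4, 0.4)

    @given(
        p1=st.floats(min_value=0.05, max_value=0.95),
        delta=st.floats(min_value=0.02, max_value=0.4),
    )
    def test_symmetry_in_the_two_proportions(self, p1, delta):
        p2 = p1 - delta
        if not 0.0 < p2 < 1.0:
            return
        a = two_proportion_sample_size(p1, p2)
        b = two_proportion_sample_size(p2, p1)
        assert a.n_per_group == b.n_per_group

    def test_n_decreasing_in_the_gap(self):
        gaps = [0.05, 0.10, 0.20, 0.30]
        ns = [two_proportion_sample_size(0.5 + g / 2, 0.5 - g / 2).n_per_group for g in gaps]
        assert ns == sorted(ns, reverse=True)

    def test_n_diverges_as_proportions_approach(self):
        assert two_proportion_sample_size(0.501, 0.499).n_per_group > 10**5

    def test_raw_scales_with_squared_z_sum(self):
        a = two_proportion_sample_size(0.5, 0.3, alpha=0.05, power=0.80)
        za = stats.norm.ppf(0.975)
        zb = stats.norm.ppf(0.80)
        var = 0.5 * 0.5 + 0.3 * 0.7
        assert a.raw == pytest.approx((za + zb) ** 2 * var / 0.04, rel=1e-12)

    def test_recruitment_helper_inflates_for_nonresponse(self):
        assert total_recruitment(91, 5, 0.05) == math.ceil(91 * 5 * 1.05)
        with pytest.raises(ValueError):
            total_recruitment(91, 5, 1.0)


class TestDeterminants:
    def test_null_covariate_recovers_unit_odds_ratio(self):
        # with ~13% private care, n = 40,000 puts the Wald SE of the
        # log-odds near 0.03, so [0.9, 1.1] is a > 3-sigma band
        ds, _ = generate_with_known_truth(
            default_params(n_households=40_000),
            {"logistic": {"private_facility": 0.0}, "che_rate": 0.5},
            seed=101,
        )
        res = fit_che_determinants(ds, covariates=("private_facility",))
        assert res.converged
        aor = res.term("private_facility")["aor"]
        assert 0.9 <= aor <= 1.1

    def test_planted_log_odds_recovered(self):
        ds, truth = generate_with_known_truth(
            default_params(n_households=40_000),
            {"logistic": {"private_facility": 1.0}, "che_rate": 0.5},
            seed=202,
        )
        res = fit_che_determinants(ds, covariates=("private_facility",))
        term = res.term("private_facility")
        # point estimate within a 3-sigma band of the planted e^1
        assert 0.9 * math.e <= term["aor"] <= 1.1 * math.e

    def test_coefficients_shrink_to_zero_on_balanced_null(self):
        ds, _ = generate_with_known_truth(
            default_params(n_households=10_000),
            {"logistic": {}, "che_rate": 0.5},
            seed=303,
        )
        res = fit_che_determinants(ds)
        assert res.converged
        for term in res.terms:
            if term["name"] == "intercept":
                continue
            assert abs(term["coef"]) < 0.25

    def test_single_class_outcome_reports_nonconvergence(self):
        ds = make_dataset([1000.0] * 30, [0.0] * 30, [0.0] * 30)
        res = fit_che_determinants(ds, covariates=("hospitalized",))
        assert not res.converged
        assert res.terms == []

    def test_full_default_model_on_synthetic_data(self, default_synth):
        res = fit_che_determinants(default_synth)
        assert res.converged
        names = {t["name"] for t in res.terms}
        assert {"intercept", "hospitalized", "private_facility", "residence_outside"} <= names
        assert {f"quintile_{k}" for k in range(1, 5)} <= names
        for t in res.terms:
            assert t["ci_low"] <= t["aor"] <= t["ci_high"]
            assert t["ci_low"] > 0

    def test_unknown_covariate_rejected(self, default_synth):
        with pytest.raises(ValueError):
            fit_che_determinants(default_synth, covariates=("astrology",))
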