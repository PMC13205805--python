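"""Monetary valuation, implementation costs, break-even, projections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from picost import (
    CostParameters,
    TranslationSpec,
    break_even_per_day,
    generate_cohort,
    gross_offset,
    implementation_cost,
    net_impact,
    project_case,
    project_strata,
    round_jpy,
)
from picost.cohort import GeneratorSpec
from picost.exceptions import ValidationError


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(6416.666, 6417), (0.5, 1), (-0.5, -1), (2.4, 2), (-2.6, -3), (0.0, 0)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_jpy(x) == expected


class TestCostParameters:
    def test_defaults_match_unit_cost_construction(self):
        params = CostParameters()
        assert params.per_day_value == 4000.0
        assert params.es_labor_per_day == 750.0
        assert params.impl_fixed_per_case == 10_017.0  # round(77000/12) + 3600

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            CostParameters(cases_per_device=0)
        with pytest.raises(ValidationError):
            CostParameters(device_cost=-1)


class TestGrossOffset:
    @pytest.mark.parametrize(
        "saved,expected",
        [(185.4205, 741_682), (45.1023, 180_409), (0.0, 0)],
    )
    def test_reported_examples(self, saved, expected):
        assert round_jpy(gross_offset(saved, 4000.0)) == expected

    def test_negative_days_pass_through(self):
        assert gross_offset(-10.0, 4000.0) == -40_000.0

    def test_proportional_in_value(self):
        assert gross_offset(126.93, 8000.0) == 2 * gross_offset(126.93, 4000.0)


class TestImplementationCost:
    @pytest.mark.parametrize(
        "t_es,expected_total",
        [(73.5795, 65_202), (17.8977, 23_440)],
    )
    def test_reported_examples(self, t_es, expected_total):
        impl = implementation_cost(t_es, CostParameters())
        assert round_jpy(impl.total) == expected_total
        assert impl.total == pytest.approx(impl.fixed + impl.variable, abs=1e-9)

    def test_free_intervention(self):
        params = CostParameters(
            device_cost=0.0, consumables_per_case=0.0, es_staff_minutes_per_day=0.0
        )
        impl = implementation_cost(40.0, params)
        assert impl.total == 0.0 and impl.per_day == 0.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            implementation_cost(0.0, CostParameters())

    @given(t_es=st.floats(1.0, 400.0))
    def test_per_day_times_duration_equals_total(self, t_es):
        impl = implementation_cost(t_es, CostParameters())
        assert impl.per_day * t_es == pytest.approx(impl.total, rel=1e-12)


class TestNetImpact:
    @pytest.mark.parametrize(
        "gross,impl,expected",
        [(741_682.1, 65_201.7, 676_480), (180_409.1, 23_440.3, 156_969)],
    )
    def test_reported_examples(self, gross, impl, expected):
        assert round_jpy(net_impact(gross, impl)) == expected

    @given(
        t_placebo=st.floats(20.0, 400.0),
        r=st.floats(1.05, 8.0),
        value=st.floats(0.0, 12_000.0),
    )
    def test_two_formulations_agree(self, t_placebo, r, value):
        """gross - C_impl/day * T_ES equals gross - (fixed + labor * T_ES)."""
        params = CostParameters()
        t_es = t_placebo / r
        saved = t_placebo - t_es
        gross = gross_offset(saved, value)
        impl = implementation_cost(t_es, params)
        via_per_day = gross - impl.per_day * t_es
        via_components = gross - (params.impl_fixed_per_case
                                  + params.es_labor_per_day * t_es)
        assert via_per_day == pytest.approx(via_components, rel=1e-10, abs=1e-6)

    def test_zero_days_saved_is_pure_cost(self):
        impl = implementation_cost(50.0, CostParameters())
        assert net_impact(gross_offset(0.0, 4000.0), impl.total) == -impl.total


class TestBreakEven:
    def test_base_case_threshold(self):
        t_es = 177.3 / 3.52
        assert break_even_per_day(177.3, t_es, 4000.0) == pytest.approx(
            4000.0 * (3.52 - 1.0), rel=1e-12
        )

    def test_no_benefit_no_budget(self):
        assert break_even_per_day(100.0, 100.0, 4000.0) == 0.0

    @given(
        t_placebo=st.floats(30.0, 400.0),
        r=st.floats(1.1, 8.0),
        value=st.floats(100.0, 12_000.0),
    )
    def test_matches_bisection_root_of_net_impact(self, t_placebo, r, value):
        t_es = t_placebo / r
        gross = gross_offset(t_placebo - t_es, value)
        root = brentq(lambda c: gross - c * t_es, 0.0, 1e9, xtol=1e-9)
        assert break_even_per_day(t_placebo, t_es, value) == pytest.approx(
            root, abs=1e-6
        )

    @given(
        t_placebo=st.floats(30.0, 400.0),
        r=st.floats(1.1, 8.0),
        device=st.floats(0.0, 500_000.0),
        minutes=st.floats(0.0, 120.0),
    )
    def test_threshold_consistency_with_net_sign(self, t_placebo, r, device, minutes):
        """net impact > 0 iff average implementation cost < break-even."""
        params = CostParameters(device_cost=device, es_staff_minutes_per_day=minutes)
        t_es = t_placebo / r
        gross = gross_offset(t_placebo - t_es, 4000.0)
        impl = implementation_cost(t_es, params)
        net = net_impact(gross, impl.total)
        threshold = break_even_per_day(t_placebo, t_es, 4000.0)
        if abs(net) > 1e-6:
            assert (net > 0) == (impl.per_day < threshold)


class TestProjections:
    def test_base_case_projection(self):
        proj = project_case(177.3, TranslationSpec(r=3.52))
        assert proj.t_es == pytest.approx(50.4, abs=0.05)
        assert proj.days_saved == pytest.approx(126.9, abs=0.05)
        assert round_jpy(proj.gross_offset) == 507_723
        assert round_jpy(proj.impl_total) == 47_794
        assert proj.c_impl_per_day == pytest.approx(949, abs=1)
        assert round_jpy(proj.net_impact) == 459_929
        assert proj.break_even_per_day == pytest.approx(10_080.0, abs=1e-9)

    def test_unity_ratio_projection_is_pure_cost(self):
        proj = project_case(177.3, TranslationSpec(r=1.0))
        assert proj.days_saved == 0.0
        assert proj.net_impact == pytest.approx(-proj.impl_total, rel=1e-12)

    def test_projection_internal_identities(self):
        proj = project_case(259.0, TranslationSpec(r=3.52))
        assert proj.impl_total == pytest.approx(
            proj.impl_fixed + proj.impl_variable, abs=1e-9
        )
        assert proj.c_impl_per_day * proj.t_es == pytest.approx(
            proj.impl_total, rel=1e-12
        )
        assert proj.net_impact == pytest.approx(
            proj.gross_offset - proj.impl_total, abs=1e-9
        )

    def test_strata_rows_match_per_case_projection(self, default_cohort):
        spec = TranslationSpec(r=3.52)
        rows = project_strata(default_cohort, spec=spec)
        assert [(p.label, p.n) for p in rows] == [
            ("deep/10-18", 5),
            ("deep/>=19", 7),
        ]
        for row, t_pl in zip(rows, (63.0, 259.0)):
            ref = project_case(t_pl, spec)
            assert row.t_es == pytest.approx(ref.t_es, rel=1e-12)
            assert row.net_impact == pytest.approx(ref.net_impact, rel=1e-12)

    def test_all_strata_cohort_gets_six_rows(self):
        strata = [
            ("<=9", "superficial", 1),
            ("10-18", "superficial", 1),
            (">=19", "superficial", 1),
            ("<=9", "deep", 1),
            ("10-18", "deep", 1),
            (">=19", "deep", 1),
        ]
        cohort = generate_cohort(GeneratorSpec(n_patients=6, strata=strata, seed=3))
        rows = project_strata(cohort, spec=TranslationSpec(r=2.0))
        assert len(rows) == 6
        assert all(p.n == 1 for p in rows)

    def test_single_stratum_cohort_matches_project_case(self, make_cohort):
        cohort = make_cohort([0.3, 0.2], [0.1, 0.05], design_r=12, depth="deep")
        rows = project_strata(cohort, spec=TranslationSpec(r=3.52))
        assert len(rows) == 1
        ref = project_case(63.0, TranslationSpec(r=3.52))
        assert rows[0].gross_offset == pytest.approx(ref.gross_offset, rel=1e-12)
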