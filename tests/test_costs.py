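"""Cost-engine unit and property tests."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdburden.costs import (
    absenteeism_fraction,
    apply_friction_period,
    care_costs,
    convert_currency,
    derive_paid_work_unit_cost,
    direct_costs,
    drug_monthly_cost,
    early_departure_cost,
    gdp_share,
    out_of_pocket_valuation,
    overall_reduction,
    paid_work_costs,
    presenteeism_fraction,
    total_indirect,
    CostBreakdown,
)
from cdburden.records import CareRecord, ExpenseAnswer, ResourceUseRecord, WorkRecord


class TestUnitCostDerivation:
    def test_printed_macro_inputs(self):
        rate = derive_paid_work_unit_cost(420_164.45e6, 16_234_000, 2016, 0.65)
        assert round(rate, 2) == 8.34

    def test_without_labour_share(self):
        rate = derive_paid_work_unit_cost(420_164.45e6, 16_234_000, 2016, 1.0)
        assert round(rate, 2) == 12.84

    @pytest.mark.parametrize("bad", [dict(gdp=0), dict(workers=0), dict(max_hours=-1), dict(elasticity=0)])
    def test_nonpositive_inputs_fatal(self, bad):
        kwargs = dict(gdp=1e9, workers=1e6, max_hours=2000, elasticity=0.65)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            derive_paid_work_unit_cost(**kwargs)


class TestAbsenteeismFraction:
    def test_nothing_missed(self):
        assert absenteeism_fraction(0, 0, 21, 8) == 0.0

    def test_all_days_missed(self):
        assert absenteeism_fraction(21, 0, 21, 8) == 1.0

    def test_hand_arithmetic(self):
        # (2*8 + 3/5*(21-2)) / (21*8) = 27.4/168
        assert absenteeism_fraction(2, 3, 21, 8) == pytest.approx(27.4 / 168)

    def test_missing_input(self):
        assert absenteeism_fraction(None, 0, 21, 8) is None
        assert absenteeism_fraction(1, 0, None, 8) is None

    def test_clamped_to_unit_interval(self):
        # exaggerated single-hours answer pushes the raw value above 1
        assert absenteeism_fraction(20, 100, 21, 8) == 1.0

    @given(
        L_d=st.floats(1, 31),
        L_h=st.floats(1, 16),
        frac_d=st.floats(0, 1),
        A_h=st.floats(0, 40),
    )
    def test_always_in_unit_interval(self, L_d, L_h, frac_d, A_h):
        r = absenteeism_fraction(frac_d * L_d, A_h, L_d, L_h)
        assert 0.0 <= r <= 1.0


class TestPresenteeismAndOverall:
    @pytest.mark.parametrize("score,expected", [(0, 0.0), (4, 0.4), (10, 1.0)])
    def test_factor_of_point_one(self, score, expected):
        assert presenteeism_fraction(score) == pytest.approx(expected)

    def test_out_of_range_missing(self):
        assert presenteeism_fraction(11) is None
        assert presenteeism_fraction(-1) is None

    def test_overall_examples(self):
        assert overall_reduction(1.0, 0.77) == pytest.approx(1.0)
        assert overall_reduction(0.0, 0.4) == pytest.approx(0.4)
        assert overall_reduction(0.163, 0.4) == pytest.approx(0.163 + (1 - 0.163) * 0.4)

    @given(ra=st.floats(0, 1), rp=st.floats(0, 1))
    def test_overall_dominates_components(self, ra, rp):
        ro = overall_reduction(ra, rp)
        assert 0.0 <= ro <= 1.0 + 1e-12
        assert ro >= max(ra, rp) - 1e-12


def _worker(**kw) -> WorkRecord:
    base = dict(occupational_activity=True, L_d=21.0, L_h=8.0, A_d=0.0, A_h=0.0, presenteeism_score=0)
    base.update(kw)
    return WorkRecord(**base)


class TestPaidWorkCosts:
    def test_no_loss(self):
        assert paid_work_costs(_worker(), 8.34) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic_full_time(self):
        absent, present, h_a, h_p = paid_work_costs(_worker(A_d=2, A_h=3, presenteeism_score=4), 8.34)
        r_a = 27.4 / 168
        assert h_a == pytest.approx(168 * r_a)
        assert absent == pytest.approx(168 * r_a * 8.34)
        assert present == pytest.approx(168 * (1 - r_a) * 0.4 * 8.34)

    def test_non_worker_zero_not_missing(self):
        absent, present, h_a, h_p = paid_work_costs(WorkRecord(occupational_activity=False), 8.34)
        assert (absent, present, h_a, h_p) == (0.0, 0.0, 0.0, 0.0)

    def test_unknown_work_status_missing(self):
        assert paid_work_costs(WorkRecord(), 8.34) == (None, None, None, None)

    def test_missing_working_time_missing_costs(self):
        assert paid_work_costs(_worker(L_d=None), 8.34)[0] is None

    @given(unit=st.floats(0.01, 100), scale=st.floats(0.1, 10))
    def test_homogeneous_in_unit_cost(self, unit, scale):
        w = _worker(A_d=3, A_h=2, presenteeism_score=5)
        a1, p1, *_ = paid_work_costs(w, unit)
        a2, p2, *_ = paid_work_costs(w, unit * scale)
        assert a2 == pytest.approx(a1 * scale)
        assert p2 == pytest.approx(p1 * scale)

    @given(
        A_d=st.integers(0, 21),
        A_h=st.floats(0, 40),
        score=st.integers(0, 10),
    )
    def test_hours_conservation(self, A_d, A_h, score):
        w = _worker(A_d=float(A_d), A_h=A_h, presenteeism_score=score)
        _, _, h_a, h_p = paid_work_costs(w, 8.34)
        r_o = overall_reduction(
            absenteeism_fraction(w.A_d, w.A_h, w.L_d, w.L_h), presenteeism_fraction(score)
        )
        assert h_a + h_p == pytest.approx(21 * 8 * r_o)


class TestEarlyDeparture:
    def test_disability_level(self):
        w = WorkRecord(on_pension=True, social_pension=False, pension_disability_level=0.75)
        assert early_departure_cost(w, 8.34, 168) == pytest.approx(0.75 * 168 * 8.34)

    def test_social_pension_full_inability(self):
        w = WorkRecord(on_pension=True, social_pension=True)
        assert early_departure_cost(w, 8.34, 168) == pytest.approx(1401.12, abs=0.005)

    def test_not_on_pension_zero(self):
        assert early_departure_cost(WorkRecord(on_pension=False), 8.34) == 0.0

    def test_pension_without_level_missing(self):
        w = WorkRecord(on_pension=True, social_pension=False)
        assert early_departure_cost(w, 8.34) is None


class TestFriction:
    def test_departure_beyond_period_zeroed(self):
        assert apply_friction_period(1000.0, 24.0, 90.0) == 0.0

    def test_recent_departure_unchanged(self):
        assert apply_friction_period(1000.0, 1.0, 90.0) == 1000.0

    def test_disabled_is_identity(self):
        assert apply_friction_period(1000.0, 24.0, None) == 1000.0

    def test_missing_departure_time_retained(self):
        assert apply_friction_period(1000.0, None, 90.0) == 1000.0


class TestCareCosts:
    def test_no_assistance(self):
        care = CareRecord(assistance_hours_per_week={"family_unpaid": 0.0})
        assert care_costs(care, 5.27, 4.345) == (0.0, 0.0, 0.0)

    def test_family_only(self):
        care = CareRecord(assistance_hours_per_week={"family_unpaid": 10.0})
        unpaid, informal, uncomp = care_costs(care, 5.27, 4.345)
        assert unpaid == pytest.approx(10 * 5.27 * 4.345)
        assert informal == unpaid
        assert uncomp == 0.0

    def test_professional_split(self):
        care = CareRecord(
            assistance_hours_per_week={
                "family_unpaid": 4.0,
                "nonrelative_unpaid": 1.0,
                "professional_or_paid": 2.0,
            }
        )
        unpaid, informal, uncomp = care_costs(care, 5.27, 4.345)
        factor = 5.27 * 4.345
        assert unpaid == pytest.approx(7 * factor)
        assert informal == pytest.approx(5 * factor)
        assert uncomp == pytest.approx(2 * factor)
        assert uncomp <= unpaid

    def test_missing_hours(self):
        assert care_costs(CareRecord(), 5.27, 4.345) == (None, None, None)

    @given(
        fam=st.floats(0, 100),
        nonrel=st.floats(0, 50),
    )
    def test_informal_bounded_by_unpaid_without_professionals(self, fam, nonrel):
        care = CareRecord(assistance_hours_per_week={"family_unpaid": fam, "nonrelative_unpaid": nonrel})
        unpaid, informal, _ = care_costs(care, 5.27, 4.345)
        assert informal == pytest.approx(unpaid)


class TestTotalIndirect:
    def test_all_zero(self):
        cb = CostBreakdown(absenteeism=0, presenteeism=0, early_departure=0, unpaid_work_uncompensated=0, informal_care=0)
        assert total_indirect(cb) == 0.0

    def test_component_sum(self):
        cb = CostBreakdown(
            absenteeism=100.0,
            presenteeism=200.0,
            early_departure=300.0,
            unpaid_work_uncompensated=10.0,
            informal_care=40.0,
        )
        assert total_indirect(cb, include_early_departure=True) == pytest.approx(650.0)
        assert total_indirect(cb, include_early_departure=False) == pytest.approx(350.0)

    def test_missing_component_propagates(self):
        cb = CostBreakdown(absenteeism=None, presenteeism=0, early_departure=0, unpaid_work_uncompensated=0, informal_care=0)
        assert total_indirect(cb) is None


class TestDirectCosts:
    def test_no_use_no_drugs(self, unit_costs):
        ru = ResourceUseRecord(
            consultations_total=0, consultations_private=0, hospitalisation_count=0,
            one_day_hospitalisations=0, surgical_hospitalisation=False,
        )
        out = direct_costs(ru, frozenset(), unit_costs)
        assert out["consultations_public"] == 0.0
        assert out["consultations_private"] == 0.0
        assert out["hospitalisations"] == 0.0
        assert out["treatment"] == 0.0

    def test_priced_example(self, unit_costs):
        ru = ResourceUseRecord(
            consultations_total=2, consultations_private=1, private_consultation_avg_cost=36.0,
            hospitalisation_count=1, one_day_hospitalisations=0, surgical_hospitalisation=False,
        )
        out = direct_costs(ru, frozenset(), unit_costs)
        assert out["consultations_public"] == pytest.approx(7.57)
        assert out["consultations_private"] == pytest.approx(36.0)
        assert out["hospitalisations"] == pytest.approx(975.98)

    def test_surgical_hospitalisation_priced_once(self, unit_costs):
        ru = ResourceUseRecord(hospitalisation_count=2, one_day_hospitalisations=0, surgical_hospitalisation=True)
        out = direct_costs(ru, frozenset(), unit_costs)
        assert out["hospitalisations"] == pytest.approx(1553.16 + 975.98)

    def test_one_day_hospitalisation(self, unit_costs):
        ru = ResourceUseRecord(hospitalisation_count=1, one_day_hospitalisations=1, surgical_hospitalisation=False)
        out = direct_costs(ru, frozenset(), unit_costs)
        assert out["hospitalisations"] == pytest.approx(109.80)

    def test_mesalazine_monthly(self, unit_costs):
        assert drug_monthly_cost("mesalazine", unit_costs) == pytest.approx(30.44 * 0.53)

    def test_mercaptopurine_weight_based(self, unit_costs):
        # 1.25 mg/kg/day at the default body weight is exactly one priced dose
        expected = 1.25 * 64.71 / 80.89 * 30.44 * 0.31
        assert drug_monthly_cost("mercaptopurine", unit_costs) == pytest.approx(expected)
        assert drug_monthly_cost("mercaptopurine", unit_costs) == pytest.approx(30.44 * 0.31, rel=1e-4)

    def test_biologic_monthly_is_annual_course_over_twelve(self, unit_costs):
        assert drug_monthly_cost("adalimumab", unit_costs) == pytest.approx(1240 / 80 * 967.01 / 12)
        assert drug_monthly_cost("infliximab", unit_costs) == pytest.approx(40 * 64.71 / 100 * 298.23 / 12)

    def test_biologic_user_gets_diagnostics(self, unit_costs):
        ru = ResourceUseRecord()
        with_bio = direct_costs(ru, frozenset({"biologic_infliximab"}), unit_costs)
        expected = drug_monthly_cost("infliximab", unit_costs) + 54.90
        assert with_bio["treatment"] == pytest.approx(expected)

    def test_unknown_drug_fatal(self, unit_costs):
        with pytest.raises(KeyError):
            drug_monthly_cost("aspirin", unit_costs)


class TestOutOfPocket:
    @pytest.mark.parametrize(
        "low,high,expected",
        [
            (23.5, 46.9, (35.2, 23.5, 46.9)),
            (0.0, 23.5, (11.75, 0.0, 23.5)),
            (200.0, 200.0, (200.0, 200.0, 200.0)),
        ],
    )
    def test_valuation(self, low, high, expected):
        got = out_of_pocket_valuation(ExpenseAnswer(low, high))
        assert got == pytest.approx(expected)

    def test_missing(self):
        assert out_of_pocket_valuation(ExpenseAnswer()) is None


class TestNormalisation:
    def test_gdp_share_printed_values(self):
        assert round(gdp_share(462.47, 10_900.0), 1) == 50.9

    def test_gdp_share_zero(self):
        assert gdp_share(0.0, 10_900.0) == 0.0

    def test_monthly_gdp_is_hundred_percent(self):
        assert gdp_share(10_900.0 / 12, 10_900.0) == pytest.approx(100.0)

    @pytest.mark.parametrize("pln,eur", [(4.2624, 1.0), (0.0, 0.0), (42.624, 10.0)])
    def test_currency_conversion(self, pln, eur):
        assert convert_currency(pln, 4.2624) == pytest.approx(eur)

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            convert_currency(1.0, 0.0)
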