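"""Cost kernel: labour valuation, event costing, payer split, base case."""

from decimal import Decimal

import pytest
from hypothesis import given, settings, strategies as st

from oatcost import (
    CohortUndefinedError,
    DosingEvent,
    base_case,
    daily_administration_count,
    event_costs,
    labour_cost,
    medication_supply_cost,
    order_costs,
)
from oatcost.costing import PAYERS, build_dosing_events
from oatcost.money import aud
from oatcost.params import ConfigurationError, LoadingRates, Role

from conftest import make_params

def _without_consumables(params):
    return params.model_copy(
        update={
            "medications": [
                m.model_copy(update={"consumables_per_dose": Decimal("0")})
                for m in params.medications
            ]
        }
    )


RN = Role(name="registered_nurse_y8", hourly_wage=Decimal("40.00"))
NO_LOAD = LoadingRates(oncost_rate=Decimal("0"), overhead_rate=Decimal("0"))
STUDY_LOAD = LoadingRates()


class TestLabourCost:
    @pytest.mark.parametrize(
        "minutes,loadings,expected",
        [
            (0, STUDY_LOAD, Decimal("0.00")),  # zero time costs nothing
            (60, NO_LOAD, Decimal("40.00")),  # identity loadings: the bare wage
            (30, STUDY_LOAD, Decimal("30.70")),  # 20 x (1 + 0.26 + 0.275)
        ],
    )
    def test_examples(self, minutes, loadings, expected):
        assert aud(labour_cost(minutes, RN, loadings)) == expected

    def test_compound_loadings_flag(self):
        # 20 x 1.26 x 1.275 = 32.13
        assert aud(labour_cost(30, RN, STUDY_LOAD, compound=True)) == Decimal("32.13")

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError, match="minutes"):
            labour_cost(-1, RN, STUDY_LOAD)


class TestDailyAdministrations:
    @pytest.mark.parametrize("cohort,days,expected", [(239, 31, 7409), (47, 31, 1457), (0, 31, 0)])
    def test_counts(self, cohort, days, expected):
        assert daily_administration_count(cohort, days) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            daily_administration_count(-1, 31)


class TestEventCosts:
    def setup_method(self):
        self.params = make_params()

    def _event(self, patients, events=1.0):
        return DosingEvent(
            facility="F", medication="methadone", patients_dosed=patients, events_per_month=events
        )

    def test_zero_patients_only_fixed_components(self):
        bd = event_costs([self._event(0)], self.params)
        assert bd.payer_total("JHFMHN") > 0  # prep + stock check still run
        assert bd.entry("clinic_supervision") > 0
        assert bd.entry("movement_supervision") == Decimal("0.00")

    def test_doubling_patients_doubles_variable_only(self):
        one = event_costs([self._event(5)], self.params)
        two = event_costs([self._event(10)], self.params)
        fixed = event_costs([self._event(0)], self.params)
        for centre in ("clinic_administration", "movement_supervision"):
            var1 = one.centre_total(centre) - fixed.centre_total(centre)
            var2 = two.centre_total(centre) - fixed.centre_total(centre)
            assert abs(var2 - 2 * var1) <= Decimal("0.02")
        assert two.entry("clinic_supervision") == one.entry("clinic_supervision")

    def test_two_identical_events_cost_twice_one(self):
        one = event_costs([self._event(7)], self.params)
        two = event_costs([self._event(7), self._event(7)], self.params)
        for payer in PAYERS:
            assert abs(two.payer_total(payer) - 2 * one.payer_total(payer)) <= Decimal("0.02")

    def test_segregation_adds_walk_time(self):
        window = event_costs(
            [DosingEvent(facility="F", medication="methadone", patients_dosed=3)], self.params
        )
        seg = event_costs(
            [DosingEvent(facility="F", medication="methadone", patients_dosed=3, mode="segregation")],
            self.params,
        )
        walk = labour_cost(10, self.params.role("registered_nurse_y8"), self.params.loadings)
        assert aud(seg.grand_total() - window.grand_total()) == aud(3 * walk)


class TestMedicationSupply:
    def setup_method(self):
        self.params = make_params()

    def test_zero_doses_zero_cost(self):
        bd = medication_supply_cost({"methadone": 0}, self.params)
        assert bd.grand_total() == Decimal("0.00")

    def test_single_monthly_depot_dose_at_calibrated_price(self):
        bd = medication_supply_cost({"depot_monthly": 1}, self.params)
        assert bd.payer_total("Commonwealth") == Decimal("368.84")

    def test_commonwealth_only(self):
        bd = medication_supply_cost({"methadone": 100, "depot_weekly": 2}, self.params)
        assert bd.payer_total("JHFMHN") == Decimal("0.00")
        assert bd.payer_total("CSNSW") == Decimal("0.00")
        assert bd.payer_total("Commonwealth") == bd.grand_total()

    def test_dose_scaling_homogeneity(self):
        one = medication_supply_cost({"sl_bpn_nlx": 10}, self.params)
        five = medication_supply_cost({"sl_bpn_nlx": 50}, self.params)
        assert five.grand_total() == 5 * one.grand_total()

    def test_missing_price_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            medication_supply_cost({"aspirin": 1}, self.params)


class TestBruteForceOracle:
    """event_costs against an explicit enumeration of every activity instance.

    One facility, two methadone patients, a two-day month and one order:
    the oracle walks day by day and patient by patient, summing each
    activity's loaded labour cost and consumables independently of the
    kernel's grouped arithmetic.
    """

    def test_toy_month_matches_enumeration(self, toy_facility):
        params = make_params(
            minutes={
                "prep_cleanup": 15,
                "stock_check": 5,
                "dosing_per_patient": 2,
                "movement_supervision": 3,
                "clinic_supervision": 30,
                "inventory_ordering": 20,
                "inventory_receiving": 15,
                "pharmacy_dispensing": 30,
                "transport": 60,
            },
            days_per_month=2,
        )
        events = build_dosing_events([toy_facility], params)
        got = event_costs(events, params) + order_costs(1, params)

        def loaded(minutes, role_name):
            role = params.role(role_name)
            return (
                Decimal(minutes) / 60 * role.hourly_wage * Decimal("1.535")
            )

        expected = Decimal("0")
        for _day in range(2):  # one window event per day
            expected += loaded(15, "registered_nurse_y8")  # preparation/clean-up
            expected += loaded(5, "registered_nurse_y8")  # stock check
            expected += loaded(30, "correctional_officer_1c_y2")  # clinic supervision
            for _patient in range(2):
                expected += loaded(2, "registered_nurse_y8")  # dosing
                expected += loaded(3, "correctional_officer_1c_y2")  # movement
                expected += Decimal("0.30")  # consumables
        # the single pharmacy order
        expected += loaded(20, "registered_nurse_y8")
        expected += loaded(15, "registered_nurse_y8")
        expected += loaded(30, "pharmacy_assistant_g1y8")
        expected += loaded(60, "pharmacy_admin_g6")

        assert abs(got.grand_total() - aud(expected)) <= Decimal("0.05")


class TestBaseCase:
    def test_administration_and_order_counts(self, facilities, params):
        bc = base_case(facilities, params)
        assert bc["methadone"].administrations == 7409
        assert bc["sl_bpn_nlx"].administrations == 1240
        assert bc["depot"].administrations == 84
        assert (bc["depot"].orders, bc["methadone"].orders, bc["sl_bpn_nlx"].orders) == (21, 24, 24)
        assert (bc["depot"].patients, bc["methadone"].patients, bc["sl_bpn_nlx"].patients) == (
            50,
            239,
            40,
        )

    def test_service_cost_ordering(self, facilities, params):
        bc = base_case(facilities, params)
        nsw = {s: bc[s].per_patient.nsw_total() for s in bc}
        assert nsw["depot"] < nsw["methadone"] < nsw["sl_bpn_nlx"]

    def test_payer_decomposition_identity(self, facilities, params):
        for sc in base_case(facilities, params).values():
            for bd in (sc.breakdown, sc.per_patient):
                jh = (
                    bd.centre_total("pharmacy")
                    + bd.centre_total("inventory_management")
                    + bd.centre_total("clinic_administration")
                )
                cs = bd.centre_total("movement_supervision") + bd.centre_total("clinic_supervision")
                assert bd.payer_total("JHFMHN") == jh
                assert bd.payer_total("CSNSW") == cs
                assert bd.payer_total("Commonwealth") == bd.centre_total("medication_supply")
                assert bd.grand_total() == jh + cs + bd.payer_total("Commonwealth")

    def test_empty_cohort_is_explicit_error(self, params):
        from oatcost import Facility

        facs = [
            Facility(
                name="NoDepot",
                cohort_depot_monthly=0,
                cohort_depot_weekly=0,
                cohort_methadone=5,
                cohort_sl_bpn=5,
            )
        ]
        with pytest.raises(CohortUndefinedError):
            base_case(facs, params)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.decimals(min_value="0.5", max_value="4", places=2))
    def test_wage_homogeneity(self, facilities, params, k):
        """Scaling every wage by k scales NSW labour costs by k, Commonwealth
        untouched. Consumables are materials priced at market rates, so the
        check runs on a zero-consumable configuration where NSW cost is pure
        labour."""
        params = _without_consumables(params)
        scaled_params = params.model_copy(
            update={"roles": [r.model_copy(update={"hourly_wage": r.hourly_wage * k}) for r in params.roles]}
        )
        base = base_case(facilities, params)
        scaled = base_case(facilities, scaled_params)
        for stream in base:
            assert abs(
                scaled[stream].breakdown.nsw_total() - k * base[stream].breakdown.nsw_total()
            ) <= Decimal("0.25")
            assert scaled[stream].breakdown.payer_total("Commonwealth") == base[
                stream
            ].breakdown.payer_total("Commonwealth")

    def test_longer_activity_time_weakly_increases_cost(self, facilities, params):
        for centre in ("dosing_per_patient", "prep_cleanup", "transport"):
            bumped_acts = [
                a.model_copy(update={"minutes_base": a.minutes_base + 1, "minutes_max": a.minutes_max + 1})
                if a.cost_centre == centre
                else a
                for a in params.activities
            ]
            bumped = params.model_copy(update={"activities": bumped_acts})
            base = base_case(facilities, params)
            more = base_case(facilities, bumped)
            for stream in base:
                assert more[stream].breakdown.grand_total() >= base[stream].breakdown.grand_total()

    def test_larger_cohort_strictly_cheaper_per_patient(self, facilities, params):
        grown = [
            f.model_copy(update={"cohort_methadone": f.cohort_methadone * 2}) for f in facilities
        ]
        base = base_case(facilities, params)
        big = base_case(grown, params)
        assert big["methadone"].per_patient.nsw_total() < base["methadone"].per_patient.nsw_total()
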