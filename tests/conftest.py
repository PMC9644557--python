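from decimal import Decimal

import pytest

from oatcost import (
    ActivityTime,
    CostParameterSet,
    Facility,
    LoadingRates,
    MedicationProfile,
    Role,
    RolloutScenario,
    load_fixture_config,
    load_fixture_july2019,
)
from oatcost.params import ACTIVITY_CENTRES

_ROLE_OF = {
    "inventory_ordering": "registered_nurse_y8",
    "inventory_receiving": "registered_nurse_y8",
    "prep_cleanup": "registered_nurse_y8",
    "dosing_per_patient": "registered_nurse_y8",
    "stock_check": "registered_nurse_y8",
    "pharmacy_dispensing": "pharmacy_assistant_g1y8",
    "transport": "pharmacy_admin_g6",
    "movement_supervision": "correctional_officer_1c_y2",
    "clinic_supervision": "correctional_officer_1c_y2",
    "segregation_walk": "registered_nurse_y8",
}
_UNIT_OF = {
    "inventory_ordering": "per_order",
    "inventory_receiving": "per_order",
    "prep_cleanup": "per_event",
    "dosing_per_patient": "per_patient_dose",
    "stock_check": "per_event",
    "pharmacy_dispensing": "per_order",
    "transport": "per_order",
    "movement_supervision": "per_patient_dose",
    "clinic_supervision": "per_event",
    "segregation_walk": "per_patient_dose",
}


def make_params(
    minutes: dict[str, float] | None = None,
    wages: dict[str, str] | None = None,
    loadings: tuple[str, str] = ("0.26", "0.275"),
    consumables: dict[str, str] | None = None,
    days_per_month: int = 31,
) -> CostParameterSet:
    """A complete parameter set with controllable values for unit tests."""
    minutes = minutes or {}
    wages = wages or {}
    consumables = consumables or {}
    default_wage = {
        "registered_nurse_y8": "48.00",
        "correctional_officer_1c_y2": "40.00",
        "pharmacy_assistant_g1y8": "29.00",
        "chief_pharmacist": "70.00",
        "pharmacy_admin_g6": "36.00",
    }
    roles = [
        Role(name=n, hourly_wage=Decimal(wages.get(n, w))) for n, w in default_wage.items()
    ]
    activities = []
    for centre in ACTIVITY_CENTRES:
        base = float(minutes.get(centre, 10.0))
        activities.append(
            ActivityTime(
                cost_centre=centre,
                minutes_base=base,
                minutes_min=base / 2,
                minutes_max=base * 2,
                role=_ROLE_OF[centre],
                per_unit=_UNIT_OF[centre],
            )
        )
    meds = [
        MedicationProfile(
            name="depot_weekly",
            dosing_frequency="weekly",
            unit_price=Decimal("96.65"),
            consumables_per_dose=Decimal(consumables.get("depot", "1.50")),
            administration_mode="consultation_room",
        ),
        MedicationProfile(
            name="depot_monthly",
            dosing_frequency="monthly",
            unit_price=Decimal("368.84"),
            consumables_per_dose=Decimal(consumables.get("depot", "1.50")),
            administration_mode="consultation_room",
        ),
        MedicationProfile(
            name="methadone",
            dosing_frequency="daily",
            unit_price=Decimal("2.74"),
            consumables_per_dose=Decimal(consumables.get("methadone", "0.30")),
            administration_mode="dosing_window_group",
        ),
        MedicationProfile(
            name="sl_bpn_nlx",
            dosing_frequency="daily",
            unit_price=Decimal("16.94"),
            consumables_per_dose=Decimal(consumables.get("sl_bpn_nlx", "0.20")),
            administration_mode="dosing_window_group",
        ),
    ]
    return CostParameterSet(
        roles=roles,
        loadings=LoadingRates(oncost_rate=Decimal(loadings[0]), overhead_rate=Decimal(loadings[1])),
        activities=activities,
        medications=meds,
        days_per_month=days_per_month,
    )


@pytest.fixture(scope="session")
def fixture_config():
    return load_fixture_config()


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture_july2019()


@pytest.fixture(scope="session")
def facilities(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def params(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def scenario():
    return RolloutScenario()


@pytest.fixture()
def toy_facility():
    """One facility, two methadone patients, used with a 2-day month."""
    return Facility(
        name="Toy",
        cohort_depot_monthly=0,
        cohort_depot_weekly=0,
        cohort_methadone=2,
        cohort_sl_bpn=0,
        orders_per_month={"methadone": 1},
    )
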