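"""Bottom-up cost kernel: labour valuation, dosing-event costing, payer split.

Every cost in the model is either

* labour (activity minutes x loaded hourly wage), charged per order, per
  administration event or per patient dose,
* consumables, charged per dose, or
* medication, charged per dose at the listed unit price.

Costs are attributed to a report cost centre and a payer: clinical and
pharmacy labour to JHFMHN (the health network), custodial supervision to
CSNSW (the custodial agency) — the two together being the NSW government
service cost — and medication supply to the Commonwealth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping

import pandas as pd

from .money import CENT, as_decimal, aud
from .params import (
    ConfigurationError,
    CostParameterSet,
    Facility,
    LoadingRates,
    Role,
    STREAMS,
)

PAYERS: tuple[str, ...] = ("JHFMHN", "CSNSW", "Commonwealth")

#: Report rows of the base-case table.
REPORT_CENTRES: tuple[str, ...] = (
    "pharmacy",
    "inventory_management",
    "clinic_administration",
    "movement_supervision",
    "clinic_supervision",
    "medication_supply",
)

#: Activity cost centre -> (report centre, payer).
ACTIVITY_ATTRIBUTION: dict[str, tuple[str, str]] = {
    "pharmacy_dispensing": ("pharmacy", "JHFMHN"),
    "transport": ("pharmacy", "JHFMHN"),
    "inventory_ordering": ("inventory_management", "JHFMHN"),
    "inventory_receiving": ("inventory_management", "JHFMHN"),
    "stock_check": ("inventory_management", "JHFMHN"),
    "prep_cleanup": ("clinic_administration", "JHFMHN"),
    "dosing_per_patient": ("clinic_administration", "JHFMHN"),
    "segregation_walk": ("clinic_administration", "JHFMHN"),
    "movement_supervision": ("movement_supervision", "CSNSW"),
    "clinic_supervision": ("clinic_supervision", "CSNSW"),
}

#: Which activities are charged once per event / per order / per patient dose.
PER_EVENT_ACTIVITIES = ("prep_cleanup", "stock_check", "clinic_supervision")
PER_ORDER_ACTIVITIES = ("inventory_ordering", "inventory_receiving", "pharmacy_dispensing", "transport")
PER_DOSE_ACTIVITIES = ("dosing_per_patient", "movement_supervision")


class CohortUndefinedError(ValueError):
    """Per-patient cost requested for an empty cohort."""


def labour_cost(minutes, role: Role, loadings: LoadingRates, compound: bool = False) -> Decimal:
    """Loaded cost of ``minutes`` of one role's time: (minutes/60) x wage
    x loading factor.

    On-costs and overheads are both fractions of the base labour cost and
    are applied additively by default: base x (1 + oncost + overhead).
    ``compound=True`` applies overheads on top of on-costed labour instead.
    Returned unquantised; cent rounding happens at the reporting edge.
    """
    m = as_decimal(minutes)
    if m < 0:
        raise ValueError(f"minutes must be >= 0, got {minutes}")
    if compound:
        factor = (1 + loadings.oncost_rate) * (1 + loadings.overhead_rate)
    else:
        factor = 1 + loadings.oncost_rate + loadings.overhead_rate
    return m / Decimal(60) * role.hourly_wage * factor


def daily_administration_count(cohort: int, days: int) -> int:
    """Administrations of a daily medication: one supervised dose per patient-day."""
    if cohort < 0 or days < 0:
        raise ValueError("cohort and days must be >= 0")
    return cohort * days


@dataclass(frozen=True)
class DosingEvent:
    """A recurring administration session at one facility for one stream.

    ``events_per_month`` and ``patients_dosed`` may be fractional: the
    rollout simulator scales cohorts continuously and carries fractional
    titration doses. Fixed per-event components (preparation/clean-up,
    stock check, clinic supervision) are charged per event regardless of
    ``patients_dosed``; dosing and movement-supervision time, consumables
    and — for segregation — the 10-minute nurse walk are charged per
    patient dose.
    """

    facility: str
    medication: str  # stream: depot | methadone | sl_bpn_nlx
    patients_dosed: float
    mode: str = "dosing_window_group"  # or consultation_room | segregation
    events_per_month: float = 1.0

    def __post_init__(self) -> None:
        if self.patients_dosed < 0 or self.events_per_month < 0:
            raise ValueError("patients_dosed and events_per_month must be >= 0")
        if self.medication not in STREAMS:
            raise ValueError(f"unknown medication stream: {self.medication}")
        if self.mode not in ("dosing_window_group", "consultation_room", "segregation"):
            raise ValueError(f"unknown mode: {self.mode}")


class CostBreakdown:
    """Money keyed by (report cost centre, payer), with accounting identities.

    JHFMHN total = pharmacy + inventory management + clinic administration;
    CSNSW total = movement + clinic supervision; NSW = JHFMHN + CSNSW;
    Commonwealth total = medication supply. Totals are always sums of the
    cent-quantised entries, so the payer decomposition holds to the cent.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Decimal] | None = None):
        self._entries: dict[tuple[str, str], Decimal] = {}
        if entries:
            for key, value in entries.items():
                self.add(key[0], value, payer=key[1])

    def add(self, centre: str, amount, payer: str | None = None) -> None:
        if payer is None:
            payer = _payer_of(centre)
        if centre not in REPORT_CENTRES:
            raise ConfigurationError(f"unknown report cost centre: {centre}")
        if payer not in PAYERS:
            raise ConfigurationError(f"unknown payer: {payer}")
        value = as_decimal(amount)
        if value < 0:
            raise ValueError("cost entries must be non-negative")
        key = (centre, payer)
        self._entries[key] = self._entries.get(key, Decimal("0")) + value

    # -- access ----------------------------------------------------------
    def entry(self, centre: str, payer: str | None = None) -> Decimal:
        if payer is None:
            payer = _payer_of(centre)
        return aud(self._entries.get((centre, payer), Decimal("0")))

    def centre_total(self, centre: str) -> Decimal:
        # sum of cent-quantised entries, so row totals match printed entries
        return sum((aud(v) for (c, _), v in self._entries.items() if c == centre), Decimal("0.00"))

    def payer_total(self, payer: str) -> Decimal:
        return sum((aud(v) for (_, p), v in self._entries.items() if p == payer), Decimal("0.00"))

    def nsw_total(self) -> Decimal:
        return self.payer_total("JHFMHN") + self.payer_total("CSNSW")

    def grand_total(self) -> Decimal:
        return sum((self.payer_total(p) for p in PAYERS), Decimal("0.00"))

    # -- algebra ---------------------------------------------------------
    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        out = CostBreakdown(self._entries)
        for (centre, payer), value in other._entries.items():
            out.add(centre, value, payer=payer)
        return out

    def scale(self, k) -> "CostBreakdown":
        kd = as_decimal(k)
        out = CostBreakdown()
        for (centre, payer), value in self._entries.items():
            out.add(centre, value * kd, payer=payer)
        return out

    def per_patient(self, cohort_size) -> "CostBreakdown":
        n = as_decimal(cohort_size)
        if n <= 0:
            raise CohortUndefinedError(
                f"per-patient cost undefined for cohort size {cohort_size}"
            )
        return self.scale(Decimal(1) / n)

    def quantised(self) -> dict[tuple[str, str], Decimal]:
        return {k: aud(v) for k, v in self._entries.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        rows = ", ".join(f"{c}/{p}: {aud(v)}" for (c, p), v in sorted(self._entries.items()))
        return f"CostBreakdown({rows})"


def _payer_of(centre: str) -> str:
    if centre in ("pharmacy", "inventory_management", "clinic_administration"):
        return "JHFMHN"
    if centre in ("movement_supervision", "clinic_supervision"):
        return "CSNSW"
    if centre == "medication_supply":
        return "Commonwealth"
    raise ConfigurationError(f"unknown report cost centre: {centre}")


def _activity_cost(params: CostParameterSet, centre: str, minutes_override=None) -> Decimal:
    act = params.activity(centre)
    minutes = act.minutes_base if minutes_override is None else minutes_override
    return labour_cost(minutes, params.role(act.role), params.loadings, params.compound_loadings)


def event_costs(events: Iterable[DosingEvent], params: CostParameterSet) -> CostBreakdown:
    """Cost a collection of dosing events.

    Per event: preparation/clean-up, stock check (JHFMHN) and clinic
    supervision (CSNSW). Per patient dose: dosing/consultation time
    (JHFMHN), movement supervision (CSNSW) and consumables (JHFMHN).
    Segregation events additionally charge the nurse walk per patient
    location. Depot streams price consumables at the depot preparation
    rate; ordering costs are charged separately (see :func:`order_costs`).
    """
    out = CostBreakdown()
    for ev in events:
        n_events = as_decimal(ev.events_per_month)
        n_dosed = as_decimal(ev.patients_dosed)
        for centre in PER_EVENT_ACTIVITIES:
            report, payer = ACTIVITY_ATTRIBUTION[centre]
            out.add(report, _activity_cost(params, centre) * n_events, payer=payer)
        for centre in PER_DOSE_ACTIVITIES:
            report, payer = ACTIVITY_ATTRIBUTION[centre]
            out.add(report, _activity_cost(params, centre) * n_events * n_dosed, payer=payer)
        if ev.mode == "segregation":
            report, payer = ACTIVITY_ATTRIBUTION["segregation_walk"]
            out.add(
                report,
                _activity_cost(params, "segregation_walk") * n_events * n_dosed,
                payer=payer,
            )
        consumable = _consumables_per_dose(params, ev.medication)
        out.add("clinic_administration", consumable * n_events * n_dosed, payer="JHFMHN")
    return out


def order_costs(n_orders, params: CostParameterSet) -> CostBreakdown:
    """Cost of pharmacy orders: creation, receipt (inventory management,
    JHFMHN) and dispensing plus transport (pharmacy, JHFMHN), per order."""
    n = as_decimal(n_orders)
    if n < 0:
        raise ValueError("n_orders must be >= 0")
    out = CostBreakdown()
    for centre in PER_ORDER_ACTIVITIES:
        report, payer = ACTIVITY_ATTRIBUTION[centre]
        out.add(report, _activity_cost(params, centre) * n, payer=payer)
    return out


def _consumables_per_dose(params: CostParameterSet, stream: str) -> Decimal:
    name = {"depot": "depot_monthly", "methadone": "methadone", "sl_bpn_nlx": "sl_bpn_nlx"}[stream]
    return params.medication(name).consumables_per_dose


def medication_supply_cost(doses: Mapping[str, float], params: CostParameterSet) -> CostBreakdown:
    """Commonwealth medication bill: sum of dose counts x listed unit prices.

    Keys are medication profile names (``depot_weekly``, ``depot_monthly``,
    ``methadone``, ``sl_bpn_nlx``); counts may be fractional (titration).
    """
    out = CostBreakdown()
    total = Decimal("0")
    for name, count in doses.items():
        med = params.medication(name)  # raises ConfigurationError if missing
        total += as_decimal(count) * med.unit_price
    out.add("medication_supply", total, payer="Commonwealth")
    return out


# ---------------------------------------------------------------------------
# Base case assembly
# ---------------------------------------------------------------------------

def build_dosing_events(facilities: Iterable[Facility], params: CostParameterSet) -> list[DosingEvent]:
    """The July-2019 style event schedule implied by a facility census.

    Daily streams run ``dosing_events_per_day`` group window events per
    facility per day; segregation patients (taken from the methadone
    cohort) are dosed in a separate daily segregation round. Each recorded
    depot administration is an individual consultation-room event.
    """
    events: list[DosingEvent] = []
    days = params.days_per_month
    for fac in facilities:
        seg = fac.segregation_patients
        if seg > fac.cohort_methadone:
            raise ConfigurationError(
                f"{fac.name}: segregation_patients ({seg}) exceeds methadone cohort"
            )
        if fac.cohort_methadone > 0:
            if fac.cohort_methadone - seg > 0:
                events.append(
                    DosingEvent(
                        facility=fac.name,
                        medication="methadone",
                        patients_dosed=fac.cohort_methadone - seg,
                        mode="dosing_window_group",
                        events_per_month=days * fac.dosing_events_per_day,
                    )
                )
            if seg > 0:
                events.append(
                    DosingEvent(
                        facility=fac.name,
                        medication="methadone",
                        patients_dosed=seg,
                        mode="segregation",
                        events_per_month=days,
                    )
                )
        if fac.cohort_sl_bpn > 0:
            events.append(
                DosingEvent(
                    facility=fac.name,
                    medication="sl_bpn_nlx",
                    patients_dosed=fac.cohort_sl_bpn,
                    mode="dosing_window_group",
                    events_per_month=days * fac.dosing_events_per_day,
                )
            )
        if fac.depot_administrations > 0:
            events.append(
                DosingEvent(
                    facility=fac.name,
                    medication="depot",
                    patients_dosed=1,
                    mode="consultation_room",
                    events_per_month=fac.depot_administrations,
                )
            )
    return events


@dataclass
class StreamCosts:
    """One medication stream's monthly totals and per-patient decomposition."""

    medication: str
    patients: int
    administrations: float
    orders: int
    breakdown: CostBreakdown
    per_patient: CostBreakdown = field(init=False)

    def __post_init__(self) -> None:
        if self.patients <= 0:
            raise CohortUndefinedError(
                f"{self.medication}: per-patient cost undefined for cohort 0"
            )
        self.per_patient = self.breakdown.per_patient(self.patients)


def base_case(facilities: list[Facility], params: CostParameterSet) -> dict[str, StreamCosts]:
    """Monthly per-patient cost table for an observed facility census.

    Returns one :class:`StreamCosts` per stream with the base-case row
    structure: JHFMHN pharmacy / inventory management / clinic
    administration, CSNSW movement / clinic supervision, Commonwealth
    medication supply, plus patient, administration and order counts.
    """
    events = build_dosing_events(facilities, params)
    days = params.days_per_month
    out: dict[str, StreamCosts] = {}
    for stream in STREAMS:
        cohort = sum(f.cohort(stream) for f in facilities)
        if cohort == 0:
            raise CohortUndefinedError(f"{stream}: per-patient cost undefined for cohort 0")
        orders = sum(f.orders_per_month.get(stream, 0) for f in facilities)
        stream_events = [e for e in events if e.medication == stream]
        breakdown = event_costs(stream_events, params) + order_costs(orders, params)
        if stream == "depot":
            admins = sum(f.depot_administrations for f in facilities)
            monthly_patients = sum(f.cohort_depot_monthly for f in facilities)
            # Recorded administrations exceed the cohort because weekly-phase
            # patients dose repeatedly; impute one monthly dose per
            # monthly-preparation patient, the remainder as weekly doses.
            monthly_doses = min(monthly_patients, admins)
            weekly_doses = admins - monthly_doses
            doses = {"depot_monthly": monthly_doses, "depot_weekly": weekly_doses}
        elif stream == "methadone":
            admins = daily_administration_count(cohort, days)
            doses = {"methadone": admins}
        else:
            admins = daily_administration_count(cohort, days)
            doses = {"sl_bpn_nlx": admins}
        breakdown = breakdown + medication_supply_cost(doses, params)
        out[stream] = StreamCosts(
            medication=stream,
            patients=cohort,
            administrations=admins,
            orders=orders,
            breakdown=breakdown,
        )
    return out


def base_case_frame(results: Mapping[str, StreamCosts]) -> pd.DataFrame:
    """Long-form table: one row per (medication, cost centre, payer)."""
    rows = []
    for stream, sc in results.items():
        for centre in REPORT_CENTRES:
            payer = _payer_of(centre)
            rows.append(
                {
                    "medication": stream,
                    "cost_centre": centre,
                    "payer": payer,
                    "total_cost": float(sc.breakdown.entry(centre, payer)),
                    "per_patient_cost": float(sc.per_patient.entry(centre, payer)),
                    "patients": sc.patients,
                    "administrations": sc.administrations,
                    "orders": sc.orders,
                }
            )
    return pd.DataFrame(rows)
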