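"""Deterministic 12-month depot-buprenorphine implementation simulator.

The scenario moves a fixed aggregate population (default 329 patients:
282 methadone + 47 sublingual buprenorphine-naloxone) onto depot
buprenorphine in equal monthly increments of 5% of the population,
capping at 60% by month 12. Methadone-origin transfers spend their first
month in a weekly (initiation) phase — two weekly depot doses plus one
monthly dose — while SL BPN-NLX transfers move straight to monthly
dosing; 6.5% of weekly-phase patients receive one extra titration dose,
carried as a fraction and rounded half-up only in the final
administration total. All months have 31 days.

Counts are computed with exact rational arithmetic so that half-up
rounding of ties (e.g. a 164.5-patient depot cohort) is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Iterable

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costing import (
    CostBreakdown,
    DosingEvent,
    daily_administration_count,
    event_costs,
    medication_supply_cost,
    order_costs,
)
from .money import as_decimal, aud, round_half_up, whole_dollars
from .params import ConfigurationError, CostParameterSet, Facility


class ScenarioError(ValueError):
    """The scenario constants produce an inconsistent cohort trajectory."""


class RolloutScenario(BaseModel):
    """Governing constants of the implementation simulation."""

    model_config = ConfigDict(frozen=True)

    months: int = Field(default=12, ge=1)
    total_population: int = Field(default=329, gt=0)
    uptake_increment: float = Field(default=0.05, ge=0, le=1)
    max_share: float = Field(default=0.60, ge=0, le=1)
    sbl_start: int = Field(default=47, ge=0)
    sbl_end: int = Field(default=5, ge=0)
    weekly_doses_per_methadone_transfer: int = Field(default=2, ge=0)
    titration_rate: float = Field(default=0.065, ge=0, le=1)
    days_per_month: int = Field(default=31, ge=1)

    @model_validator(mode="after")
    def _consistent(self) -> "RolloutScenario":
        if self.sbl_end > self.sbl_start:
            raise ValueError("sbl_end must not exceed sbl_start")
        if self.sbl_start > self.total_population:
            raise ValueError("sbl_start exceeds total_population")
        return self

    # exact rational views of the float config fields
    @property
    def uptake(self) -> Fraction:
        return Fraction(str(self.uptake_increment))

    @property
    def cap(self) -> Fraction:
        return Fraction(str(self.max_share))

    @property
    def titration(self) -> Fraction:
        return Fraction(str(self.titration_rate))

    def depot_share(self, month: int) -> Fraction:
        return min(month * self.uptake, self.cap)

    def progress(self, month: int) -> Fraction:
        """Rollout progress in [0, 1]: depot share relative to its cap.

        The SL BPN-NLX wind-down is indexed to this, so a zero-uptake
        scenario leaves every cohort at its month-0 value.
        """
        if self.cap == 0:
            return Fraction(0)
        return self.depot_share(month) / self.cap


@dataclass(frozen=True)
class CohortState:
    """Per-month cohort counts and this month's transfers."""

    month: int
    depot: int
    methadone: int
    sl_bpn: int
    weekly_phase: int
    transfers_from_methadone: int
    transfers_from_sbl: int

    @property
    def total(self) -> int:
        return self.depot + self.methadone + self.sl_bpn


@dataclass(frozen=True)
class AdministrationCounts:
    """Dose counts for one month; depot total rounded half-up once."""

    depot: int
    methadone: int
    sl_bpn: int
    depot_monthly_doses: int
    depot_weekly_doses: int
    titration_doses: Fraction

    @property
    def depot_exact(self) -> Fraction:
        return (
            Fraction(self.depot_monthly_doses)
            + Fraction(self.depot_weekly_doses)
            + self.titration_doses
        )


def cohort_trajectory(scenario: RolloutScenario) -> list[CohortState]:
    """Months 0..months of the deterministic cohort transition.

    depot(m) = round_half_up(population x min(m x uptake, cap));
    SL BPN-NLX interpolates linearly from start to end with rollout
    progress; methadone is the remainder. Transfers are month-over-month
    decrements; the weekly phase is exactly this month's methadone-origin
    transfers.
    """
    states: list[CohortState] = []
    prev_depot = prev_meth = prev_sbl = None
    for m in range(scenario.months + 1):
        depot = round_half_up(scenario.total_population * scenario.depot_share(m))
        sbl = round_half_up(
            Fraction(scenario.sbl_start)
            + (Fraction(scenario.sbl_end) - Fraction(scenario.sbl_start)) * scenario.progress(m)
        )
        meth = scenario.total_population - depot - sbl
        if meth < 0:
            raise ScenarioError(f"month {m}: methadone cohort would be negative ({meth})")
        if m == 0:
            t_meth = t_sbl = 0
        else:
            t_sbl = prev_sbl - sbl
            t_meth = prev_meth - meth
            if t_meth < 0 or t_sbl < 0:
                raise ScenarioError(f"month {m}: negative transfer (methadone {t_meth}, SL {t_sbl})")
        states.append(
            CohortState(
                month=m,
                depot=depot,
                methadone=meth,
                sl_bpn=sbl,
                weekly_phase=t_meth,
                transfers_from_methadone=t_meth,
                transfers_from_sbl=t_sbl,
            )
        )
        prev_depot, prev_meth, prev_sbl = depot, meth, sbl
    return states


def dose_schedule(state: CohortState, scenario: RolloutScenario) -> AdministrationCounts:
    """Administrations implied by one month's cohort state.

    Every current depot patient (carry-over plus new transfer) receives
    one monthly dose, so monthly doses equal the depot cohort;
    methadone-origin transfers add the configured weekly doses; 6.5% of
    weekly-phase patients add one titration dose, kept fractional. The
    depot total is rounded half-up once, at the end.
    """
    monthly = state.depot
    weekly = scenario.weekly_doses_per_methadone_transfer * state.transfers_from_methadone
    titration = scenario.titration * state.weekly_phase
    return AdministrationCounts(
        depot=round_half_up(Fraction(monthly) + Fraction(weekly) + titration),
        methadone=daily_administration_count(state.methadone, scenario.days_per_month),
        sl_bpn=daily_administration_count(state.sl_bpn, scenario.days_per_month),
        depot_monthly_doses=monthly,
        depot_weekly_doses=weekly,
        titration_doses=titration,
    )


def weekly_share(state: CohortState) -> tuple[int, bool]:
    """Weekly-phase share of the depot cohort as a whole percent.

    Returns ``(percent, defined)``; an empty depot cohort reports 0% with
    ``defined=False``.
    """
    if state.depot == 0:
        return 0, False
    return round_half_up(Fraction(100 * state.weekly_phase, state.depot)), True


# ---------------------------------------------------------------------------
# Costed simulation
# ---------------------------------------------------------------------------

@dataclass
class MonthRecord:
    """One simulated month: counts plus exact per-patient costs by payer."""

    state: CohortState
    admin: AdministrationCounts
    weekly_pct: int
    weekly_pct_defined: bool
    service_per_patient: dict[str, dict[str, Decimal]]  # stream -> {JHFMHN, CSNSW, total}
    medication_per_patient: dict[str, Decimal]  # stream -> Commonwealth per patient
    service_total: dict[str, CostBreakdown]


@dataclass
class SimulationTable:
    """Month-by-month rollout results (month 0 baseline included)."""

    scenario: RolloutScenario
    rows: list[MonthRecord]

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Tabular form; money as whole dollars (half-up) when ``rounded``."""

        def dollars(x: Decimal) -> float | int:
            return whole_dollars(x) if rounded else float(x)

        records = []
        for r in self.rows:
            s, a = r.state, r.admin
            records.append(
                {
                    "rollout_pct": round_half_up(100 * self.scenario.depot_share(s.month)),
                    "month": s.month,
                    "depot_patients": s.depot,
                    "depot_weekly_patients": s.weekly_phase,
                    "weekly_pct": r.weekly_pct,
                    "depot_admins": a.depot,
                    "depot_jh": dollars(r.service_per_patient["depot"]["JHFMHN"]),
                    "depot_cs": dollars(r.service_per_patient["depot"]["CSNSW"]),
                    "depot_total": dollars(r.service_per_patient["depot"]["total"]),
                    "methadone_patients": s.methadone,
                    "methadone_admins": a.methadone,
                    "methadone_jh": dollars(r.service_per_patient["methadone"]["JHFMHN"]),
                    "methadone_cs": dollars(r.service_per_patient["methadone"]["CSNSW"]),
                    "methadone_total": dollars(r.service_per_patient["methadone"]["total"]),
                    "sbl_patients": s.sl_bpn,
                    "sbl_admins": a.sl_bpn,
                    "sbl_jh": dollars(r.service_per_patient["sl_bpn_nlx"]["JHFMHN"]),
                    "sbl_cs": dollars(r.service_per_patient["sl_bpn_nlx"]["CSNSW"]),
                    "sbl_total": dollars(r.service_per_patient["sl_bpn_nlx"]["total"]),
                    "oat_cost_depot": dollars(r.medication_per_patient["depot"]),
                    "oat_cost_methadone": dollars(r.medication_per_patient["methadone"]),
                    "oat_cost_sbl": dollars(r.medication_per_patient["sl_bpn_nlx"]),
                    "total_patients": s.total,
                }
            )
        return pd.DataFrame(records)


def _scaled_events(
    facilities: list[Facility],
    params: CostParameterSet,
    state: CohortState,
    admin: AdministrationCounts,
    baseline_meth: int,
    baseline_sbl: int,
) -> list[DosingEvent]:
    """Facility event schedule for one simulated month.

    Per-event fixed costs are held constant — every facility keeps running
    its daily window events for a stream while the stream's aggregate
    cohort is positive — and cohorts are scaled continuously in proportion
    to baseline facility shares. Each (possibly fractional) depot
    administration is an individual consultation-room event.
    """
    events: list[DosingEvent] = []
    days = params.days_per_month
    for fac in facilities:
        if state.methadone > 0 and fac.cohort_methadone > 0:
            scaled = Fraction(state.methadone * fac.cohort_methadone, baseline_meth)
            seg = min(Fraction(fac.segregation_patients), scaled)
            if scaled - seg > 0:
                events.append(
                    DosingEvent(
                        facility=fac.name,
                        medication="methadone",
                        patients_dosed=float(scaled - seg),
                        mode="dosing_window_group",
                        events_per_month=days * fac.dosing_events_per_day,
                    )
                )
            if seg > 0:
                events.append(
                    DosingEvent(
                        facility=fac.name,
                        medication="methadone",
                        patients_dosed=float(seg),
                        mode="segregation",
                        events_per_month=days,
                    )
                )
        if state.sl_bpn > 0 and fac.cohort_sl_bpn > 0:
            scaled = Fraction(state.sl_bpn * fac.cohort_sl_bpn, baseline_sbl)
            events.append(
                DosingEvent(
                    facility=fac.name,
                    medication="sl_bpn_nlx",
                    patients_dosed=float(scaled),
                    mode="dosing_window_group",
                    events_per_month=days * fac.dosing_events_per_day,
                )
            )
    if admin.depot_exact > 0:
        events.append(
            DosingEvent(
                facility="(aggregate)",
                medication="depot",
                patients_dosed=1.0,
                mode="consultation_room",
                events_per_month=float(admin.depot_exact),
            )
        )
    return events


def simulate(
    scenario: RolloutScenario,
    facilities: list[Facility],
    params: CostParameterSet,
) -> SimulationTable:
    """Join the cohort trajectory and dose schedule with the cost kernel.

    Order volumes stay at their baseline monthly totals for streams with
    patients (fixed costs); depot incurs orders only once it has patients.
    Per-patient service costs divide the stream's NSW cost over its
    (integer) cohort; the medication column prices monthly, weekly and
    titration doses at the configured unit prices.
    """
    baseline_meth = sum(f.cohort_methadone for f in facilities)
    baseline_sbl = sum(f.cohort_sl_bpn for f in facilities)
    if baseline_meth == 0 or baseline_sbl == 0:
        raise ConfigurationError("facility census must include methadone and SL BPN-NLX cohorts")
    orders = {
        stream: sum(f.orders_per_month.get(stream, 0) for f in facilities)
        for stream in ("depot", "methadone", "sl_bpn_nlx")
    }
    scenario_days = scenario.days_per_month
    if scenario_days != params.days_per_month:
        params = params.model_copy(update={"days_per_month": scenario_days})

    rows: list[MonthRecord] = []
    for state in cohort_trajectory(scenario):
        admin = dose_schedule(state, scenario)
        events = _scaled_events(facilities, params, state, admin, baseline_meth, baseline_sbl)
        service: dict[str, CostBreakdown] = {}
        for stream in ("depot", "methadone", "sl_bpn_nlx"):
            bd = event_costs([e for e in events if e.medication == stream], params)
            cohort = {"depot": state.depot, "methadone": state.methadone, "sl_bpn_nlx": state.sl_bpn}[stream]
            if cohort > 0:
                bd = bd + order_costs(orders[stream], params)
            service[stream] = bd

        meds: dict[str, Decimal] = {}
        per_patient: dict[str, dict[str, Decimal]] = {}
        for stream, cohort in (
            ("depot", state.depot),
            ("methadone", state.methadone),
            ("sl_bpn_nlx", state.sl_bpn),
        ):
            if stream == "depot":
                supply = medication_supply_cost(
                    {
                        "depot_monthly": admin.depot_monthly_doses,
                        "depot_weekly": Fraction(admin.depot_weekly_doses) + admin.titration_doses,
                    },
                    params,
                )
            else:
                name = "methadone" if stream == "methadone" else "sl_bpn_nlx"
                supply = medication_supply_cost(
                    {name: daily_administration_count(cohort, scenario_days)}, params
                )
            if cohort > 0:
                jh = aud(service[stream].payer_total("JHFMHN") / as_decimal(cohort))
                cs = aud(service[stream].payer_total("CSNSW") / as_decimal(cohort))
                med = aud(supply.payer_total("Commonwealth") / as_decimal(cohort))
            else:
                jh = cs = med = Decimal("0.00")
            per_patient[stream] = {"JHFMHN": jh, "CSNSW": cs, "total": aud(jh + cs)}
            meds[stream] = med

        pct, defined = weekly_share(state)
        rows.append(
            MonthRecord(
                state=state,
                admin=admin,
                weekly_pct=pct,
                weekly_pct_defined=defined,
                service_per_patient=per_patient,
                medication_per_patient=meds,
                service_total=service,
            )
        )
    return SimulationTable(scenario=scenario, rows=rows)


def dose_counts_by_month(scenario: RolloutScenario) -> dict[int, tuple[Fraction, Fraction, int]]:
    """(monthly doses, weekly+titration doses, depot patients) per month.

    The dose-count input the depot price calibration consumes.
    """
    out: dict[int, tuple[Fraction, Fraction, int]] = {}
    for state in cohort_trajectory(scenario):
        a = dose_schedule(state, scenario)
        out[state.month] = (
            Fraction(a.depot_monthly_doses),
            Fraction(a.depot_weekly_doses) + a.titration_doses,
            state.depot,
        )
    return out
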