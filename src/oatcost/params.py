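"""Domain types, configuration schema, fixture loading and parameter generation.

The study's unit-cost workbook (per-role award wages, per-cost-centre
activity times with min/base/max ranges, loading rates, consumable and
medication prices) is not publicly deposited, so this module plays two
roles: it defines the schema every other module consumes, and it ships

* a hand-constructed synthetic default parameter set whose dollar values
  are realistic for 2021-22 NSW but are NOT the study's, and
* a seeded generator that draws parameter sets within stated ranges for
  robustness testing.

Facility census data (cohorts and recorded July-2019 administrations)
ARE published and are packaged verbatim in ``data/july2019.yaml``.
"""

from __future__ import annotations

import importlib.resources
from decimal import Decimal
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

RoleName = Literal[
    "registered_nurse_y8",
    "correctional_officer_1c_y2",
    "pharmacy_assistant_g1y8",
    "chief_pharmacist",
    "pharmacy_admin_g6",
]

ActivityCentre = Literal[
    "inventory_ordering",
    "inventory_receiving",
    "prep_cleanup",
    "dosing_per_patient",
    "stock_check",
    "pharmacy_dispensing",
    "transport",
    "movement_supervision",
    "clinic_supervision",
    "segregation_walk",
]

#: Every cost centre a complete parameter set must price exactly once.
ACTIVITY_CENTRES: tuple[str, ...] = (
    "inventory_ordering",
    "inventory_receiving",
    "prep_cleanup",
    "dosing_per_patient",
    "stock_check",
    "pharmacy_dispensing",
    "transport",
    "movement_supervision",
    "clinic_supervision",
    "segregation_walk",
)

PerUnit = Literal["per_order", "per_event", "per_patient_dose", "per_month"]

MedicationName = Literal["depot_weekly", "depot_monthly", "methadone", "sl_bpn_nlx"]

#: Treatment streams as administered (the two depot preparations share a stream).
STREAMS: tuple[str, ...] = ("depot", "methadone", "sl_bpn_nlx")


class ConfigurationError(ValueError):
    """A parameter set or config file violates the schema or an invariant."""


class Role(BaseModel):
    """A costed staff classification with its loaded hourly award wage."""

    model_config = ConfigDict(frozen=True)

    name: RoleName
    hourly_wage: Decimal = Field(gt=0, description="AUD per hour, 2021-22")


class LoadingRates(BaseModel):
    """On-costs and overheads, each expressed as a fraction of base labour cost."""

    model_config = ConfigDict(frozen=True)

    oncost_rate: Decimal = Field(default=Decimal("0.26"), ge=0, le=1)
    overhead_rate: Decimal = Field(default=Decimal("0.275"), ge=0, le=1)


class ActivityTime(BaseModel):
    """An observed activity at one cost centre: minutes, staff role, charge unit.

    ``minutes_min``/``minutes_max`` carry the across-site observation range
    used by the sensitivity analysis; ``minutes_base`` is the central value
    costing runs with.
    """

    model_config = ConfigDict(frozen=True)

    cost_centre: ActivityCentre
    minutes_base: float = Field(ge=0)
    minutes_min: float = Field(ge=0)
    minutes_max: float = Field(ge=0)
    role: RoleName
    per_unit: PerUnit

    @model_validator(mode="after")
    def _ordered(self) -> "ActivityTime":
        if not (self.minutes_min <= self.minutes_base <= self.minutes_max):
            raise ValueError(
                f"{self.cost_centre}: minutes must satisfy min <= base <= max "
                f"({self.minutes_min}/{self.minutes_base}/{self.minutes_max})"
            )
        return self


class MedicationProfile(BaseModel):
    """A dosed OAT preparation: unit price, consumables and administration mode."""

    model_config = ConfigDict(frozen=True)

    name: MedicationName
    dosing_frequency: Literal["daily", "weekly", "monthly"]
    unit_price: Decimal = Field(ge=0, description="AUD per dose unit")
    consumables_per_dose: Decimal = Field(default=Decimal("0"), ge=0)
    administration_mode: Literal["dosing_window_group", "consultation_room"]

    @model_validator(mode="after")
    def _mode_matches(self) -> "MedicationProfile":
        if self.name in ("methadone", "sl_bpn_nlx"):
            if self.dosing_frequency != "daily" or self.administration_mode != "dosing_window_group":
                raise ValueError(f"{self.name} must be daily dosing-window administration")
        else:
            if self.administration_mode != "consultation_room":
                raise ValueError(f"{self.name} must be consultation-room administration")
        return self


class Facility(BaseModel):
    """One correctional centre: cohorts by stream and recorded activity volumes."""

    model_config = ConfigDict(frozen=True)

    name: str
    security: str = ""
    cohort_depot_monthly: int = Field(ge=0)
    cohort_depot_weekly: int = Field(ge=0)
    cohort_methadone: int = Field(ge=0)
    cohort_sl_bpn: int = Field(ge=0)
    segregation_patients: int = Field(default=0, ge=0)
    dosing_events_per_day: int = Field(default=1, ge=1)
    orders_per_month: dict[str, int] = Field(default_factory=dict)
    depot_administrations: int = Field(default=0, ge=0)

    @field_validator("orders_per_month")
    @classmethod
    def _streams_known(cls, v: dict[str, int]) -> dict[str, int]:
        for k, n in v.items():
            if k not in STREAMS:
                raise ValueError(f"unknown stream in orders_per_month: {k!r}")
            if n < 0:
                raise ValueError(f"orders_per_month[{k}] must be >= 0")
        return v

    @property
    def cohort_depot(self) -> int:
        return self.cohort_depot_monthly + self.cohort_depot_weekly

    def cohort(self, stream: str) -> int:
        return {
            "depot": self.cohort_depot,
            "methadone": self.cohort_methadone,
            "sl_bpn_nlx": self.cohort_sl_bpn,
        }[stream]


class CostParameterSet(BaseModel):
    """Everything needed to price a month of OAT delivery.

    Completeness invariant: every activity cost centre appears exactly once,
    every activity's role is defined, and all four medication profiles are
    present.
    """

    roles: list[Role]
    loadings: LoadingRates = Field(default_factory=LoadingRates)
    activities: list[ActivityTime]
    medications: list[MedicationProfile]
    days_per_month: int = Field(default=31, ge=1)
    currency_year: str = "2021-22"
    compound_loadings: bool = False

    @model_validator(mode="after")
    def _complete(self) -> "CostParameterSet":
        centres = [a.cost_centre for a in self.activities]
        if sorted(centres) != sorted(ACTIVITY_CENTRES):
            missing = set(ACTIVITY_CENTRES) - set(centres)
            dupes = {c for c in centres if centres.count(c) > 1}
            raise ValueError(
                f"activity set incomplete: missing={sorted(missing)} duplicated={sorted(dupes)}"
            )
        role_names = {r.name for r in self.roles}
        if len(role_names) != len(self.roles):
            raise ValueError("duplicate role definitions")
        for a in self.activities:
            if a.role not in role_names:
                raise ValueError(f"activity {a.cost_centre} references undefined role {a.role}")
        med_names = sorted(m.name for m in self.medications)
        if med_names != sorted(["depot_monthly", "depot_weekly", "methadone", "sl_bpn_nlx"]):
            raise ValueError(f"medication profiles incomplete or duplicated: {med_names}")
        return self

    # -- lookups ---------------------------------------------------------
    def role(self, name: str) -> Role:
        for r in self.roles:
            if r.name == name:
                return r
        raise ConfigurationError(f"undefined role: {name}")

    def activity(self, cost_centre: str) -> ActivityTime:
        for a in self.activities:
            if a.cost_centre == cost_centre:
                return a
        raise ConfigurationError(f"undefined activity cost centre: {cost_centre}")

    def medication(self, name: str) -> MedicationProfile:
        for m in self.medications:
            if m.name == name:
                return m
        raise ConfigurationError(f"undefined medication: {name}")


class StudyConfig(BaseModel):
    """Top-level config file: facilities + cost parameters + scenario block."""

    facilities: list[Facility]
    roles: list[Role]
    loadings: LoadingRates = Field(default_factory=LoadingRates)
    activities: list[ActivityTime]
    medications: list[MedicationProfile]
    scenario: dict = Field(default_factory=dict)
    days_per_month: int = Field(default=31, ge=1)
    currency_year: str = "2021-22"
    compound_loadings: bool = False

    @property
    def parameter_set(self) -> CostParameterSet:
        return CostParameterSet(
            roles=self.roles,
            loadings=self.loadings,
            activities=self.activities,
            medications=self.medications,
            days_per_month=self.days_per_month,
            currency_year=self.currency_year,
            compound_loadings=self.compound_loadings,
        )


# ---------------------------------------------------------------------------
# Serialisation round-trip
# ---------------------------------------------------------------------------

def config_to_yaml(config: StudyConfig) -> str:
    """Serialise a config to YAML (money as strings so cents survive)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_from_yaml(text: str) -> StudyConfig:
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed YAML: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        return StudyConfig.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigurationError(str(exc)) from exc


def load_config(path) -> StudyConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_yaml(fh.read())


# ---------------------------------------------------------------------------
# Packaged July-2019 fixture
# ---------------------------------------------------------------------------

def _fixture_text() -> str:
    return (
        importlib.resources.files("oatcost").joinpath("data/july2019.yaml").read_text("utf-8")
    )


def load_fixture_july2019() -> tuple[list[Facility], CostParameterSet]:
    """The packaged July-2019 base case: 7 facilities plus default unit costs.

    Facility cohorts and administration counts are the published census
    values (50 depot = 32 monthly + 18 weekly, 239 methadone, 40 SL
    BPN-NLX; 84 recorded depot administrations; 21/24/24 pharmacy orders).
    Unit costs are the synthetic defaults.
    """
    cfg = config_from_yaml(_fixture_text())
    return cfg.facilities, cfg.parameter_set


def load_fixture_config() -> StudyConfig:
    """The full packaged config (facilities, parameters and scenario block)."""
    return config_from_yaml(_fixture_text())


def allocate_proportionally(total: int, weights: Sequence[int]) -> list[int]:
    """Integer allocation of ``total`` across ``weights``: floor of the
    proportional share, with the remainder assigned to the largest weight.

    Used to spread facility order counts when only totals are recorded.
    """
    if total < 0:
        raise ConfigurationError("total must be >= 0")
    w = np.asarray(list(weights), dtype=float)
    if w.sum() <= 0:
        raise ConfigurationError("weights must have positive sum")
    shares = np.floor(total * w / w.sum()).astype(int)
    shares[int(np.argmax(w))] += total - int(shares.sum())
    return [int(s) for s in shares]


# ---------------------------------------------------------------------------
# Seeded generator
# ---------------------------------------------------------------------------

class ParameterRanges(BaseModel):
    """Sampling bounds for :func:`generate_parameter_set`.

    ``wage_bounds`` maps role name to (low, high) hourly wages;
    ``activity_bounds`` maps cost centre to (low, high) base minutes —
    the generated min/max observation range brackets the sampled base.
    """

    wage_bounds: dict[str, tuple[float, float]]
    activity_bounds: dict[str, tuple[float, float]]
    consumable_bounds: dict[str, tuple[float, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _wellformed(self) -> "ParameterRanges":
        for label, table in (
            ("wage_bounds", self.wage_bounds),
            ("activity_bounds", self.activity_bounds),
            ("consumable_bounds", self.consumable_bounds),
        ):
            for field, (lo, hi) in table.items():
                if lo > hi:
                    raise ValueError(f"{label}[{field}]: min {lo} > max {hi}")
                if lo < 0:
                    raise ValueError(f"{label}[{field}]: bounds must be >= 0")
        return self


def default_ranges() -> ParameterRanges:
    """Ranges bracketing the synthetic default fixture (±25% on wages/times)."""
    _, params = load_fixture_july2019()
    wage = {r.name: (float(r.hourly_wage) * 0.75, float(r.hourly_wage) * 1.25) for r in params.roles}
    act = {
        a.cost_centre: (a.minutes_base * 0.75, a.minutes_base * 1.25) for a in params.activities
    }
    cons = {
        m.name: (float(m.consumables_per_dose) * 0.75, float(m.consumables_per_dose) * 1.25)
        for m in params.medications
    }
    return ParameterRanges(wage_bounds=wage, activity_bounds=act, consumable_bounds=cons)


def generate_parameter_set(seed: int, ranges: ParameterRanges | None = None) -> CostParameterSet:
    """Draw a complete parameter set uniformly within ``ranges``.

    Deterministic for a fixed seed. Degenerate ranges (min == max
    everywhere) return the midpoint set exactly. Money values are
    quantised to the cent, times to 0.1 minute.
    """
    if ranges is None:
        ranges = default_ranges()
    rng = np.random.default_rng(seed)
    _, base = load_fixture_july2019()

    roles = []
    for r in base.roles:
        lo, hi = ranges.wage_bounds.get(r.name, (float(r.hourly_wage), float(r.hourly_wage)))
        wage = round(float(rng.uniform(lo, hi)), 2)
        roles.append(Role(name=r.name, hourly_wage=Decimal(str(wage))))

    activities = []
    for a in base.activities:
        lo, hi = ranges.activity_bounds.get(a.cost_centre, (a.minutes_base, a.minutes_base))
        mins = round(float(rng.uniform(lo, hi)), 1)
        activities.append(
            ActivityTime(
                cost_centre=a.cost_centre,
                minutes_base=mins,
                minutes_min=min(round(lo, 1), mins),
                minutes_max=max(round(hi, 1), mins),
                role=a.role,
                per_unit=a.per_unit,
            )
        )

    medications = []
    for m in base.medications:
        lo, hi = ranges.consumable_bounds.get(
            m.name, (float(m.consumables_per_dose), float(m.consumables_per_dose))
        )
        cons = round(float(rng.uniform(lo, hi)), 2)
        medications.append(
            MedicationProfile(
                name=m.name,
                dosing_frequency=m.dosing_frequency,
                unit_price=m.unit_price,
                consumables_per_dose=Decimal(str(cons)),
                administration_mode=m.administration_mode,
            )
        )

    return CostParameterSet(
        roles=roles,
        loadings=base.loadings,
        activities=activities,
        medications=medications,
        days_per_month=base.days_per_month,
        currency_year=base.currency_year,
    )
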