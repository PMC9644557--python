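"""One-way sensitivity analysis of the per-patient NSW service cost.

Eight scenario groups, each perturbed low and high (16 runs): the five
observed activity-time variables swing to their across-site minimum and
maximum, pharmacy dispensing time moves +/-10%, overheads +/-2.5
percentage points and labour on-costs +/-5 points. Each perturbation is
applied to a clone of the base parameter set, the base case is
recomputed, and the signed percentage change in monthly per-patient NSW
service cost is reported per medication. Published results for this
analysis are figure-only, so the reproduction targets are structural:
zero change at base, symmetric signs for linear variables, and daily
medications being the most sensitive to dosing time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Literal

import pandas as pd

from .costing import base_case
from .params import CostParameterSet, Facility

Direction = Literal["low", "high"]

#: group id -> (variable, perturbation kind, size). Kinds: set_to_min /
#: set_to_max on observed ranges, relative (fraction of base time),
#: absolute (percentage points on a loading rate).
GROUPS: dict[int, tuple[str, str, float]] = {
    1: ("inventory_ordering", "minmax", 0.0),
    2: ("inventory_receiving", "minmax", 0.0),
    3: ("prep_cleanup", "minmax", 0.0),
    4: ("dosing_per_patient", "minmax", 0.0),
    5: ("stock_check", "minmax", 0.0),
    6: ("pharmacy_dispensing", "relative", 0.10),
    7: ("overhead_rate", "absolute", 0.025),
    8: ("oncost_rate", "absolute", 0.05),
}


@dataclass(frozen=True)
class SensitivityScenario:
    group: int
    variable: str
    direction: Direction

    @property
    def label(self) -> str:
        return f"{self.variable}_{self.direction}"


@dataclass(frozen=True)
class SensitivityResult:
    scenario: SensitivityScenario
    pct_change: dict[str, float]  # stream -> signed % change in NSW per-patient cost


def all_scenarios() -> list[SensitivityScenario]:
    return [
        SensitivityScenario(group=g, variable=var, direction=d)
        for g, (var, _, _) in GROUPS.items()
        for d in ("low", "high")
    ]


def perturb(params: CostParameterSet, scenario: SensitivityScenario) -> CostParameterSet:
    """Clone the parameter set with exactly one variable perturbed.

    Values that would go negative are clamped at zero with a warning.
    """
    variable, kind, size = GROUPS[scenario.group]
    if kind == "minmax":
        activities = []
        for a in params.activities:
            if a.cost_centre == variable:
                new = a.minutes_min if scenario.direction == "low" else a.minutes_max
                activities.append(a.model_copy(update={"minutes_base": new}))
            else:
                activities.append(a)
        return params.model_copy(update={"activities": activities})
    if kind == "relative":
        factor = 1 - size if scenario.direction == "low" else 1 + size
        activities = []
        for a in params.activities:
            if a.cost_centre == variable:
                new = a.minutes_base * factor
                if new < 0:
                    warnings.warn(f"{variable}: perturbed time clamped at 0")
                    new = 0.0
                activities.append(
                    a.model_copy(
                        update={
                            "minutes_base": new,
                            "minutes_min": min(a.minutes_min, new),
                            "minutes_max": max(a.minutes_max, new),
                        }
                    )
                )
            else:
                activities.append(a)
        return params.model_copy(update={"activities": activities})
    # absolute percentage-point shift on a loading rate
    delta = Decimal(str(size)) * (-1 if scenario.direction == "low" else 1)
    current = getattr(params.loadings, variable)
    new_rate = current + delta
    if new_rate < 0:
        warnings.warn(f"{variable}: perturbed rate clamped at 0")
        new_rate = Decimal("0")
    loadings = params.loadings.model_copy(update={variable: new_rate})
    return params.model_copy(update={"loadings": loadings})


def _nsw_per_patient(facilities: list[Facility], params: CostParameterSet) -> dict[str, Decimal]:
    return {
        stream: sc.per_patient.nsw_total() for stream, sc in base_case(facilities, params).items()
    }


def run_scenario(
    scenario: SensitivityScenario,
    base_params: CostParameterSet,
    facilities: list[Facility],
    baseline: dict[str, Decimal] | None = None,
) -> SensitivityResult:
    """Recompute the base case under one perturbation; report % changes."""
    if baseline is None:
        baseline = _nsw_per_patient(facilities, base_params)
    perturbed = _nsw_per_patient(facilities, perturb(base_params, scenario))
    pct = {
        stream: float(100 * (perturbed[stream] - baseline[stream]) / baseline[stream])
        for stream in baseline
    }
    return SensitivityResult(scenario=scenario, pct_change=pct)


def tornado(
    base_params: CostParameterSet,
    facilities: list[Facility],
    scenarios: Iterable[SensitivityScenario] | None = None,
) -> pd.DataFrame:
    """All 16 one-way runs, sorted by largest absolute impact.

    Columns: group, variable, direction and the signed % change per
    medication, plus ``max_abs_pct`` (the sort key across medications).
    """
    scenarios = list(scenarios) if scenarios is not None else all_scenarios()
    baseline = _nsw_per_patient(facilities, base_params)
    rows = []
    for sc in scenarios:
        res = run_scenario(sc, base_params, facilities, baseline=baseline)
        row = {"group": sc.group, "variable": sc.variable, "direction": sc.direction}
        for stream, change in res.pct_change.items():
            row[f"pct_{stream}"] = change
        row["max_abs_pct"] = max(abs(v) for v in res.pct_change.values())
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values("max_abs_pct", ascending=False, kind="stable").reset_index(drop=True)


def plot_tornado(frame: pd.DataFrame, path, stream: str = "methadone") -> None:
    """Horizontal tornado bars of % change for one medication stream."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = f"pct_{stream}"
    pivot = frame.pivot_table(index="variable", columns="direction", values=col, aggfunc="first")
    order = pivot.abs().max(axis=1).sort_values().index
    pivot = pivot.loc[order]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.barh(pivot.index, pivot.get("high", 0), color="#c44e52", label="high")
    ax.barh(pivot.index, pivot.get("low", 0), color="#4c72b0", label="low")
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel(f"% change in per-patient NSW service cost ({stream})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
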