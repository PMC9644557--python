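"""Depot price calibration from published aggregate cost columns.

The study's per-dose prices for the weekly and monthly depot
preparations are not printed, but the implementation table publishes the
per-patient depot medication cost every month alongside enough
information to reconstruct each month's dose mix. Because

    per_patient_cost(m) = (P_monthly * monthly_doses(m)
                           + P_weekly * weekly_doses(m)) / patients(m)

is linear in the two unknown prices, any two months with linearly
independent weekly-dose-per-patient ratios identify them exactly: a 2x2
linear solve, performed here in exact rational arithmetic. The fitted
prices are then judged by their prediction residuals on every other
month of the published schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .money import aud, round_half_up
from .published import DEPOT_MEDICATION_COST_PER_PATIENT


class CalibrationError(ValueError):
    """The anchor months do not identify both prices (singular system)."""


def _frac(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, Decimal):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class PriceCalibration:
    """Fitted depot dose prices and the anchors that produced them."""

    weekly_price: Decimal
    monthly_price: Decimal
    anchor_months: tuple[int, int]
    residual: Decimal  # max |residual| at the anchors; 0 by construction


class DepotPriceModel:
    """Two-parameter price model for the depot medication bill.

    Parameters
    ----------
    per_patient_costs
        month -> published per-patient depot medication cost (AUD).
    dose_counts
        month -> (monthly_doses, weekly_doses, patients). Weekly doses
        include titration doses and may be fractional.
    """

    def __init__(
        self,
        per_patient_costs: Mapping[int, object],
        dose_counts: Mapping[int, tuple],
    ):
        self.per_patient_costs = {m: _frac(v) for m, v in per_patient_costs.items()}
        self.dose_counts = {
            m: (_frac(a), _frac(b), _frac(c)) for m, (a, b, c) in dose_counts.items()
        }
        missing = set(self.per_patient_costs) - set(self.dose_counts)
        if missing:
            raise CalibrationError(f"months without dose counts: {sorted(missing)}")

    def _totals(self, month: int) -> tuple[Fraction, Fraction, Fraction]:
        """(monthly doses, weekly doses, total bill) for one month."""
        monthly, weekly, patients = self.dose_counts[month]
        total = self.per_patient_costs[month] * patients
        return monthly, weekly, total

    def fit(self, anchors: Sequence[int] = (1, 12)) -> "DepotPriceResults":
        """Solve the 2x2 system exactly on the two anchor months."""
        a1, a2 = anchors
        for a in (a1, a2):
            if a not in self.per_patient_costs:
                raise CalibrationError(f"anchor month {a} not in the cost schedule")
        m1, w1, t1 = self._totals(a1)
        m2, w2, t2 = self._totals(a2)
        det = m1 * w2 - m2 * w1
        if det == 0:
            raise CalibrationError(
                f"anchor months {a1} and {a2} have identical dose ratios; "
                "weekly and monthly prices are not jointly identifiable"
            )
        monthly_price = (t1 * w2 - t2 * w1) / det
        weekly_price = (m1 * t2 - m2 * t1) / det
        if monthly_price <= 0 or weekly_price <= 0:
            raise CalibrationError(
                f"calibrated prices not positive (monthly={float(monthly_price):.2f}, "
                f"weekly={float(weekly_price):.2f})"
            )
        return DepotPriceResults(
            model=self,
            monthly_price_exact=monthly_price,
            weekly_price_exact=weekly_price,
            anchor_months=(int(a1), int(a2)),
        )


class DepotPriceResults:
    """Fitted prices plus residual diagnostics over the full schedule."""

    def __init__(
        self,
        model: DepotPriceModel,
        monthly_price_exact: Fraction,
        weekly_price_exact: Fraction,
        anchor_months: tuple[int, int],
    ):
        self.model = model
        self.monthly_price_exact = monthly_price_exact
        self.weekly_price_exact = weekly_price_exact
        self.anchor_months = anchor_months

    @property
    def monthly_price(self) -> Decimal:
        return aud(self.monthly_price_exact)

    @property
    def weekly_price(self) -> Decimal:
        return aud(self.weekly_price_exact)

    def predict(self, month: int) -> Fraction:
        """Exact predicted per-patient medication cost for one month."""
        monthly, weekly, patients = self.model.dose_counts[month]
        if patients == 0:
            return Fraction(0)
        return (self.monthly_price_exact * monthly + self.weekly_price_exact * weekly) / patients

    def residual_frame(self) -> pd.DataFrame:
        """Observed vs predicted per-patient cost, every month on record."""
        rows = []
        for month in sorted(self.model.per_patient_costs):
            observed = self.model.per_patient_costs[month]
            predicted = self.predict(month)
            rows.append(
                {
                    "month": month,
                    "observed": float(observed),
                    "predicted": float(predicted),
                    "predicted_rounded": round_half_up(predicted),
                    "residual": float(predicted - observed),
                    "is_anchor": month in self.anchor_months,
                }
            )
        return pd.DataFrame(rows)

    def calibration(self) -> PriceCalibration:
        anchor_resid = max(
            abs(self.predict(a) - self.model.per_patient_costs[a]) for a in self.anchor_months
        )
        return PriceCalibration(
            weekly_price=self.weekly_price,
            monthly_price=self.monthly_price,
            anchor_months=self.anchor_months,
            residual=aud(anchor_resid),
        )

    def summary(self) -> str:
        frame = self.residual_frame()
        lines = [
            "Depot medication price calibration",
            "==================================",
            f"anchor months:     {self.anchor_months[0]}, {self.anchor_months[1]}",
            f"weekly dose price: ${self.weekly_price}",
            f"monthly dose price: ${self.monthly_price}",
            "",
            frame.to_string(index=False, float_format=lambda v: f"{v:10.2f}"),
        ]
        return "\n".join(lines)


def calibrate_prices(
    per_patient_costs: Mapping[int, object],
    dose_counts: Mapping[int, tuple],
    anchors: Sequence[int] = (1, 12),
) -> PriceCalibration:
    """Functional wrapper: fit on two anchors, return the fitted prices."""
    return DepotPriceModel(per_patient_costs, dose_counts).fit(anchors).calibration()


def calibrate_from_published(scenario=None, anchors: Sequence[int] = (1, 12)) -> DepotPriceResults:
    """Fit against the packaged published cost schedule.

    Dose counts come from the default rollout scenario (or a supplied
    one); months with no depot patients are excluded.
    """
    from .rollout import RolloutScenario, dose_counts_by_month

    scenario = scenario or RolloutScenario()
    counts = dose_counts_by_month(scenario)
    costs = {
        m: c
        for m, c in enumerate(DEPOT_MEDICATION_COST_PER_PATIENT)
        if m in counts and counts[m][2] > 0
    }
    counts = {m: counts[m] for m in costs}
    return DepotPriceModel(costs, counts).fit(anchors)
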