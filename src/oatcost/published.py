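"""Published benchmark series from the NSW correctional OAT costing study.

These are *inputs*, not reproduction targets: the per-patient depot
medication-cost schedule is the data the depot price calibration is fit
against, and the count series document the implementation scenario the
default :class:`~oatcost.rollout.RolloutScenario` encodes. Whole-dollar
and whole-count values exactly as printed (month 0 = pre-implementation).
"""

from __future__ import annotations

#: Per-patient depot medication (Commonwealth) cost, months 0..12, AUD.
DEPOT_MEDICATION_COST_PER_PATIENT: tuple[int, ...] = (
    0, 531, 442, 422, 409, 401, 394, 390, 388, 386, 385, 384, 381,
)

#: Depot cohort by month under the published implementation scenario.
DEPOT_PATIENTS: tuple[int, ...] = (0, 16, 33, 49, 66, 82, 99, 115, 132, 148, 165, 181, 197)

#: Methadone cohort by month.
METHADONE_PATIENTS: tuple[int, ...] = (282, 269, 256, 243, 230, 217, 204, 191, 178, 165, 152, 139, 127)

#: Sublingual buprenorphine-naloxone cohort by month.
SL_BPN_PATIENTS: tuple[int, ...] = (47, 44, 40, 37, 33, 30, 26, 23, 19, 16, 12, 9, 5)

#: Total depot administrations by month (monthly + weekly + titration doses).
DEPOT_ADMINISTRATIONS: tuple[int, ...] = (0, 43, 60, 76, 93, 109, 126, 142, 159, 175, 192, 208, 222)

#: Depot patients in the weekly (initiation) phase by month.
WEEKLY_PHASE_PATIENTS: tuple[int, ...] = (0, 13, 13, 13, 13, 13, 13, 13, 13, 13, 13, 13, 12)

#: Weekly-phase share of the depot cohort, whole percent.
WEEKLY_PHASE_PERCENT: tuple[int, ...] = (0, 81, 39, 27, 20, 16, 13, 11, 10, 9, 8, 7, 6)
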