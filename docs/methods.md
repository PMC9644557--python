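# Methods

## Scope and perspective

`oatcost` models the monthly cost of delivering three opioid agonist
treatments — depot buprenorphine (weekly and monthly preparations),
liquid methadone and sublingual buprenorphine–naloxone (SL BPN-NLX) —
across a network of correctional centres, from two payer perspectives:
the NSW government (JHFMHN clinical/pharmacy labour plus CSNSW custodial
supervision) and the Commonwealth (medication supply). Medical
assessment and review time, adverse events, downstream health-care and
diversion-related costs are out of scope. All money is 2021-22 AUD,
entered already indexed; no internal CPI adjustment is applied.

## Cost kernel

Each activity is observed as minutes of one staff role's time and
charged per pharmacy order, per administration event or per patient
dose. Labour is valued at the role's hourly award wage scaled by
on-costs (26%) and overheads (27.5%), both expressed as fractions *of
base labour cost* and therefore applied **additively**
(×(1 + 0.26 + 0.275) = ×1.535). Whether the source accounting
compounded overheads over on-costed labour cannot be determined, so
additive is the default and `compound_loadings: true` switches to
×1.26×1.275. Internal arithmetic uses `decimal.Decimal` unrounded;
entries are quantised to the cent when read, payer totals are sums of
quantised entries (so the payer decomposition holds to the cent by
construction), and printed tables round to whole dollars, half-up.

Daily medications run one group dosing-window event per facility per day
(`dosing_events_per_day`, default 1 — the source does not state a
count); segregation patients are dosed in a separate daily round that
repeats the event's preparation and checking times and adds a 10-minute
nurse walk per patient location. Each depot administration is an
individual consultation-room event carrying its own preparation, stock
check and supervision. Movement supervision is charged per patient per
administration and clinic supervision per event duration; the field
observations behind that granularity are not published, so the split is
a design choice exposed through the activity table.

Consumables are per-dose materials at market rates. They sit in the
JHFMHN clinic-administration line but do not scale with wages, so the
wage-homogeneity property (×k wages → ×k NSW cost) is exact only for
labour; tests check it on a zero-consumable configuration.

## Parameters

| parameter | unit | default | why |
|---|---|---|---|
| on-cost rate | fraction of base labour | 0.26 | stated loading |
| overhead rate | fraction of base labour | 0.275 | stated loading |
| days per month | days | 31 | every published daily-administration count equals cohort × 31 |
| uptake increment | share of population/month | 0.05 | published scenario |
| max depot share | share | 0.60 | published scenario |
| weekly doses per methadone transfer | doses | 2 | published scenario (the trial's own 4-weekly-dose initiation regimen is reachable by setting 4, but is not a reproduction target) |
| titration rate | fraction of weekly-phase patients | 0.065 | published scenario |
| SL BPN-NLX wind-down | patients | 47 → 5 | see below |
| wages, activity minutes, consumables | AUD/h, min, AUD | synthetic | unit-cost workbook unavailable |

The packaged facility census (cohorts 32/18 depot, 239 methadone, 40 SL
BPN-NLX; 84 recorded depot administrations; 21/24/24 monthly pharmacy
orders) is published data. Order totals are spread across the seven
facilities proportionally to cohort size with the remainder assigned to
the largest facility, because only totals are recorded; the
`segregation_patients` counts (one at each maximum-security site) are
synthetic. The composition of the 84 recorded depot administrations is
not published; the base case imputes one monthly dose per
monthly-preparation patient (32) and costs the remaining 52 as weekly
doses.

## Rollout simulation

A closed population of 329 (282 methadone + 47 SL BPN-NLX at month 0)
transitions deterministically for 12 months:

* depot(m) = round_half_up(329 · min(m·0.05, 0.60));
* SL BPN-NLX interpolates linearly from 47 to 5 **with rollout
  progress** min(m·uptake, cap)/cap rather than with calendar month.
  Under defaults this is identical (progress = m/12) and reproduces all
  13 published cohort counts; it also makes a zero-uptake scenario a
  true no-op, which a calendar-indexed wind-down would not be. The
  scenario narrative's "two SL BPN-NLX patients left by month 12"
  conflicts with the printed 5; the printed table is followed.
* methadone is the remainder; month-over-month decrements are the
  transfers, and this month's methadone-origin transfers are exactly the
  weekly-phase cohort.

Every depot patient takes one monthly dose (carry-over + new transfers
= the current cohort), methadone-origin transfers add two weekly doses,
and titration adds 0.065 doses per weekly-phase patient, kept as an
exact fraction; the monthly total is rounded half-up once, at the end.
All count arithmetic uses `fractions.Fraction`, because several printed
values are exact ties (the 164.5-patient depot cohort at month 10, the
43.5 SL BPN-NLX cohort at month 1) and half-up rounding of a binary
float would not be trustworthy there. This convention reproduces all 13
published depot administration counts (0, 43, 60, …, 222).

Costing holds per-event fixed costs constant — all seven facilities keep
running their daily window events while a stream has any patients, and
baseline order volumes persist — while cohorts scale continuously in
proportion to baseline facility shares. Depot incurs orders only once
it has patients, and its month-0 per-patient costs are reported as zero
with an explicit undefined flag. This structure makes unrounded
per-patient methadone and SL BPN-NLX service costs non-decreasing and
unrounded depot service cost non-increasing from month 1, matching the
published qualitative trends; the monotonicity tests run on unrounded
values because whole-dollar printing can wobble by a dollar or two.

## Price calibration

Per-patient depot medication cost is linear in the two unknown dose
prices, so months 1 and 12 of the published schedule (dose mixes
16 monthly + 26.845 weekly-equivalent over 16 patients, and 197 + 24.78
over 197) identify them exactly: weekly $96.65, monthly $368.84, solved
in rational arithmetic. Anchor months are reproduced to the cent by
construction; all other months predict within 2%, with month 2 the
largest deviation (≈1.2% — plausibly box-packaging effects in the
source data, which the linear model does not represent). Anchors with
proportional dose mixes make the system singular and raise a
`CalibrationError` rather than returning an arbitrary solution.

## Sensitivity analysis

Sixteen one-way runs (8 groups × low/high) perturb a clone of the base
parameter set and recompute the July-2019 base case; results are signed
percentage changes in per-patient NSW service cost per medication,
sorted for a tornado plot. Published results for this analysis exist
only as a figure, so acceptance is property-based: no change at base,
antisymmetry of the ±10% dispensing perturbation, loadings hitting all
medications by one global factor, and daily medications being most
sensitive to per-patient dosing time (their dose count is 31× depot's).
Times and rates that would go negative are clamped at zero with a
warning. Perturbations run against the base case; rerunning them
through the rollout simulator is a matter of swapping the evaluation
function.

## Synthetic defaults: what passing tests do and do not show

The default wages (RN $48/h, correctional officer $40/h, pharmacy
assistant $29/h, chief pharmacist $70/h, administrator $36/h), activity
minutes and consumables are one hand-constructed set chosen for realism
and for the observed service-cost ordering depot < methadone < SL
BPN-NLX; the seeded generator draws alternatives within ±25% ranges for
robustness testing. Count reproduction and all structural properties
are independent of these values; the dollar figures the package prints
are *not* estimates of the study's dollar figures and should not be
read as such. Real-world features the fixture does not emulate include
actual award-wage schedules, PBS pack sizes and wastage, intra-month
census churn, and clinic-space constraints.

## Problem sizes

All computations are closed-form accounting over 7 facilities × 13
months × 3 streams; the full pipeline (base case, 13-month simulation,
calibration, 16 sensitivity runs) executes in well under a minute on a
single core, so no scaling-down of the study conditions was needed
anywhere.

## Known limitations

* One aggregate depot "event" per administration: satellite clinics are
  not separated from main-clinic consultations.
* The rollout treats the population as closed (no receptions/releases).
* Methadone and SL BPN-NLX medication prices are the constant published
  per-patient monthly figures ($85, $525) spread over 31 daily doses,
  not PBS pack-level prices.
* Probabilistic (Monte-Carlo) sensitivity analysis is not implemented;
  the analysis is deliberately one-way.
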