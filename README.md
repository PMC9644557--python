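# oatcost

Bottom-up (time-driven activity-based) micro-costing of opioid agonist
treatment (OAT) delivery in correctional centres, built around the 2019
NSW setting in which depot buprenorphine was introduced alongside daily
liquid methadone and sublingual buprenorphine–naloxone (SL BPN-NLX).

The package is for health economists and service planners who need to
compare the monthly per-patient cost of the three medications from the
budget holders' perspectives — the state health network (JHFMHN) and
custodial agency (CSNSW), together the NSW government service cost, and
the Commonwealth, which pays for medication through the PBS — and to
project how those costs move as a prison system rolls depot
buprenorphine out.

## The model

Every cost is one of three kinds:

* **labour** — activity minutes × the role's hourly award wage, loaded
  additively for on-costs (26% of base labour) and overheads (27.5%):
  `cost = (minutes / 60) · w · (1 + 0.26 + 0.275)`.
  Activities are charged per pharmacy order (ordering, receiving,
  dispensing, transport), per administration event (preparation/clean-up,
  stock check, clinic supervision) or per patient dose (dosing /
  consultation time, movement supervision, and a 10-minute nurse walk for
  segregation dosing);
* **consumables** — per dose, at market rates;
* **medication** — doses × PBS unit price, paid by the Commonwealth.

Daily medications are administered to the whole cohort through a dosing
window once per facility-day; depot administrations are individual
consultation-room events. Because event- and order-level costs are fixed
while dose-level costs scale with the cohort, per-patient cost falls as
cohorts grow — the mechanism that drives every trend in the rollout
simulation.

The **rollout simulator** moves a closed population of 329 patients
(282 methadone + 47 SL BPN-NLX) onto depot buprenorphine in 5%-of-
population monthly steps to a 60% cap at month 12. Methadone-origin
transfers spend their first month in a weekly initiation phase (two
weekly doses + one monthly dose); SL BPN-NLX transfers switch directly
to monthly dosing; 6.5% of weekly-phase patients receive one extra
titration dose, carried fractionally and rounded half-up only in the
monthly total. Exact rational arithmetic makes every printed count
reproducible, ties included.

The **price calibration** recovers the unpublished weekly and monthly
depot dose prices from the published per-patient medication-cost
schedule: the per-patient cost is linear in the two prices, so two
months with independent dose mixes identify them through an exact 2×2
solve (`DepotPriceModel(...).fit()`), judged by prediction residuals on
the remaining months.

The **sensitivity module** runs the eight one-way scenario groups (five
activity-time ranges to their observed min/max, dispensing time ±10%,
overheads ±2.5 points, on-costs ±5 points), both directions, and reports
the % change in per-patient NSW service cost per medication.

The study's unit-cost workbook is not public, so the packaged default
parameter set is synthetic (realistic 2021-22 AUD values); published
*count* surfaces reproduce exactly, published *dollar* surfaces are
matched structurally (ordering, trends, accounting identities), not in
value. See `docs/methods.md`.

## Worked example

```bash
$ oatcost --log-level WARNING base-case --out bc.csv
depot: 50 patients, 84 administrations, NSW $153.54/patient, Commonwealth $336.57/patient
methadone: 239 patients, 7409 administrations, NSW $228.67/patient, Commonwealth $84.94/patient
sl_bpn_nlx: 40 patients, 1240 administrations, NSW $517.87/patient, Commonwealth $525.14/patient
```

The July-2019 census: 50 depot patients (32 monthly / 18 weekly) took 84
administrations, while 239 methadone and 40 SL BPN-NLX patients each
needed a dose every one of 31 days (7,409 and 1,240 administrations).
Depot is the cheapest service to run per patient and SL BPN-NLX by far
the dearest — its small cohort shares the same fixed event costs as
methadone's large one.

```bash
$ oatcost --log-level WARNING rollout --out rollout.csv && head -3 rollout.csv
rollout_pct,month,depot_patients,depot_weekly_patients,weekly_pct,depot_admins,...
0,0,0,0,0,0,0,0,0,282,8742,123,94,217,47,1457,257,205,462,0,85,525,329
5,1,16,13,81,43,235,88,322,269,8339,124,95,220,44,1364,269,215,484,531,85,525,329
```

Month 1: 16 depot patients, 13 of them (81%) in the weekly phase, 43
depot administrations; per-patient depot service cost then falls every
month (initiation share shrinks) while methadone and SL BPN-NLX
per-patient costs rise as their cohorts thin out against fixed costs.

```bash
$ oatcost --log-level WARNING calibrate --out cal.csv
weekly dose price: $96.65
monthly dose price: $368.84
```

With those two prices the predicted per-patient depot medication cost
matches the published schedule at both anchors exactly and everywhere
else within 2% (month 3 rounds to the printed $422).

`oatcost sensitivity --out tornado.csv --plot tornado.png` and
`oatcost generate-config --seed 7 --out cfg.yaml` cover the remaining
stages; every output comes with a `.manifest.json` recording the config
digest, seed and package version.

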