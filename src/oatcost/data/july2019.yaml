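# July 2019 base case: seven NSW correctional centres delivering OAT.
#
# Facility cohorts, recorded depot administrations and pharmacy-order
# totals (21 depot / 24 methadone / 24 SL BPN-NLX, spread across
# facilities proportionally to cohort size, remainder to the largest
# facility) are the published census values for the study month.
#
# Unit costs (wages, activity minutes, consumables) are SYNTHETIC
# defaults: the study's unit-cost workbook is not publicly available, so
# these are hand-constructed, realistic 2021-22 AUD values. Dollar
# outputs computed from them are not reproductions of the published
# dollar tables. segregation_patients counts are likewise synthetic.
#
# Depot medication prices are the pair calibrated against the published
# implementation-scenario per-patient medication-cost schedule; methadone
# and SL BPN-NLX per-dose prices are the published constant per-patient
# monthly figures ($85, $525) divided over 31 daily doses.

days_per_month: 31
currency_year: "2021-22"
compound_loadings: false

loadings:
  oncost_rate: "0.26"
  overhead_rate: "0.275"

roles:
  - {name: registered_nurse_y8, hourly_wage: "48.00"}
  - {name: correctional_officer_1c_y2, hourly_wage: "40.00"}
  - {name: pharmacy_assistant_g1y8, hourly_wage: "29.00"}
  - {name: chief_pharmacist, hourly_wage: "70.00"}
  - {name: pharmacy_admin_g6, hourly_wage: "36.00"}

activities:
  - {cost_centre: inventory_ordering,   minutes_base: 20, minutes_min: 15,  minutes_max: 30,  role: registered_nurse_y8,        per_unit: per_order}
  - {cost_centre: inventory_receiving,  minutes_base: 15, minutes_min: 10,  minutes_max: 25,  role: registered_nurse_y8,        per_unit: per_order}
  - {cost_centre: prep_cleanup,         minutes_base: 15, minutes_min: 10,  minutes_max: 25,  role: registered_nurse_y8,        per_unit: per_event}
  - {cost_centre: dosing_per_patient,   minutes_base: 2,  minutes_min: 1.5, minutes_max: 4,   role: registered_nurse_y8,        per_unit: per_patient_dose}
  - {cost_centre: stock_check,          minutes_base: 5,  minutes_min: 3,   minutes_max: 10,  role: registered_nurse_y8,        per_unit: per_event}
  - {cost_centre: pharmacy_dispensing,  minutes_base: 30, minutes_min: 20,  minutes_max: 45,  role: pharmacy_assistant_g1y8,    per_unit: per_order}
  - {cost_centre: transport,            minutes_base: 60, minutes_min: 30,  minutes_max: 120, role: pharmacy_admin_g6,          per_unit: per_order}
  - {cost_centre: movement_supervision, minutes_base: 2,  minutes_min: 1,   minutes_max: 5,   role: correctional_officer_1c_y2, per_unit: per_patient_dose}
  - {cost_centre: clinic_supervision,   minutes_base: 30, minutes_min: 20,  minutes_max: 45,  role: correctional_officer_1c_y2, per_unit: per_event}
  - {cost_centre: segregation_walk,     minutes_base: 10, minutes_min: 10,  minutes_max: 10,  role: registered_nurse_y8,        per_unit: per_patient_dose}

medications:
  - {name: depot_weekly,  dosing_frequency: weekly,  unit_price: "96.65",  consumables_per_dose: "1.50", administration_mode: consultation_room}
  - {name: depot_monthly, dosing_frequency: monthly, unit_price: "368.84", consumables_per_dose: "1.50", administration_mode: consultation_room}
  - {name: methadone,     dosing_frequency: daily,   unit_price: "2.74",   consumables_per_dose: "0.30", administration_mode: dosing_window_group}
  - {name: sl_bpn_nlx,    dosing_frequency: daily,   unit_price: "16.94",  consumables_per_dose: "0.20", administration_mode: dosing_window_group}

facilities:
  - name: Inner Metro 1
    security: Min
    cohort_depot_monthly: 4
    cohort_depot_weekly: 4
    cohort_methadone: 33
    cohort_sl_bpn: 5
    depot_administrations: 11
    segregation_patients: 0
    dosing_events_per_day: 1
    orders_per_month: {depot: 3, methadone: 3, sl_bpn_nlx: 3}
  - name: Inner Metro 2
    security: Min/Med/Max
    cohort_depot_monthly: 5
    cohort_depot_weekly: 3
    cohort_methadone: 16
    cohort_sl_bpn: 1
    depot_administrations: 12
    segregation_patients: 0
    dosing_events_per_day: 1
    orders_per_month: {depot: 3, methadone: 1, sl_bpn_nlx: 0}
  - name: Outer Metro 1
    security: Min/Med/Max
    cohort_depot_monthly: 4
    cohort_depot_weekly: 0
    cohort_methadone: 21
    cohort_sl_bpn: 3
    depot_administrations: 4
    segregation_patients: 0
    dosing_events_per_day: 1
    orders_per_month: {depot: 1, methadone: 2, sl_bpn_nlx: 1}
  - name: Regional 1
    security: Max
    cohort_depot_monthly: 0
    cohort_depot_weekly: 6
    cohort_methadone: 32
    cohort_sl_bpn: 5
    depot_administrations: 20
    segregation_patients: 1
    dosing_events_per_day: 1
    orders_per_month: {depot: 2, methadone: 3, sl_bpn_nlx: 3}
  - name: Regional 2
    security: Min/Max
    cohort_depot_monthly: 10
    cohort_depot_weekly: 0
    cohort_methadone: 32
    cohort_sl_bpn: 12
    depot_administrations: 10
    segregation_patients: 0
    dosing_events_per_day: 1
    orders_per_month: {depot: 7, methadone: 3, sl_bpn_nlx: 7}
  - name: Regional Remand
    security: Min/Med
    cohort_depot_monthly: 0
    cohort_depot_weekly: 5
    cohort_methadone: 53
    cohort_sl_bpn: 13
    depot_administrations: 18
    segregation_patients: 0
    dosing_events_per_day: 1
    orders_per_month: {depot: 2, methadone: 7, sl_bpn_nlx: 10}
  - name: Regional 3
    security: Max
    cohort_depot_monthly: 9
    cohort_depot_weekly: 0
    cohort_methadone: 52
    cohort_sl_bpn: 1
    depot_administrations: 9
    segregation_patients: 1
    dosing_events_per_day: 1
    orders_per_month: {depot: 3, methadone: 5, sl_bpn_nlx: 0}

scenario:
  months: 12
  total_population: 329
  uptake_increment: 0.05
  max_share: 0.60
  sbl_start: 47
  sbl_end: 5
  weekly_doses_per_methadone_transfer: 2
  titration_rate: 0.065
  days_per_month: 31
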