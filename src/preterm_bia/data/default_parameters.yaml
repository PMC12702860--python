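label: default-calibrated
currency_year: 2024
inflation_index: {2017: 100.0, 2018: 102.0, 2019: 104.9, 2020: 109.2, 2021: 111.3,
  2022: 114.9, 2023: 118.3, 2024: 121.8}
parameters:
  charge_to_cost_ratio:
    value: 0.44
    kind: factor
    bounds: [0.05, 1.5]
    note: 'placeholder: scalar hospital cost-to-charge ratio'
  cost_home_infection: {value: 1049.0, kind: cost, year_of_value: 2024, note: 'placeholder:
      per home-managed infection'}
  cost_infection_hosp: {value: 2263.0, kind: charge, year_of_value: 2024, note: 'placeholder:
      per in-hospital NGT infection'}
  cost_ngt_discharge: {value: 3852.0, kind: cost, year_of_value: 2024, note: 'placeholder:
      per discharge home with an NGT'}
  cost_rehospitalization: {value: 13900.0, kind: cost, year_of_value: 2024, note: 'placeholder:
      per rehospitalization episode'}
  fertility_rate_annual: {value: 0.0565, kind: rate, period_days: 365.0, note: 'placeholder:
      births per woman-year'}
  home_infection_annual_y1: {value: 0.12, kind: probability, period_days: 365.0, note: 'placeholder:
      declining home-infection risk'}
  home_infection_annual_y2: {value: 0.1, kind: probability, period_days: 365.0, note: placeholder}
  home_infection_annual_y3: {value: 0.08, kind: probability, period_days: 365.0, note: placeholder}
  home_infection_annual_y4: {value: 0.07, kind: probability, period_days: 365.0, note: placeholder}
  home_infection_annual_y5: {value: 0.06, kind: probability, period_days: 365.0, note: placeholder}
  m2_rehosp_factor:
    value: 1.3
    kind: factor
    bounds: [0.2, 5.0]
    note: 'placeholder: elevated year-1 rehospitalization risk with an NGT at home'
  mort_home_annual_later: {value: 0.003, kind: probability, period_days: 365.0, note: 'placeholder:
      later-year at-home mortality'}
  mort_home_annual_y1: {value: 0.01, kind: probability, period_days: 365.0, note: 'placeholder:
      first-year at-home mortality'}
  mort_hospital_daily: {value: 0.0002, kind: probability, period_days: 1.0, note: 'placeholder:
      in-hospital background mortality'}
  n_patients: {value: 100.0, kind: count, uncertainty_frac: 0.0, note: 'published:
      100 hypothetical preterm infants, GAB 25-30 weeks'}
  ngt_home_infection_or: {value: 2.0, kind: odds_ratio, note: 'placeholder: elevated
      year-1 infection odds with an NGT at home'}
  nicu_charge_per_day: {value: 3371.187537993888, kind: charge, year_of_value: 2024,
    note: 'back-solved: SoC payer NICU category matches the published magnitude'}
  nonfof_staff_factor:
    value: 1.3
    kind: factor
    bounds: [0.2, 5.0]
    note: 'placeholder: extra training effort in the non-FOF group'
  p_infection_hosp_daily: {value: 0.0012, kind: probability, period_days: 1.0, note: 'back-solved:
      ~7-8 NGT infections per 100 over the NICU stay'}
  prop_births_preterm_25_30: {value: 0.009355341550269913, kind: probability, period_days: 365.0,
    note: 'back-solved below: covered lives exactly 982,791'}
  prop_discharge_to_ward: {value: 0.1, kind: probability, period_days: 365.0, note: 'placeholder:
      share of NICU discharges via a lower-acuity ward'}
  prop_gab_25_28: {value: 0.5, kind: probability, period_days: 365.0, note: 'placeholder:
      GAB mix for weighted rehospitalization risk'}
  prop_nns_at_birth: {value: 0.02, kind: probability, period_days: 365.0, note: 'placeholder:
      small fraction with NNS already developed at birth'}
  prop_train_success_pfos: {value: 0.9336, kind: probability, period_days: 365.0,
    note: 'back-solved: yields ~6.4 NGT discharges per 100 (PFOS)'}
  prop_train_success_soc: {value: 0.9384, kind: probability, period_days: 365.0, note: 'back-solved:
      yields ~5.9 NGT discharges per 100 (SoC)'}
  prop_women_reproductive_age: {value: 0.1925, kind: probability, period_days: 365.0,
    note: 'placeholder: share of insured population who are women of reproductive
      age'}
  rehosp_los_days:
    value: 9.0
    kind: count
    bounds: [1.5, 90.0]
    note: 'placeholder: mean rehospitalization stay'
  rehosp_rate_24_27_y1: {value: 0.51, kind: rate, period_days: 365.0, note: 'back-solved:
      GAB 24-27 rehospitalization risk, year 1; levels chosen so the mixed cohort
      accrues ~123 rehospitalizations per 100 over 5 years'}
  rehosp_rate_24_27_y2: {value: 0.32, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_24_27_y3: {value: 0.21, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_24_27_y4: {value: 0.16, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_24_27_y5: {value: 0.13, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_28_31_y1: {value: 0.34, kind: rate, period_days: 365.0, note: 'back-solved:
      GAB 28-31 rehospitalization risk, year 1'}
  rehosp_rate_28_31_y2: {value: 0.22, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_28_31_y3: {value: 0.145, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_28_31_y4: {value: 0.11, kind: rate, period_days: 365.0, note: back-solved}
  rehosp_rate_28_31_y5: {value: 0.085, kind: rate, period_days: 365.0, note: back-solved}
  sessions_per_patient_pfos:
    value: 48.0
    kind: count
    bounds: [0.0, 500.0]
    note: 'placeholder: fewer hands-on sessions with the pulsed-pacifier device'
  sessions_per_patient_soc:
    value: 57.0
    kind: count
    bounds: [0.0, 500.0]
    note: 'placeholder: manual oral-stimulation sessions per SoC patient'
  staff_min_per_session:
    value: 15.0
    kind: count
    bounds: [1.0, 120.0]
    note: 'placeholder: hands-on minutes per training session'
  staff_wage_per_hour: {value: 60.0, kind: cost, year_of_value: 2024, note: 'placeholder:
      loaded nursing wage'}
  time_to_fof_pfos:
    value: 39.093636961604126
    kind: count
    bounds: [2.0, 1000000000.0]
    note: 'back-solved: calibrated to 59.8 d arm LOS'
  time_to_fof_soc:
    value: 45.175218476316495
    kind: count
    bounds: [2.0, 1000000000.0]
    note: 'back-solved: mean days in training state; calibrated to 65.8 d arm LOS'
  training_start_day:
    value: 21.0
    kind: count
    bounds: [0.0, 180.0]
    note: 'placeholder: oral stimulation typically starts ~3 weeks after birth'
  ttd:
    value: 0.8
    kind: factor
    bounds: [0.05, 5.0]
    note: 'published base case: time-to-discharge factor for the non-FOF group'
  ward_charge_per_day: {value: 985.0, kind: charge, year_of_value: 2024, note: 'placeholder:
      lower-acuity (level I) daily charge'}
  ward_los_days:
    value: 10.0
    kind: count
    bounds: [1.5, 120.0]
    note: 'placeholder: mean lower-acuity ward stay'
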