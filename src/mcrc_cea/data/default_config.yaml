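# Default model configuration.
#
# Costs are US$ per administration / day / episode at a reference patient
# (55.6 kg, 1.6 m^2 BSA); sampling distributions are gamma(shape, scale)
# for costs and beta(alpha, beta) for utilities and probabilities.
#
# AE incidences are NOT part of the published table; the values below are
# package defaults in the range reported by first-line mCRC trials and are
# meant to be overridden with trial-specific rates.
#
# Population presets give the true weekly transition probabilities used by
# the synthetic trial generator (p_pf_pd, p_pf_dead, p_pd_dead).

parameters:
  # -- systemic therapy regimens (per administration) --
  folfox4:      {base: 219,  low: 137,    high: 273,    family: gamma, a: 100.4, b: 2.2,    unit: per_administration}
  folfiri:      {base: 134,  low: 87,     high: 184,    family: gamma, a: 42.5,  b: 3.2,    unit: per_administration}
  mfolfox6:     {base: 141,  low: 93,     high: 177,    family: gamma, a: 93.4,  b: 1.5,    unit: per_administration}
  xelox:        {base: 68,   low: 54,     high: 83,     family: gamma, a: 118.9, b: 0.6,    unit: per_administration}
  cetuximab:    {base: 1577, low: 1183,   high: 1972,   family: gamma, a: 89.8,  b: 17.6,   unit: per_administration}
  panitumumab:  {base: 2318, low: 1738,   high: 2897,   family: gamma, a: 90.2,  b: 25.7,   unit: per_administration}
  bevacizumab:  {base: 1104, low: 828,    high: 1380,   family: gamma, a: 90.1,  b: 12.3,   unit: per_administration}
  # -- management of grade 3-4 adverse events (per episode) --
  acneiform_rash: {base: 387,  low: 204,  high: 569,    family: gamma, a: 28.7,  b: 13.5,   unit: per_episode}
  desquamation:   {base: 387,  low: 204,  high: 569,    family: gamma, a: 28.7,  b: 13.5,   unit: per_episode}
  diarrhea:       {base: 2118, low: 1341, high: 2895,   family: gamma, a: 46.0,  b: 46.0,   unit: per_episode}
  infection:      {base: 6732, low: 4653, high: 8811,   family: gamma, a: 60.4,  b: 111.4,  unit: per_episode}
  leukopenia:     {base: 6732, low: 4653, high: 8811,   family: gamma, a: 60.4,  b: 111.4,  unit: per_episode}
  neutropenia:    {base: 6732, low: 4653, high: 8811,   family: gamma, a: 60.4,  b: 111.4,  unit: per_episode}
  # -- treatment-related procedures --
  laboratory_test:         {base: 241,  low: 181,  high: 301,  family: gamma, a: 90.8,  b: 2.7,  unit: per_administration}
  radiographic_test:       {base: 1494, low: 1256, high: 1731, family: gamma, a: 217.6, b: 6.9,  unit: per_episode}
  consultation:            {base: 192,  low: 101,  high: 283,  family: gamma, a: 28.2,  b: 6.8,  unit: per_administration}
  hospitalization_per_day: {base: 710,  low: 568,  high: 853,  family: gamma, a: 137.1, b: 5.2,  unit: per_day}
  palliative_care_per_day: {base: 1173, low: 836,  high: 1510, family: gamma, a: 69.2,  b: 16.9, unit: per_day}
  # -- indirect costs --
  time_cost_per_day:         {base: 72,  low: 51,  high: 114,  family: gamma, a: 52.5, b: 1.4, unit: per_day}
  transportation_round_trip: {base: 6.4, low: 2.6, high: 10.3, family: gamma, a: 18.4, b: 0.3, unit: per_round_trip}
  # -- health utilities --
  progression_free:    {base: 0.72, low: 0.49,   high: 0.95,   family: beta, a: 17,  b: 6.5,    unit: unitless}
  progressed_relative: {base: 0.88, low: 0.75,   high: 1.0,    family: beta, a: 42,  b: 5.7,    unit: unitless}
  palliative_relative: {base: 0.50, low: 0.4,    high: 0.6,    family: beta, a: 67,  b: 66.5,   unit: unitless}
  ae_decrement:        {base: 0.07, low: 0.0525, high: 0.0875, family: beta, a: 83,  b: 1104.5, unit: unitless}

arms:
  bev:
    first_line_drug: bevacizumab
    admin_interval_weeks: 2
    backbone: mfolfox6
    second_line_drug: panitumumab
    second_line_backbone: folfiri
    second_line_interval_weeks: 2
    ae_profile:
      diarrhea:    {probability: 0.09, a: 18.0, b: 182.0, cost: diarrhea}
      infection:   {probability: 0.05, a: 10.0, b: 190.0, cost: infection}
      leukopenia:  {probability: 0.03, a: 6.0,  b: 194.0, cost: leukopenia}
      neutropenia: {probability: 0.22, a: 44.0, b: 156.0, cost: neutropenia}
  anti_egfr:
    first_line_drug: cetuximab
    admin_interval_weeks: 2
    backbone: folfiri
    second_line_drug: bevacizumab
    second_line_backbone: mfolfox6
    second_line_interval_weeks: 2
    ae_profile:
      acneiform_rash: {probability: 0.17, a: 34.0, b: 166.0, cost: acneiform_rash}
      diarrhea:       {probability: 0.12, a: 24.0, b: 176.0, cost: diarrhea}
      infection:      {probability: 0.06, a: 12.0, b: 188.0, cost: infection}
      leukopenia:     {probability: 0.03, a: 6.0,  b: 194.0, cost: leukopenia}
      neutropenia:    {probability: 0.25, a: 50.0, b: 150.0, cost: neutropenia}

settings:
  horizon_weeks: 520
  annual_discount_rate: 0.03
  wtp: 97832.0
  second_line_duration_weeks: 52
  ae_decrement_duration_weeks: 4
  imaging_interval_weeks: 8
  half_cycle_correction: false

populations:
  kras_wt:
    bev:       {p_pf_pd: 0.0162, p_pf_dead: 0.0018, p_pd_dead: 0.0080}
    anti_egfr: {p_pf_pd: 0.0150, p_pf_dead: 0.0017, p_pd_dead: 0.0068}
  pan_ras_wt:
    bev:       {p_pf_pd: 0.0155, p_pf_dead: 0.0018, p_pd_dead: 0.0076}
    anti_egfr: {p_pf_pd: 0.0140, p_pf_dead: 0.0016, p_pd_dead: 0.0060}
  pan_ras_wt_left:
    bev:       {p_pf_pd: 0.0148, p_pf_dead: 0.0017, p_pd_dead: 0.0070}
    anti_egfr: {p_pf_pd: 0.0124, p_pf_dead: 0.0014, p_pd_dead: 0.0050}

trial:
  n_per_arm: 300
  accrual_weeks: 78
  max_follow_up_weeks: 312
  risk_table_interval_weeks: 26
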