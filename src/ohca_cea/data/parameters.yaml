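# Model parameter registry: means, 95% CIs and sampling-distribution families
# for the OHCA care-pathway model. Costs in 2016-17 pound sterling, lengths of
# stay in days, person-years in years, utilities as QALY weights.
#
# Probabilities use beta distributions, costs / durations use gamma
# distributions; entries printed without an interval are held fixed in the
# probabilistic sensitivity analysis. p_survival_hospital_als carries the
# cohort value 0.258 (survival to hospital arrival, 25.8%).
parameters:
  - {name: cost_prehospital_als,      mean: 347.0,   family: fixed}
  - {name: cost_prehospital_ccm_addon, mean: 1711.0, family: fixed}
  - {name: p_survival_hospital_als,   mean: 0.258,   ci: [0.25, 0.27],    family: beta}
  - {name: cost_ed,                   mean: 377.0,   ci: [355.0, 399.0],  family: gamma}
  - {name: p_icu_admission,           mean: 0.65,    ci: [0.58, 0.71],    family: beta}
  - {name: cost_icu_daily_survivor,   mean: 1745.0,  ci: [1654.0, 1836.0], family: gamma}
  - {name: los_icu_survivor,          mean: 5.7,     ci: [5.4, 6.0],      family: gamma}
  - {name: cost_icu_daily_death,      mean: 1768.0,  ci: [1668.0, 1868.0], family: gamma}
  - {name: los_icu_death,             mean: 2.4,     ci: [2.3, 2.5],      family: gamma}
  - {name: cost_nonicu_survivor,      mean: 12823.0, ci: [10123.0, 15523.0], family: gamma}
  - {name: cost_nonicu_death,         mean: 3835.0,  ci: [3045.0, 4625.0], family: gamma}
  - {name: p_survival_discharge_als,  mean: 0.09,    ci: [0.08, 0.10],    family: beta}
  - {name: p_cpc12,                   mean: 0.85,    ci: [0.826, 0.871],  family: beta}
  - {name: p_5yr_cpc12,               mean: 0.740,   ci: [0.709, 0.768],  family: beta}
  - {name: p_5yr_cpc34,               mean: 0.408,   ci: [0.332, 0.489],  family: beta}
  - {name: py_death_cpc12,            mean: 1.827,   ci: [1.750, 1.878],  family: gamma}
  - {name: py_death_cpc34,            mean: 0.313,   ci: [0.254, 0.375],  family: gamma}
  - {name: utility_cpc12,             mean: 0.75,    ci: [0.70, 0.80],    family: beta}
  - {name: utility_cpc34,             mean: 0.47,    ci: [0.42, 0.52],    family: beta}
  - {name: annual_cost_cpc12,         mean: 3358.0,  family: fixed}
  - {name: annual_cost_cpc34,         mean: 43670.0, family: fixed}
  - {name: discount_rate,             mean: 0.035,   family: fixed}
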