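# Default synthetic-registry scenario.
#
# Stratum mix mirrors a realistic national SMI register (24.4%
# schizophrenia, 14.1% bipolar, 61.5% major depression); onset ages follow
# a truncated log-normal with median 38 on [18, 94]; diagnosis years span
# 1981-2019 so the 2000 study start sees both prevalent and incident cases.
# Hazards rise after age 60 and the natural-cause hazard declines over
# calendar time while the unnatural hazard stays flat, the qualitative
# pattern the trend analysis is designed to detect.
n_individuals: 20000
seed: 2000
sex_mix: {male: 0.5, female: 0.5}
smi_mix: {schizophrenia: 0.244, bipolar: 0.141, depression: 0.615}
onset: {kind: lognormal, median: 38.0, sigma: 0.45}
diagnosis_years: {start: 1981, end: 2019}
hazards:
  default:
    ages: [0.0, 60.0, 80.0]
    natural: [0.012, 0.045, 0.12]
    unnatural: [0.006, 0.003, 0.003]
calendar_effects:
  - {from_year: 2005, natural: 0.9, unnatural: 1.0}
  - {from_year: 2010, natural: 0.8, unnatural: 1.0}
  - {from_year: 2015, natural: 0.7, unnatural: 1.0}
prob_prior_less_severe: 0.15
n_non_smi: 500
study_start_year: 2000
study_end_year: 2019
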