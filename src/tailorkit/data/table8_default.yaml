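# Baseline-cohort generator defaults, calibrated to the published
# participant characteristics of the evaluated cohort (n = 92).
n: 92
seed: 0
age_mean: 56
age_sd: 10
age_min: 34
age_max: 74
bmi_mean: 26.60
bmi_sd: 5.11
married_rate: 0.796
p_meet_aerobic: 0.235
p_meet_resistance: 0.1531
resistance_threshold: 6
disability_dist: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}
change_dist: {1: 0.30, 2: 0.20, 3: 0.50}
missingness: {}
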