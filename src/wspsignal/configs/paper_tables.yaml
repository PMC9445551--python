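# Full characterisation grid: three cohort sizes, three background AE
# rates, four ADR fractions (of the background rate), three ADR timing
# means and three timing SDs, all on the unit observation period.
# Cells whose appended ADR count falls outside [11, 300] are excluded
# by the runner as unrealistic for signal detection.
n_subjects: [2500, 5000, 10000]
background_rate: [0.01, 0.05, 0.10]
adr_fraction: [0.10, 0.20, 0.50, 1.00]
adr_time_mean: [0.25, 0.50, 0.75]
adr_time_sd: [0.05, 0.10, 0.50]
n_replicates: 1000
seed: 20220823
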