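# Named simulation presets and the default data-generating constants.
#
# Instrument strength is expressed through `calibrate_main_f`: the target
# Monte-Carlo mean of the first-stage F statistic to which the per-variant
# main effects are rescaled (on the interaction-free template) before any
# interaction terms or linkage disequilibrium are applied.  Correlated-variant
# presets state the target mean pairwise genotype r-squared; the latent
# equicorrelation is derived from it in closed form.
#
# Shared defaults (independent designs): n=5000, K=3, maf=0.3, causal effect
# beta=+0.2, confounder loadings +1 on the risk factor and -1 on the outcome
# (negative confounding), unit-SD normal confounder and residual noise.
# Correlated designs imply allele frequency 0.5 (latent sign threshold).

defaults:
  n: 5000
  maf: 0.3
  beta: 0.2
  conf_x: 1.0
  conf_y: -1.0
  sd_ex: 1.0
  sd_ey: 1.0
  sd_u: 1.0

table1_row1: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [0.0, 0.0, 0.0]}
table1_row2: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [0.08, 0.10, 0.12]}
table1_row3: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [-0.08, 0.10, 0.12]}
table1_row4: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [0.08, -0.10, 0.12]}
table1_row5: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [0.08, 0.10, -0.12]}
table1_row6: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [-0.08, -0.10, 0.12]}
table1_row7: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [-0.08, 0.10, -0.12]}
table1_row8: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [0.08, -0.10, -0.12]}
table1_row9: {design: independent, k: 3, calibrate_main_f: 47.3, alpha_int: [-0.08, -0.10, -0.12]}

table2_r2_0: {design: correlated, k: 3, calibrate_main_f: 42.6, target_r2: 0.0}
table2_r2_006: {design: correlated, k: 3, calibrate_main_f: 42.6, target_r2: 0.06}
table2_r2_013: {design: correlated, k: 3, calibrate_main_f: 42.6, target_r2: 0.13}
table2_r2_026: {design: correlated, k: 3, calibrate_main_f: 42.6, target_r2: 0.26}
table2_r2_041: {design: correlated, k: 3, calibrate_main_f: 42.6, target_r2: 0.41}

weak20: {design: independent, k: 20, calibrate_main_f: 10.5, alpha_int: [0.0, 0.0, 0.0]}
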