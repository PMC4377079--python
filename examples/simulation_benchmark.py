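"""Monte-Carlo benchmark of the estimators under a named preset.

Builds the base independent-variant preset (per-variant effects calibrated
so the mean first-stage F is ~47), runs a modest number of replicates, and
prints the performance table: bias, spread, CI coverage and power.
At 10,000 replicates the coverage pattern is: 2SLS ~95%, likelihood ~94%,
IVW ~93% (slightly anti-conservative); here a smaller run shows the same
picture with wider Monte-Carlo error.
"""

from mrsummary import build_preset, results_table, run_scenario

sc = build_preset("table1_row1", calibration_seed=1)
print(f"calibrated per-variant effect: {sc.alpha_main[0]:.3f}")

res = run_scenario(sc, methods=("tsls", "ivw", "mle"), reps=500, seed=1)
cols = ["method", "mean", "median", "sd", "mean_se", "coverage", "power",
        "mean_f", "mc_se_mean"]
print(results_table(res)[cols].round(3).to_string(index=False))

print("\nTrue effect is +0.2: 'mean' near 0.2 means little bias; 'coverage' "
      "near 95 means the CIs are honest; IVW's mean_se below its sd is why "
      "its coverage dips below nominal.")
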