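"""Individual-level versus summarized-data analysis of one simulated cohort.

Simulates 5,000 people under the base independent-variant design (three SNPs,
true causal effect +0.2, negative confounding), then compares the estimators
that need the raw data (2SLS, LIML, observational OLS) with the summary-data
estimators applied to the per-variant regression coefficients alone.
"""

from mrsummary import (
    IndependentScenario,
    f_statistic,
    gen_independent,
    ivw_estimate,
    liml,
    mle_estimate,
    ols_observational,
    summarize,
    tsls,
)

sc = IndependentScenario(seed=42)  # true causal effect +0.2
d = gen_independent(sc)
print(f"simulated n={d.n}, K={d.k}; first-stage F = {f_statistic(d):.1f} "
      "(well above 10: strong instruments)")

s = summarize(d)  # per-variant OLS summaries + sample X-Y correlation
print(f"summary rho (sample corr of X and Y): {s.rho:.2f}")


def show(name, est):
    print(f"  {name:<22} {est.beta:6.3f}  (95% CI {est.ci_low:6.3f} to {est.ci_high:6.3f})")


print("\nindividual-level data:")
show("2SLS", tsls(d))
show("LIML", liml(d))
show("OLS (observational)", ols_observational(d))
print("summarized data only:")
show("IVW", ivw_estimate(s))
show("likelihood-based", mle_estimate(s))

print(f"\nTrue effect: +{sc.beta}.  The IV estimators agree with each other "
      "and their 95% CIs all include the truth, while the confounded OLS "
      "slope is wildly off (the simulated confounder pushes it negative) — "
      "the whole point of using genetic instruments.")
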