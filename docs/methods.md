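# Methods notes

## Model and assumptions

All estimators target the causal effect β of a risk factor X on an outcome
Y, assuming every genetic variant used is a valid instrumental variable
(associated with X; independent of confounders; affecting Y only through X)
and that all relationships are linear with homogeneous effects.  Summary
inputs are per-allele association estimates with known standard errors; for
binary outcomes the outcome association is a log odds (or log risk) change
and β is a log odds (risk) ratio.

The **IVW estimator** is computed in the algebraic weighted-average form
β̂ = ΣX̂ₖŶₖσ_Yk⁻² / ΣX̂ₖ²σ_Yk⁻², which is identical to meta-analysing the
per-variant ratio estimates with inverse-variance weights built from the
leading delta-method SE, but never divides by X̂ₖ, so a variant with a null
risk-factor association contributes zero weight instead of an error.  The
ratio estimator itself uses the leading delta term σ_Yk/|X̂ₖ|; the
second-order term (adding Ŷₖ²σ_Xk²/X̂ₖ⁴) is available behind an opt-in flag
because the leading term dominates whenever the risk-factor association is
much better estimated than the outcome association, and the leading-term
convention is what the IVW weights are defined by.

The **likelihood-based estimator** maximizes the bivariate normal
likelihood over (β, ξ₁..ξ_K) jointly.  Numerics: analytic gradient,
BFGS started at β = IVW and ξₖ = X̂ₖ, gradient tolerance 1e-8, with a
Nelder–Mead restart if quasi-Newton stalls; failure to converge raises an
error carrying the optimizer diagnostics rather than returning a value.
The SE is taken from the observed information of the full parameter vector:
the Hessian is an arrowhead matrix (ξ's don't interact), so the (β,β)
element of its inverse has the closed form 1/(H_ββ − Σₖ H_βξₖ²/H_ξₖξₖ).
Whether to use observed information or profile likelihood was genuinely
open; observed information was chosen because the reported intervals are
symmetric Wald intervals anyway.  All 95% intervals use the normal critical
value 1.96 — SEs are treated as known throughout, so no t correction or
residual degrees-of-freedom adjustment is applied (this also keeps the
summary and individual-level modules consistent; at the benchmark n = 5000
the difference is invisible).

ρ, the correlation between the paired association estimates, defaults to 0
(two-sample designs); when summaries are computed from one sample,
`summarize` plugs in the sample X–Y correlation, and `rho_sensitivity`
provides the recommended grid analysis.  The estimators deliberately apply
no correction for correlated (LD) variants — that misuse is documented and
its consequences are demonstrated by the simulation engine instead.

**2SLS** uses an additive-in-variants first stage with intercept, and the
standard IV variance estimator (second-stage residuals recomputed at the
observed risk factor).  **LIML** is the k-class estimator with κ the
smallest eigenvalue of (W′M_Z W)⁻¹(W′M₁W), W = [y, x]; it equals 2SLS when
just-identified and is markedly less median-biased with many weak
instruments.

## Synthetic-data designs and their defaults

The generator reproduces the benchmark study conditions: n = 5000
individuals, three biallelic SNPs, true causal effect +0.2, and an
unmeasured standard-normal confounder loading +1 on X and −1 on Y (negative
confounding, so the observational OLS slope is pushed far below the causal
effect — it lands near −0.29 under the defaults).  Residual noise on X and
Y is standard normal.  For independent variants, genotypes are
Binomial(2, MAF) under Hardy–Weinberg with MAF 0.3, and X may include the
three pairwise gene–gene interaction terms.  For correlated variants, two
latent equicorrelated normal vectors per individual act as haplotypes; an
allele is recorded where a component is positive (allele frequency 1/2),
giving pairwise genotype correlation 2·arcsin(θ)/π, inverted in closed form
by `calibrate_theta` so a target mean pairwise genotype r² can be dialled
in exactly.

The per-variant main effects on X were never published as numbers; the
printed, checkable summary of instrument strength is the mean first-stage F
statistic.  `calibrate_strength` therefore rescales the main effects by a
Monte-Carlo search (common random numbers, (F−1) ∝ effect², relative
tolerance 2%) to hit a target mean F: 47.3 for the base design, 42.6 for
the LD-free analogue of the correlated design, and "just above 10"
(default 10.5) for the 20-variant weak-instrument design.  The calibrated
base-design effect is ≈0.21 per allele, explaining ≈2.7% of the variance of
X.  All named presets live in `presets.yaml`.

Replicate r of a Monte-Carlo run uses an RNG seeded by `[master_seed, r]`,
so results are bit-reproducible and order-independent; estimator failures
within a run are counted and reported, never silently dropped.

What passing these simulations does **not** show about real data: the
designs have no pleiotropy, no population stratification, no selection
(winner's curse), exact linearity and effect homogeneity, and
equicorrelated LD only — they probe the estimators' statistical behaviour
under the stated violations (interactions, LD, weak instruments), not the
validity of the IV assumptions in any application.

### A note on the LD benchmark

With the latent equicorrelation calibrated so the mean pairwise *squared*
genotype correlation is 0.41 (genotype correlation ≈0.64), the mean F rises
from 42.6 to ≈93 and IVW coverage falls to ≈77%.  The reference pattern
this benchmark mirrors shows a milder F increase (to ≈75) and IVW coverage
≈82% at the same nominal r², consistent with a realized genotype
correlation numerically close to the quoted r² itself; the discrepancy is a
labelling/calibration ambiguity in the target, not in the estimators.  The
qualitative conclusion is identical and robustly reproduced: summary-data
coverage collapses monotonically as LD grows while 2SLS stays nominal.

## Hierarchical model

Eq-level structure: (X̂ₖₘ, Ŷₖₘ) bivariate normal about (ξₖₘ, βₘξₖₘ) with
known SEs and per-study correlation ρₘ; ξₖₘ ~ N(μₖ, τ_ξ²);
βₘ ~ N(β, τ²).  Priors: N(0, 10²) on β and each μₖ, half-normal(1) on τ and
τ_ξ.  `fixed_effect=True` sets both heterogeneity SDs to zero (shared β and
shared per-variant ξ), which makes a single-study fit collapse exactly to
the summary-data MLE model — a property the tests exploit.  Missing
(variant, study) cells contribute no likelihood term; the random-effects
distributions act as implicit priors for their parameters.

Sampling is Metropolis-within-Gibbs: every location parameter has a
conjugate normal full conditional (sampled exactly, vectorized over cells),
and the two heterogeneity SDs take log-scale random-walk Metropolis steps
(step 0.5).  At least two chains are required; convergence is flagged via
split-R̂ < 1.05 on every stored parameter, with effective sample sizes from
Geyer's initial positive sequence.  Defaults (2 chains × 2000 iterations,
half burn-in) suit quick exploration; the examples use 4000–8000 iterations
because τ and τ_ξ mix slowly when the number of studies is small — with
M = 5 studies the heterogeneity SDs are only weakly identified and their
posteriors lean on the prior, which is expected behaviour for hierarchical
meta-analysis, not a defect.

## Problem sizes used in the checks

The packaged acceptance run uses 2000 replicates for the base and LD
scenarios and 2500 for the weak-instrument scenario (Monte-Carlo SE ≈0.5
percentage points on a 95% coverage, ≈0.002 on a mean estimate), with
calibration on 300 replicates; the test suite uses 250–2000 replicates per
scenario and 50 synthetic datasets for the hierarchical recovery check.
These sizes make the whole suite run in a few minutes while keeping every
comparison inside ~3 Monte-Carlo SEs.

## Known limitations

* No heterogeneity/random-effects IVW, median, or pleiotropy-robust
  estimators, and no correction for correlated variants — out of scope.
* Individual-level estimation supports continuous outcomes only (summary
  inputs may still be log odds ratios from external logistic fits).
* The OR transform takes the contrast Δx explicitly (e.g. `--or-delta=-0.3`
  for a 30% reduction when the risk-factor associations are on a
  proportional scale); it does not guess unit conventions.
* The equicorrelated LD design cannot represent realistic block structure;
  `calibrate_theta` assumes θ ≥ 0.
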