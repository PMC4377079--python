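"""Monte-Carlo simulation designs for benchmarking the estimators.

Three data-generating designs are provided:

* **Independent variants** (:class:`IndependentScenario`): K SNPs drawn
  binomially under Hardy–Weinberg equilibrium, a risk factor built from
  additive per-allele effects plus optional pairwise gene–gene interaction
  terms, and an outcome depending linearly on the risk factor with an
  unmeasured confounder loading on both with opposite signs (negative
  confounding)::

      x = sum_k alpha_k g_k + a12 g1 g2 + a13 g1 g3 + a23 g2 g3
          + conf_x * u + eps_x
      y = beta * x + conf_y * u + eps_y

* **Correlated variants** (:class:`CorrelatedScenario`): genotypes built
  from two latent haplotype draws per individual taken from a zero-mean
  equicorrelated multivariate normal; an allele is recorded on a haplotype
  wherever the latent component is positive, so each variant has allele
  frequency 1/2 and the latent equicorrelation ``theta`` controls the
  pairwise genotype correlation (linkage disequilibrium).  The risk factor
  and outcome are built as above, without interactions.

* **Weak instruments** (:func:`weak_scenario`): an independent-variant
  scenario with many equal, small per-variant effects, calibrated so the
  first-stage mean F statistic sits at a chosen level.

Because the per-variant effect sizes are stated only through the resulting
mean F statistics, :func:`calibrate_strength` rescales the main effects by
Monte Carlo until the mean F matches a target, and :func:`calibrate_theta`
maps a target mean pairwise genotype r² to the latent equicorrelation in
closed form.  :func:`run_scenario` repeats a scenario, applies the requested
estimators, and reports the usual Monte-Carlo performance metrics (mean,
median, SD, mean SE, coverage, power, mean F) with Monte-Carlo standard
errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import IndividualData
from .estimators import ConvergenceError, ivw_estimate, mle_estimate
from .individual import f_statistic, liml, ols_observational, summarize, tsls

__all__ = [
    "IndependentScenario",
    "CorrelatedScenario",
    "ScenarioResult",
    "gen_independent",
    "gen_correlated",
    "calibrate_theta",
    "calibrate_strength",
    "weak_scenario",
    "run_scenario",
    "results_table",
]


@dataclass(frozen=True)
class IndependentScenario:
    """Independent-variant design with optional pairwise interactions.

    Defaults follow the benchmark set-up: 5,000 participants, three SNPs of
    minor allele frequency 0.3, causal effect +0.2, a standard-normal
    confounder loading +1 on the risk factor and -1 on the outcome, and
    standard-normal residual noise.  ``alpha_int`` gives the pairwise
    interaction coefficients (g1g2, g1g3, g2g3) and requires K = 3.
    """

    n: int = 5000
    k: int = 3
    maf: float = 0.3
    alpha_main: tuple[float, ...] = (0.2124, 0.2124, 0.2124)
    alpha_int: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beta: float = 0.2
    conf_x: float = 1.0
    conf_y: float = -1.0
    sd_ex: float = 1.0
    sd_ey: float = 1.0
    sd_u: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.maf < 0.5:
            raise ValueError(f"maf must be in (0, 0.5), got {self.maf}")
        if self.n < 10 or self.k < 1:
            raise ValueError("need n >= 10 and K >= 1")
        if len(self.alpha_main) != self.k:
            raise ValueError("alpha_main must have one entry per variant")
        if any(a != 0 for a in self.alpha_int) and self.k != 3:
            raise ValueError("pairwise interactions are defined for K = 3 only")
        if self.conf_x * self.conf_y > 0:
            raise ValueError("confounder loadings must not share a sign "
                             "(negative or absent confounding only)")


@dataclass(frozen=True)
class CorrelatedScenario:
    """Correlated-variant (linkage disequilibrium) design.

    ``theta`` is the equicorrelation of the latent K-dimensional normal from
    which the two haplotypes are drawn; the implied mean pairwise genotype
    correlation is ``2 arcsin(theta) / pi`` (allele frequency 1/2 follows
    from thresholding the zero-mean latent draws at zero).
    """

    n: int = 5000
    k: int = 3
    theta: float = 0.0
    alpha_main: tuple[float, ...] = (0.19, 0.19, 0.19)
    beta: float = 0.2
    conf_x: float = 1.0
    conf_y: float = -1.0
    sd_ex: float = 1.0
    sd_ey: float = 1.0
    sd_u: float = 1.0
    seed: int | None = None

    # interactions are absent by design in the correlated study
    alpha_int: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0), init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.theta < 1:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if self.k < 2:
            raise ValueError("correlated design needs K >= 2")
        if len(self.alpha_main) != self.k:
            raise ValueError("alpha_main must have one entry per variant")
        if self.conf_x * self.conf_y > 0:
            raise ValueError("confounder loadings must not share a sign "
                             "(negative or absent confounding only)")


@dataclass(frozen=True)
class ScenarioResult:
    """Monte-Carlo performance summary for one scenario × estimator."""

    method: str
    mean: float
    median: float
    sd: float
    mean_se: float
    coverage: float  # % of 95% CIs containing the true effect
    power: float  # % of 95% CIs excluding zero
    mean_f: float
    reps: int
    n_failed: int
    mc_se_mean: float
    mc_se_coverage: float


def _build_xy(sc, g: np.ndarray, rng: np.random.Generator) -> IndividualData:
    n = sc.n
    u = sc.sd_u * rng.standard_normal(n)
    x = g @ np.asarray(sc.alpha_main, dtype=float)
    a12, a13, a23 = sc.alpha_int
    if a12 or a13 or a23:
        x = x + a12 * g[:, 0] * g[:, 1] + a13 * g[:, 0] * g[:, 2] + a23 * g[:, 1] * g[:, 2]
    x = x + sc.conf_x * u + sc.sd_ex * rng.standard_normal(n)
    y = sc.beta * x + sc.conf_y * u + sc.sd_ey * rng.standard_normal(n)
    return IndividualData(genotypes=g, x=x, y=y, u=u)


def gen_independent(
    sc: IndependentScenario, rng: np.random.Generator | None = None
) -> IndividualData:
    """Draw one dataset under the independent-variant design."""
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    g = rng.binomial(2, sc.maf, size=(sc.n, sc.k)).astype(float)
    return _build_xy(sc, g, rng)


def gen_correlated(
    sc: CorrelatedScenario, rng: np.random.Generator | None = None
) -> IndividualData:
    """Draw one dataset under the correlated-variant (LD) design.

    Two latent equicorrelated normal vectors are drawn per individual (the
    haplotypes); each positive component records one variant allele, and the
    genotype is the sum over the two haplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    # Equicorrelated normals via a single common factor (valid for theta >= 0).
    sq_c, sq_e = np.sqrt(sc.theta), np.sqrt(1.0 - sc.theta)
    g = np.zeros((sc.n, sc.k))
    for _ in range(2):  # two haplotype draws
        common = rng.standard_normal(sc.n)
        latent = sq_c * common[:, None] + sq_e * rng.standard_normal((sc.n, sc.k))
        g += latent > 0
    return _build_xy(sc, g, rng)


def calibrate_theta(target_r2: float) -> float:
    """Latent equicorrelation giving a target mean pairwise genotype r².

    For zero-mean bivariate normal components with correlation theta, the
    allele indicators have correlation ``2 arcsin(theta) / pi`` (the
    tetrachoric/orthant relation), which the genotype sums inherit; so the
    target squared correlation inverts in closed form:
    ``theta = sin(pi * sqrt(target_r2) / 2)``.
    """
    if not 0 <= target_r2 < 1:
        raise ValueError(f"target r2 must be in [0, 1), got {target_r2}")
    return float(np.sin(np.pi * np.sqrt(target_r2) / 2.0))


def _mean_f(sc, reps: int, cal_seed: int) -> float:
    gen = gen_correlated if isinstance(sc, CorrelatedScenario) else gen_independent
    fs = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng([cal_seed, r])
        fs[r] = f_statistic(gen(sc, rng))
    return float(fs.mean())


def _scale_main(sc, scale: float):
    return dataclasses.replace(
        sc, alpha_main=tuple(scale * a for a in sc.alpha_main)
    )


def calibrate_strength(
    sc,
    target_mean_f: float,
    reps: int = 200,
    seed: int = 0,
    tol: float = 0.02,
    max_iter: int = 12,
):
    """Rescale the main per-variant effects so the mean F hits a target.

    Monte-Carlo search with common random numbers: the mean first-stage F is
    evaluated on the same ``reps`` seeded datasets at every candidate scale,
    making the objective a smooth increasing function of the scale, and the
    scale is updated via the approximate proportionality of (F - 1) to the
    squared effect size.  Converges to within ``tol`` (relative) of the
    target; raises if it cannot.
    """
    if not target_mean_f > 1:
        raise ValueError("target mean F must exceed 1")
    scale = 1.0
    for _ in range(max_iter):
        f = _mean_f(_scale_main(sc, scale), reps, seed)
        if abs(f - target_mean_f) <= tol * target_mean_f:
            return _scale_main(sc, scale)
        if f <= 1.0:
            scale *= 4.0
            continue
        scale *= np.sqrt((target_mean_f - 1.0) / (f - 1.0))
    raise RuntimeError(
        f"effect-size calibration did not converge to mean F {target_mean_f} "
        f"(last mean F {f:.2f})"
    )


def weak_scenario(
    n: int = 5000,
    k: int = 20,
    target_mean_f: float = 10.5,
    calibration_reps: int = 200,
    calibration_seed: int = 0,
) -> IndependentScenario:
    """Many-weak-instrument scenario: K equal-effect variants, no interactions.

    Per-variant effects are calibrated so the first-stage mean F statistic
    matches ``target_mean_f``; with independent equal-strength variants the
    univariate expected F per variant approximately equals the joint F.
    """
    if k < 1:
        raise ValueError("need K >= 1")
    template = IndependentScenario(n=n, k=k, alpha_main=(0.1,) * k,
                                   alpha_int=(0.0, 0.0, 0.0))
    return calibrate_strength(template, target_mean_f,
                              reps=calibration_reps, seed=calibration_seed)


_METHODS: dict[str, Callable[[IndividualData, object], object]] = {
    "tsls": lambda d, s: tsls(d),
    "liml": lambda d, s: liml(d),
    "ols": lambda d, s: ols_observational(d),
    "ivw": lambda d, s: ivw_estimate(s),
    "mle": lambda d, s: mle_estimate(s),
}


def run_scenario(
    sc,
    methods: Sequence[str] = ("tsls", "ivw", "mle"),
    reps: int = 1000,
    seed: int = 0,
) -> list[ScenarioResult]:
    """Monte-Carlo evaluation of estimators under one scenario.

    Each replicate draws a fresh dataset (replicate r uses an RNG seeded by
    ``[seed, r]``, so runs are reproducible and trivially parallelizable),
    summarizes it for the summary-data methods (with rho set to the sample
    X–Y correlation), applies every requested estimator, and accumulates
    mean/median/SD of the estimates, the mean reported SE, 95% CI coverage
    of the true effect, power against zero, and the first-stage mean F.
    Estimator failures are counted per method, never silently dropped.
    """
    unknown = [m for m in methods if m not in _METHODS]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; choose from {sorted(_METHODS)}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    gen = gen_correlated if isinstance(sc, CorrelatedScenario) else gen_independent
    need_summary = any(m in ("ivw", "mle") for m in methods)

    est = {m: [] for m in methods}
    fail = {m: 0 for m in methods}
    fs = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        d = gen(sc, rng)
        fs[r] = f_statistic(d)
        s = summarize(d) if need_summary else None
        for m in methods:
            try:
                est[m].append(_METHODS[m](d, s))
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                fail[m] += 1

    mean_f = float(fs.mean())
    out = []
    for m in methods:
        b = np.array([e.beta for e in est[m]])
        se = np.array([e.se for e in est[m]])
        lo = np.array([e.ci_low for e in est[m]])
        hi = np.array([e.ci_high for e in est[m]])
        nr = len(b)
        cov = float(np.mean((lo <= sc.beta) & (sc.beta <= hi)) * 100)
        pw = float(np.mean((lo > 0) | (hi < 0)) * 100)
        c = cov / 100
        out.append(ScenarioResult(
            method=m,
            mean=float(b.mean()),
            median=float(np.median(b)),
            sd=float(b.std(ddof=1)) if nr > 1 else 0.0,
            mean_se=float(se.mean()),
            coverage=cov,
            power=pw,
            mean_f=mean_f,
            reps=nr,
            n_failed=fail[m],
            mc_se_mean=float(b.std(ddof=1) / np.sqrt(nr)) if nr > 1 else float("nan"),
            mc_se_coverage=float(np.sqrt(c * (1 - c) / nr)),
        ))
    return out


def results_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Stack ScenarioResults into a table mirroring the usual report layout."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
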