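"""Hierarchical (multi-study) model for summarized genetic associations.

When study-level summary statistics are available from several studies, the
bivariate-normal summary likelihood extends naturally to a Bayesian
hierarchical model.  For variant k in study m, the observed associations
(X_km with the risk factor, Y_km with the outcome) are modelled as

    (X_km, Y_km) ~ BVN( (xi_km, beta_m * xi_km),
                        SEs known, within-study correlation rho_m )
    xi_km  ~ N(mu_k, tau_xi^2)      # variant effects vary across studies
    beta_m ~ N(beta, tau^2)         # study causal effects vary around beta

with the overall causal effect beta as the target of inference.  Setting
``fixed_effect=True`` collapses both random-effects distributions
(tau = tau_xi = 0), so all studies share one causal effect and one true
association per variant.  Missing (variant, study) cells simply contribute
no likelihood term; the random-effects distribution acts as an implicit
prior for the unobserved parameters.

Priors are weakly informative by default: Normal(0, 10^2) on beta and each
mu_k, half-normal(1) on the heterogeneity SDs tau and tau_xi.

Sampling is by Metropolis-within-Gibbs: every location parameter has a
conjugate normal full conditional (sampled exactly, vectorized), while the
two heterogeneity SDs use random-walk Metropolis steps on the log scale.
Convergence is assessed by the split potential-scale-reduction statistic
(R-hat) over at least two chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MultiStudySummary",
    "PriorSpec",
    "HierarchicalFit",
    "hierarchical_fit",
    "gen_multistudy",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class MultiStudySummary:
    """Long-format multi-study summarized associations.

    ``table`` has one row per observed (study, variant) cell with columns
    ``study, variant, beta_x, se_x, beta_y, se_y``; missing cells are simply
    absent.  ``rho`` maps each study to the within-study correlation between
    its paired association estimates (0 for two-sample studies, the
    default).
    """

    table: pd.DataFrame
    rho: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["study", "variant", "beta_x", "se_x", "beta_y", "se_y"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"multi-study table missing column(s) {missing}")
        t = self.table.reset_index(drop=True)
        if len(t) == 0:
            raise ValueError("need at least one (study, variant) cell")
        if t.duplicated(["study", "variant"]).any():
            raise ValueError("duplicate (study, variant) cells")
        for c in ("se_x", "se_y"):
            if not (t[c] > 0).all():
                raise ValueError(f"all {c} must be > 0")
        for r in self.rho.values():
            if not abs(r) < 1:
                raise ValueError("per-study rho must satisfy |rho| < 1")
        object.__setattr__(self, "table", t)

    @property
    def studies(self) -> list:
        return list(pd.unique(self.table["study"]))

    @property
    def variants(self) -> list:
        return list(pd.unique(self.table["variant"]))


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative default priors for the hierarchical model."""

    beta_scale: float = 10.0  # Normal(0, scale^2) on the overall effect
    mu_scale: float = 10.0  # Normal(0, scale^2) on each variant mean
    tau_scale: float = 1.0  # half-normal scale on the causal-effect SD tau
    tau_xi_scale: float = 1.0  # half-normal scale on the association SD tau_xi


@dataclass
class HierarchicalFit:
    """Posterior summaries and sampler diagnostics."""

    summary: pd.DataFrame  # index: parameter; mean, sd, q2.5, q97.5
    beta_draws: np.ndarray  # (chains, draws) retained posterior draws of beta
    rhat: dict
    ess: dict
    chains: int
    draws_per_chain: int
    fixed_effect: bool
    converged: bool

    @property
    def beta_mean(self) -> float:
        return float(self.summary.loc["beta", "mean"])

    @property
    def beta_sd(self) -> float:
        return float(self.summary.loc["beta", "sd"])

    @property
    def beta_interval(self) -> tuple[float, float]:
        return (float(self.summary.loc["beta", "q2.5"]),
                float(self.summary.loc["beta", "q97.5"]))


def _split_rhat(draws: np.ndarray) -> float:
    """Split potential-scale-reduction statistic over (chains, draws)."""
    c, n = draws.shape
    half = n // 2
    seqs = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    m, n2 = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def _ess(draws: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    c, n = draws.shape
    acov = np.zeros(n)
    for ch in range(c):
        x = draws[ch] - draws[ch].mean()
        f = np.fft.rfft(x, 2 * n)
        acov += np.fft.irfft(f * np.conj(f))[:n] / n
    acov /= c
    if acov[0] <= 0:
        return float(c * n)
    rho = acov / acov[0]
    s, t = 0.0, 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        s += pair
        t += 2
    return float(c * n / (1.0 + 2.0 * s))


def _normal_draw(rng, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sample N(b/a, 1/a) elementwise from natural parameters."""
    return b / a + rng.standard_normal(np.shape(a)) / np.sqrt(a)


def hierarchical_fit(
    data: MultiStudySummary,
    priors: PriorSpec | None = None,
    fixed_effect: bool = False,
    chains: int = 2,
    iterations: int = 2000,
    burn: int | None = None,
    seed: int = 0,
) -> HierarchicalFit:
    """Fit the hierarchical multi-study model by MCMC.

    Parameters
    ----------
    data : MultiStudySummary
        Observed study-level summarized associations.
    priors : PriorSpec, optional
        Prior scales; weakly informative defaults.
    fixed_effect : bool
        If True, set tau = tau_xi = 0: one causal effect shared by all
        studies and one true association per variant.
    chains, iterations, burn, seed
        Sampler controls; ``burn`` defaults to ``iterations // 2`` and at
        least two chains are required for the convergence diagnostic.
    """
    if priors is None:
        priors = PriorSpec()
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence assessment")
    if iterations < 1000:
        raise ValueError("need at least 1000 iterations per chain")
    if burn is None:
        burn = iterations // 2

    t = data.table
    studies = data.studies
    variants = data.variants
    m_idx = t["study"].map({s: i for i, s in enumerate(studies)}).to_numpy()
    k_idx = t["variant"].map({v: i for i, v in enumerate(variants)}).to_numpy()
    nm, nk, nc = len(studies), len(variants), len(t)
    x = t["beta_x"].to_numpy(float)
    y = t["beta_y"].to_numpy(float)
    sx = t["se_x"].to_numpy(float)
    sy = t["se_y"].to_numpy(float)
    rho = np.array([float(data.rho.get(s, 0.0)) for s in studies])[m_idx]
    w = 1.0 / (1.0 - rho**2)

    # constant pieces of the cell-level quadratic forms
    c_xx = w / sx**2
    c_xy = w * rho / (sx * sy)
    c_yy = w / sy**2

    names = (["beta", "tau", "tau_xi"]
             + [f"beta_m[{s}]" for s in studies]
             + [f"mu_k[{v}]" for v in variants])
    kept = iterations - burn
    store = {nm_: np.empty((chains, kept)) for nm_ in names}

    for ch in range(chains):
        rng = np.random.default_rng([seed, ch])
        # crude but serviceable initial values from per-cell ratios
        xi = x.copy()
        ratio0 = np.nanmedian(y / np.where(x == 0, np.nan, x))
        beta = float(ratio0) if np.isfinite(ratio0) else 0.0
        beta_m = np.full(nm, beta)
        mu = np.array([x[k_idx == j].mean() for j in range(nk)])
        tau = 0.1 if not fixed_effect else 0.0
        tau_xi = 0.1 if not fixed_effect else 0.0
        step_t = step_tx = 0.5

        for it in range(iterations):
            bm_cell = beta_m[m_idx] if not fixed_effect else np.full(nc, beta)
            if fixed_effect:
                # mu_k enters the bivariate likelihood directly (xi = mu_k)
                a_cell = c_xx - 2.0 * bm_cell * c_xy + bm_cell**2 * c_yy
                b_cell = x * c_xx - (bm_cell * x + y) * c_xy + bm_cell * y * c_yy
                a_k = np.bincount(k_idx, a_cell, nk) + priors.mu_scale**-2
                b_k = np.bincount(k_idx, b_cell, nk)
                mu = _normal_draw(rng, a_k, b_k)
                xi = mu[k_idx]
                # shared beta from all cells
                a_b = float(np.sum(c_yy * xi**2)) + priors.beta_scale**-2
                b_b = float(np.sum(xi * (y * c_yy - (x - xi) * c_xy)))
                beta = float(_normal_draw(rng, np.array(a_b), np.array(b_b)))
                beta_m = np.full(nm, beta)
            else:
                # xi_km | rest
                a_cell = (c_xx - 2.0 * bm_cell * c_xy + bm_cell**2 * c_yy
                          + tau_xi**-2)
                b_cell = (x * c_xx - (bm_cell * x + y) * c_xy
                          + bm_cell * y * c_yy + mu[k_idx] * tau_xi**-2)
                xi = _normal_draw(rng, a_cell, b_cell)
                # beta_m | rest
                a_m = np.bincount(m_idx, c_yy * xi**2, nm) + tau**-2
                b_m = np.bincount(m_idx, xi * (y * c_yy - (x - xi) * c_xy), nm) \
                    + beta * tau**-2
                beta_m = _normal_draw(rng, a_m, b_m)
                # mu_k | xi
                counts = np.bincount(k_idx, minlength=nk)
                a_k = counts * tau_xi**-2 + priors.mu_scale**-2
                b_k = np.bincount(k_idx, xi, nk) * tau_xi**-2
                mu = _normal_draw(rng, a_k, b_k)
                # beta | beta_m
                a_b = nm * tau**-2 + priors.beta_scale**-2
                b_b = beta_m.sum() * tau**-2
                beta = float(_normal_draw(rng, np.array(a_b), np.array(b_b)))
                # tau, tau_xi | residuals — log-scale random-walk Metropolis
                tau = _mh_scale(rng, tau, beta_m - beta, priors.tau_scale, step_t)
                tau_xi = _mh_scale(rng, tau_xi, xi - mu[k_idx],
                                   priors.tau_xi_scale, step_tx)

            if it >= burn:
                j = it - burn
                store["beta"][ch, j] = beta
                store["tau"][ch, j] = tau
                store["tau_xi"][ch, j] = tau_xi
                for i, s in enumerate(studies):
                    store[f"beta_m[{s}]"][ch, j] = beta_m[i]
                for i, v in enumerate(variants):
                    store[f"mu_k[{v}]"][ch, j] = mu[i]

    rows, rhats, esss = [], {}, {}
    for nm_ in names:
        d = store[nm_]
        flat = d.ravel()
        rows.append({
            "parameter": nm_, "mean": flat.mean(), "sd": flat.std(ddof=1),
            "q2.5": np.quantile(flat, 0.025), "q97.5": np.quantile(flat, 0.975),
        })
        if fixed_effect and nm_ in ("tau", "tau_xi"):
            rhats[nm_], esss[nm_] = 1.0, float(flat.size)
        else:
            rhats[nm_] = _split_rhat(d)
            esss[nm_] = _ess(d)
    summary = pd.DataFrame(rows).set_index("parameter")
    converged = all(r <= RHAT_THRESHOLD for r in rhats.values())
    return HierarchicalFit(
        summary=summary, beta_draws=store["beta"], rhat=rhats, ess=esss,
        chains=chains, draws_per_chain=kept, fixed_effect=fixed_effect,
        converged=converged,
    )


def _mh_scale(rng, cur: float, resid: np.ndarray, prior_scale: float,
              step: float) -> float:
    """One log-scale random-walk Metropolis update for a heterogeneity SD.

    Target: prod_i N(resid_i; 0, s^2) * halfnormal(s; prior_scale), sampled
    on log s (Jacobian + log s).
    """
    n = resid.size
    ss = float(resid @ resid)

    def logpost(s: float) -> float:
        return (-n * np.log(s) - ss / (2 * s**2)
                - s**2 / (2 * prior_scale**2) + np.log(s))

    prop = float(cur * np.exp(step * rng.standard_normal()))
    if np.log(rng.uniform()) < logpost(prop) - logpost(cur):
        return prop
    return cur


def gen_multistudy(
    beta: float = 0.2,
    tau: float = 0.05,
    tau_xi: float = 0.02,
    mu: np.ndarray | None = None,
    k: int = 3,
    m: int = 5,
    se_x: float = 0.02,
    se_y: float = 0.05,
    rho: float = 0.0,
    missing_prob: float = 0.0,
    seed: int = 0,
) -> MultiStudySummary:
    """Draw a synthetic multi-study summary dataset from the model itself.

    Study effects ``beta_m ~ N(beta, tau^2)``; true per-study variant
    associations ``xi_km ~ N(mu_k, tau_xi^2)``; observed estimates from the
    within-study bivariate normal with the supplied SEs and correlation.
    ``missing_prob`` drops cells at random (at least one cell per study is
    kept).
    """
    if k < 1 or m < 1:
        raise ValueError("need K >= 1 and M >= 1")
    rng = np.random.default_rng(seed)
    if mu is None:
        mu = rng.uniform(0.1, 0.4, size=k)
    mu = np.asarray(mu, float)
    beta_m = beta + tau * rng.standard_normal(m)
    rows = []
    for mi in range(m):
        keep = rng.uniform(size=k) >= missing_prob
        if not keep.any():
            keep[rng.integers(k)] = True
        for ki in range(k):
            if not keep[ki]:
                continue
            xi = mu[ki] + tau_xi * rng.standard_normal()
            z1 = rng.standard_normal()
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal()
            rows.append({
                "study": f"s{mi + 1}", "variant": f"g{ki + 1}",
                "beta_x": xi + se_x * z1, "se_x": se_x,
                "beta_y": beta_m[mi] * xi + se_y * z2, "se_y": se_y,
            })
    table = pd.DataFrame(rows)
    return MultiStudySummary(table, rho={f"s{mi + 1}": rho for mi in range(m)})
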