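"""Causal-effect estimators for summarized genetic association data.

Three estimators of the causal effect beta of a risk factor X on an outcome Y
from per-variant summary statistics:

* :func:`ratio_estimate` — single-variant Wald/ratio estimate
  ``beta_y / beta_x`` with the leading delta-method standard error
  ``se_y / |beta_x|``.
* :func:`ivw_estimate` — inverse-variance weighted fixed-effect combination
  of the per-variant ratio estimates,

  .. math::

     \\hat\\beta_{IVW} = \\frac{\\sum_k X_k Y_k \\sigma_{Yk}^{-2}}
                              {\\sum_k X_k^2 \\sigma_{Yk}^{-2}},
     \\qquad
     \\mathrm{se} = \\sqrt{\\frac{1}{\\sum_k X_k^2 \\sigma_{Yk}^{-2}}} ,

  computed in this algebraic form (identical to meta-analysing the ratio
  estimates with weights ``beta_x**2 / se_y**2``) so that a variant with
  ``beta_x == 0`` contributes zero weight rather than a division error.
* :func:`mle_estimate` — maximum likelihood under a bivariate normal model
  for each pair of association estimates,

  .. math::

     \\begin{pmatrix} X_k \\\\ Y_k \\end{pmatrix} \\sim
     N\\!\\left( \\begin{pmatrix} \\xi_k \\\\ \\beta\\,\\xi_k \\end{pmatrix},
     \\begin{pmatrix} \\sigma_{Xk}^2 & \\rho\\sigma_{Xk}\\sigma_{Yk} \\\\
     \\rho\\sigma_{Xk}\\sigma_{Yk} & \\sigma_{Yk}^2 \\end{pmatrix} \\right),

  with the SEs treated as known.  The nuisance parameters ``xi_k`` are the
  true per-allele associations with the risk factor; ``rho`` is the
  correlation between the paired estimates when both come from one sample
  (0 in a two-sample design).

All confidence intervals are Wald intervals at the normal 1.96 critical
value.  None of these estimators accounts for correlation (linkage
disequilibrium) between variants: applying them to correlated variants
overstates precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .data import (
    CausalEstimate,
    SummarySet,
    UndefinedRatioError,
    VariantAssociation,
    Z95,
)

__all__ = [
    "ratio_estimate",
    "ivw_estimate",
    "mle_estimate",
    "rho_sensitivity",
    "effect_transform",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Likelihood maximization failed; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def ratio_estimate(v: VariantAssociation, second_order: bool = False) -> CausalEstimate:
    """Single-variant ratio estimate of the causal effect.

    The point estimate is ``beta_y / beta_x``.  By default the standard error
    is the leading delta-method term ``se_y / |beta_x|``, which dominates
    whenever the genetic association with the risk factor is estimated much
    more precisely than the association with the outcome.  ``second_order``
    adds the next delta-method term, giving
    ``sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4)``.
    """
    if v.beta_x == 0:
        raise UndefinedRatioError(
            f"variant {v.label!r}: ratio estimate undefined for beta_x == 0"
        )
    beta = v.beta_y / v.beta_x
    se = v.se_y / abs(v.beta_x)
    if second_order:
        se = np.sqrt(se**2 + v.beta_y**2 * v.se_x**2 / v.beta_x**4)
    return CausalEstimate(beta=beta, se=float(se), method="ratio", k=1)


def ivw_estimate(s: SummarySet) -> CausalEstimate:
    """Inverse-variance weighted estimate combining all variants.

    A fixed-effect meta-analysis of the per-variant ratio estimates using the
    leading-term delta-method SEs.  ``s.rho`` is ignored: the method has no
    mechanism to use the correlation between paired association estimates.
    """
    bx, by, sy = s.beta_x, s.beta_y, s.se_y
    w = sy**-2.0
    denom = float(np.sum(bx**2 * w))
    if denom <= 0:
        raise ValueError("IVW undefined: all variants have beta_x == 0")
    beta = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    return CausalEstimate(beta=beta, se=se, method="ivw", k=len(s))


def _nll_terms(s: SummarySet):
    """Pre-computed constants for the bivariate-normal negative log-likelihood."""
    bx, sx, by, sy = s.beta_x, s.se_x, s.beta_y, s.se_y
    rho = s.rho
    w = 1.0 / (1.0 - rho**2)
    return bx, sx, by, sy, rho, w


def _nll(theta: np.ndarray, s: SummarySet) -> float:
    """Negative log-likelihood (dropping parameter-free constants).

    ``theta = (beta, xi_1 .. xi_K)``.
    """
    bx, sx, by, sy, rho, w = _nll_terms(s)
    beta, xi = theta[0], theta[1:]
    a = (bx - xi) / sx
    b = (by - beta * xi) / sy
    return float(0.5 * w * np.sum(a**2 - 2.0 * rho * a * b + b**2))


def _nll_grad(theta: np.ndarray, s: SummarySet) -> np.ndarray:
    bx, sx, by, sy, rho, w = _nll_terms(s)
    beta, xi = theta[0], theta[1:]
    a = bx - xi
    b = by - beta * xi
    # dQ/dbeta = -w * xi * (b/sy^2 - rho*a/(sx*sy)); dQ/dxi analogous.
    d_beta = -w * np.sum(xi * (b / sy**2 - rho * a / (sx * sy)))
    d_xi = w * (-a / sx**2 + rho * (b + beta * a) / (sx * sy) - beta * b / sy**2)
    return np.concatenate(([d_beta], d_xi))


def _beta_se_from_information(theta: np.ndarray, s: SummarySet) -> float:
    """SE of beta from the inverse observed information of the full likelihood.

    The Hessian of the negative log-likelihood in ``(beta, xi)`` is an
    arrowhead matrix (the ``xi_k`` do not interact), so the (beta, beta)
    entry of its inverse has the closed form
    ``1 / (H_bb - sum_k H_bk^2 / H_kk)``.
    """
    bx, sx, by, sy, rho, w = _nll_terms(s)
    beta, xi = theta[0], theta[1:]
    a = bx - xi
    b = by - beta * xi
    h_bb = w * np.sum(xi**2 / sy**2)
    h_kk = w * (1.0 / sx**2 - 2.0 * rho * beta / (sx * sy) + beta**2 / sy**2)
    h_bk = -w * (b / sy**2 - rho * a / (sx * sy)) + w * xi * (
        beta / sy**2 - rho / (sx * sy)
    )
    var_beta = 1.0 / (h_bb - np.sum(h_bk**2 / h_kk))
    if not (np.isfinite(var_beta) and var_beta > 0):
        raise ConvergenceError(
            "observed information for beta is not positive at the optimum",
            {"var_beta": float(var_beta)},
        )
    return float(np.sqrt(var_beta))


def mle_estimate(s: SummarySet, tol: float = 1e-8) -> CausalEstimate:
    """Likelihood-based estimate under the bivariate-normal summary model.

    Maximizes the likelihood jointly over ``(beta, xi_1..xi_K)`` by
    quasi-Newton iteration started at the IVW estimate (``xi_k`` at the
    observed ``beta_x_k``), falling back to Nelder–Mead restarts on failure.
    The SE is the square root of the (beta, beta) entry of the inverse
    observed information; the CI is Wald.

    Raises
    ------
    ConvergenceError
        If the optimizer fails to converge; diagnostics are attached.
    """
    try:
        beta0 = ivw_estimate(s).beta
    except ValueError:
        beta0 = 0.0
    x0 = np.concatenate(([beta0], s.beta_x))

    res = optimize.minimize(
        _nll, x0, args=(s,), jac=_nll_grad, method="BFGS",
        options={"gtol": tol, "maxiter": 500},
    )
    # BFGS can stall on precision loss near the optimum; accept if the
    # gradient is small, otherwise restart derivative-free.
    if not res.success and np.max(np.abs(_nll_grad(res.x, s))) > 1e-5:
        res2 = optimize.minimize(
            _nll, x0, args=(s,), method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-10, "maxiter": 20000},
        )
        if res2.fun <= res.fun:
            res = res2
        if not res.success and np.max(np.abs(_nll_grad(res.x, s))) > 1e-4:
            raise ConvergenceError(
                "likelihood maximization did not converge",
                {"message": res.message, "nll": float(res.fun),
                 "grad_max": float(np.max(np.abs(_nll_grad(res.x, s))))},
            )
    se = _beta_se_from_information(res.x, s)
    return CausalEstimate(beta=float(res.x[0]), se=se, method="mle", k=len(s))


def rho_sensitivity(s: SummarySet, rhos: Sequence[float]) -> pd.DataFrame:
    """Likelihood-based estimates over a grid of correlation values.

    Returns one row per requested ``rho`` (input order preserved) with
    columns ``rho, beta, se, ci_low, ci_high, k``.  Used as a sensitivity
    analysis when the within-sample correlation between the paired
    association estimates is unknown.
    """
    rows = []
    for rho in rhos:
        est = mle_estimate(s.with_rho(float(rho)))
        rows.append(
            {"rho": float(rho), "beta": est.beta, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high, "k": est.k}
        )
    return pd.DataFrame(rows)


def effect_transform(e: CausalEstimate, delta_x: float) -> CausalEstimate:
    """Re-express a log-scale estimate as an odds (or risk) ratio for a contrast.

    ``e.beta`` must be a log odds ratio (or log relative risk) per unit of the
    risk factor; ``delta_x`` is the contrast in risk-factor units, with sign
    supplied by the caller (e.g. a negative ``delta_x`` for a reduction).
    Returns the exponentiated estimate ``exp(beta * delta_x)`` with a Wald CI
    built on the transformed scale, whose width uses ``se * |delta_x|``.
    """
    if delta_x == 0:
        raise ValueError("delta_x must be nonzero")
    log_or = e.beta * delta_x
    log_se = e.se * abs(delta_x)
    return CausalEstimate(
        beta=float(np.exp(log_or)),
        se=float(np.exp(log_or) * log_se),  # delta-method SE on the ratio scale
        ci_low=float(np.exp(log_or - Z95 * log_se)),
        ci_high=float(np.exp(log_or + Z95 * log_se)),
        method=e.method,
        k=e.k,
    )
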