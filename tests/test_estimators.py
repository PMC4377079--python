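"""Summary-data estimators: ratio, IVW, likelihood-based, transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from mrsummary import (
    SummarySet,
    VariantAssociation,
    effect_transform,
    ivw_estimate,
    mle_estimate,
    ratio_estimate,
    rho_sensitivity,
    summary_set_from_arrays,
)
from mrsummary.data import UndefinedRatioError
from mrsummary.estimators import _nll


def wls_slope_oracle(s: SummarySet):
    """Zero-intercept weighted least squares of beta_y on beta_x, weights se_y^-2."""
    import statsmodels.api as sm

    fit = sm.WLS(s.beta_y, s.beta_x, weights=s.se_y**-2.0).fit()
    return float(fit.params[0]), float(fit.bse[0])


@pytest.mark.parametrize(
    "bx, by, sy, want_beta, want_se",
    [(2.0, 1.0, 0.5, 0.5, 0.25), (1.0, 0.0, 1.0, 0.0, 1.0), (-2.0, 1.0, 0.5, -0.5, 0.25)],
)
def test_ratio_point_and_leading_se(bx, by, sy, want_beta, want_se):
    v = VariantAssociation("v", bx, 0.1, by, sy)
    est = ratio_estimate(v)
    assert est.beta == pytest.approx(want_beta)
    assert est.se == pytest.approx(want_se)
    assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
    assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)


def test_ratio_undefined_for_null_instrument():
    with pytest.raises(UndefinedRatioError):
        ratio_estimate(VariantAssociation("v", 0.0, 0.1, 0.5, 0.1))


def test_ratio_delta_se_close_to_bootstrap_sd(rng):
    """The leading delta-method SE tracks the sampling SD of the ratio.

    Parametric bootstrap: redraw both associations with independent normal
    errors and compare the empirical SD of the ratio with the reported SE.
    """
    v = VariantAssociation("v", 0.4, 0.04, 0.12, 0.05)
    est = ratio_estimate(v)
    assert est.beta == pytest.approx(0.30)
    n = 100_000
    bx = v.beta_x + v.se_x * rng.standard_normal(n)
    by = v.beta_y + v.se_y * rng.standard_normal(n)
    sd = np.std(by / bx)
    assert abs(est.se - sd) / sd < 0.10
    # the opt-in second-order correction moves the SE toward the bootstrap SD
    est2 = ratio_estimate(v, second_order=True)
    expected2 = np.sqrt(v.se_y**2 / v.beta_x**2 + v.beta_y**2 * v.se_x**2 / v.beta_x**4)
    assert est2.se == pytest.approx(expected2)
    assert abs(est2.se - sd) <= abs(est.se - sd) + 1e-4


def test_ivw_single_variant_collapses_to_ratio():
    v = VariantAssociation("v", 0.4, 0.04, 0.12, 0.05)
    r, i = ratio_estimate(v), ivw_estimate(SummarySet((v,)))
    assert i.beta == pytest.approx(r.beta)
    assert i.se == pytest.approx(r.se)


def test_ivw_identical_studies_fixed_effect_average():
    s = summary_set_from_arrays([1, 1], [0.1, 0.1], [2, 2], [1, 1])
    est = ivw_estimate(s)
    assert est.beta == pytest.approx(2.0)
    assert est.se == pytest.approx(1 / np.sqrt(2))


def test_ivw_equals_weighted_regression_oracle(five_variant_set):
    est = ivw_estimate(five_variant_set)
    beta, se = wls_slope_oracle(five_variant_set)
    assert est.beta == pytest.approx(beta, rel=1e-12)


def test_ivw_never_wider_than_any_single_ratio(five_variant_set):
    est = ivw_estimate(five_variant_set)
    for v in five_variant_set:
        assert est.se <= ratio_estimate(v).se + 1e-15


@given(
    st.lists(
        st.tuples(
            st.floats(0.05, 2.0), st.floats(0.01, 0.5),
            st.floats(-1.0, 1.0), st.floats(0.01, 0.5),
        ),
        min_size=1, max_size=8,
    )
)
def test_ivw_matches_oracle_property(rows):
    bx = [r[0] for r in rows]
    sx = [r[1] for r in rows]
    by = [r[2] for r in rows]
    sy = [r[3] for r in rows]
    s = summary_set_from_arrays(bx, sx, by, sy)
    beta, _ = wls_slope_oracle(s)
    assert ivw_estimate(s).beta == pytest.approx(beta, rel=1e-10, abs=1e-12)


def test_allele_recoding_invariance(five_variant_set):
    """Flipping the coded allele of any variant negates both associations."""
    s = five_variant_set
    flipped = summary_set_from_arrays(
        -s.beta_x, s.se_x, -s.beta_y, s.se_y, rho=s.rho
    )
    assert ivw_estimate(flipped).beta == pytest.approx(ivw_estimate(s).beta)
    assert mle_estimate(flipped).beta == pytest.approx(mle_estimate(s).beta, abs=1e-6)


def test_scale_equivariance_of_ivw(five_variant_set):
    s = five_variant_set
    c = 3.7
    scaled = summary_set_from_arrays(c * s.beta_x, c * s.se_x, s.beta_y, s.se_y)
    assert ivw_estimate(scaled).beta == pytest.approx(ivw_estimate(s).beta / c)


@pytest.mark.parametrize("rho", [0.0, -0.4, 0.6])
def test_mle_single_variant_is_exact_ratio(rho):
    """With one variant the model is saturated: beta = beta_y / beta_x exactly."""
    v = VariantAssociation("v", 0.4, 0.04, 0.12, 0.05)
    est = mle_estimate(SummarySet((v,), rho=rho))
    assert est.beta == pytest.approx(0.3, abs=1e-6)


def test_mle_limits_to_ivw_when_sex_vanishes(five_variant_set):
    """With negligible risk-factor-side uncertainty and rho=0, MLE -> IVW."""
    s = five_variant_set
    tiny = summary_set_from_arrays(
        s.beta_x, 1e-6 * s.se_y, s.beta_y, s.se_y, rho=0.0
    )
    assert mle_estimate(tiny).beta == pytest.approx(ivw_estimate(tiny).beta, abs=1e-4)


def test_mle_likelihood_at_optimum_dominates_ivw_point(five_variant_set):
    s = five_variant_set
    est = mle_estimate(s)
    opt = optimize.minimize(
        _nll, np.concatenate(([est.beta], s.beta_x)), args=(s,), method="Nelder-Mead",
        options={"fatol": 1e-12, "xatol": 1e-12, "maxiter": 50000},
    )
    ivw_point = np.concatenate(([ivw_estimate(s).beta], s.beta_x))
    assert opt.fun <= _nll(ivw_point, s) + 1e-8


def _bvn_nll_oracle(theta, s):
    """Independent negative log-likelihood via scipy's multivariate normal."""
    beta, xi = theta[0], np.asarray(theta[1:])
    total = 0.0
    for j, v in enumerate(s):
        cov = np.array([
            [v.se_x**2, s.rho * v.se_x * v.se_y],
            [s.rho * v.se_x * v.se_y, v.se_y**2],
        ])
        total -= stats.multivariate_normal.logpdf(
            [v.beta_x, v.beta_y], mean=[xi[j], beta * xi[j]], cov=cov
        )
    return total


@pytest.mark.parametrize("rho", [-0.5, 0.0, 0.5])
def test_mle_matches_grid_search_oracle(rho):
    """Brute-force maximization of an independently written likelihood."""
    s = summary_set_from_arrays(
        [0.3, 0.3], [0.05, 0.05], [0.09, 0.09], [0.04, 0.04], rho=rho
    )
    est = mle_estimate(s)
    res = optimize.brute(
        _bvn_nll_oracle, ((0.0, 0.6), (0.1, 0.5), (0.1, 0.5)), args=(s,),
        Ns=25, full_output=True, finish=optimize.fmin,
    )
    assert est.beta == pytest.approx(res[0][0], abs=1e-3)


def test_mle_beta_flat_or_monotone_in_rho_on_symmetric_set():
    s = summary_set_from_arrays(
        [0.3, 0.3], [0.05, 0.05], [0.09, 0.09], [0.04, 0.04]
    )
    rhos = [-0.6, -0.3, 0.0, 0.3, 0.6]
    betas = rho_sensitivity(s, rhos)["beta"].to_numpy()
    diffs = np.diff(betas)
    assert (diffs >= -1e-6).all() or (diffs <= 1e-6).all()


def test_rho_sensitivity_preserves_order_and_matches_single_fit(five_variant_set):
    tab = rho_sensitivity(five_variant_set, [0.2, -0.2, 0.0])
    assert list(tab["rho"]) == [0.2, -0.2, 0.0]
    single = mle_estimate(five_variant_set.with_rho(0.0))
    row = tab[tab["rho"] == 0.0].iloc[0]
    assert row["beta"] == pytest.approx(single.beta, abs=1e-8)
    assert row["se"] == pytest.approx(single.se, rel=1e-6)


def test_effect_transform_closed_forms():
    from mrsummary.data import CausalEstimate

    null = CausalEstimate(beta=0.0, se=0.1, method="mle", k=3)
    orr = effect_transform(null, delta_x=2.5)
    assert orr.beta == pytest.approx(1.0)
    assert orr.ci_low < 1.0 < orr.ci_high

    doubling = CausalEstimate(beta=np.log(2), se=0.1, method="ivw", k=3)
    assert effect_transform(doubling, 1.0).beta == pytest.approx(2.0)

    e = CausalEstimate(beta=0.5, se=0.1, method="mle", k=5)
    orr = effect_transform(e, delta_x=-2.0)
    assert orr.beta == pytest.approx(np.exp(-1.0))
    assert orr.ci_low == pytest.approx(np.exp(-1 - 1.96 * 0.2))
    assert orr.ci_high == pytest.approx(np.exp(-1 + 1.96 * 0.2))


def test_summary_set_validation():
    v = VariantAssociation("a", 0.1, 0.01, 0.02, 0.01)
    with pytest.raises(ValueError, match="duplicate"):
        SummarySet((v, v))
    with pytest.raises(ValueError, match="rho"):
        SummarySet((v,), rho=1.0)
    with pytest.raises(ValueError, match="se_y"):
        VariantAssociation("a", 0.1, 0.01, 0.02, 0.0)
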