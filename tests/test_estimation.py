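"""Estimation tests: closed-form MLEs, parameter recovery, standard-error
behaviour, information criteria, likelihood nesting, and a cross-check of the
pooled fits against an independent implementation (statsmodels)."""

import math

import numpy as np
import pandas as pd
import pytest

from zinbpanel import (
    OptimizerConfig,
    PanelDataset,
    fit,
    information_criteria,
    standard_errors,
    total_loglik,
)
from zinbpanel.fit import _ic

from conftest import intercept_only_panel

FAST = OptimizerConfig(quad_order=9)


def test_poisson_intercept_only_closed_form():
    """The intercept-only Poisson MLE is the sample mean, with SE
    sqrt(mean/N) for the rate."""
    rng = np.random.default_rng(1)
    counts = rng.poisson(0.7, 5000)
    panel = intercept_only_panel(counts)
    res = fit(panel, "poisson")
    rate = math.exp(res.estimates[0])
    ybar = counts.mean()
    assert rate == pytest.approx(ybar, rel=1e-7)
    # delta method: se(rate) = rate * se(beta0)
    se_rate = rate * res.se[0]
    assert se_rate == pytest.approx(math.sqrt(ybar / len(counts)), rel=1e-3)


def test_nb_intercept_only_recovery():
    """Intercept-only NB on simulated data recovers (lambda, alpha) within
    3 SE at N = 20,000."""
    rng = np.random.default_rng(2)
    n = 20_000
    lam, alpha = 0.5, 1.5
    g = rng.gamma(1.0 / alpha, alpha, n)
    counts = rng.poisson(lam * g)
    panel = intercept_only_panel(counts)
    res = fit(panel, "nb")
    est_lam = math.exp(res.estimates[0])
    se_lam = est_lam * res.se[0]
    j = res.param_names.index("alpha")
    assert abs(est_lam - lam) < 3 * se_lam
    assert abs(res.estimates[j] - alpha) < 3 * res.se[j]


def test_information_additivity_duplicated_panel(fit_panel):
    """Duplicating every site halves the variance: pooled SEs shrink ~1/sqrt(2)."""
    res1 = fit(fit_panel, "nb", FAST)
    df2 = fit_panel.frame.copy()
    df2["site_id"] = df2["site_id"].astype(str) + "_dup"
    doubled = PanelDataset(
        pd.concat([fit_panel.frame, df2]),
        fit_panel.count_design,
        fit_panel.zero_design,
    )
    res2 = fit(doubled, "nb", FAST)
    ratio = res2.se / res1.se
    assert np.allclose(ratio, 1.0 / math.sqrt(2.0), atol=0.02)


def test_se_finite_difference_step_stability(fit_panel):
    """Halving the Hessian finite-difference step moves SEs by < 0.1%."""
    res = fit(fit_panel, "zinb", FAST)
    se_a = standard_errors(res, fit_panel, step=1e-4).copy()
    se_b = standard_errors(res, fit_panel, step=5e-5)
    assert np.all(np.abs(se_b - se_a) / se_a < 1e-3)


def test_likelihood_nesting(fit_panel):
    """Richer models cannot fit worse: Poisson <= NB <= ZINB <= ZINB-RE."""
    lls = {}
    for label in ("poisson", "nb", "zinb", "zinb_re"):
        lls[label] = fit(fit_panel, label, FAST, compute_se=False).loglik
    tol = 1e-4
    assert lls["nb"] >= lls["poisson"] - tol
    assert lls["zinb"] >= lls["nb"] - tol
    assert lls["zinb_re"] >= lls["zinb"] - tol


def test_reported_loglik_matches_total_loglik(fit_panel):
    res = fit(fit_panel, "zinb_re", FAST, compute_se=False)
    assert res.loglik == pytest.approx(
        total_loglik(fit_panel, res.params, FAST.quad_order), abs=1e-8
    )


def test_stationarity_of_returned_optimum(fit_panel):
    """Refitting from the returned optimum barely moves the parameters."""
    res = fit(fit_panel, "zinb", FAST, compute_se=False)
    res2 = fit(fit_panel, "zinb", FAST, start_params=res.theta, compute_se=False)
    assert np.max(np.abs(res2.theta - res.theta)) < 1e-5


def test_information_criteria_identities():
    # arithmetic of the criteria at a fitted-scale example: a model with 26
    # free parameters and loglik -7572.5 on N = 328,529 rows
    aic, bic, neg2ll = _ic(-7572.5, 26, 328_529)
    assert neg2ll == pytest.approx(15_145.0)
    assert aic == pytest.approx(15_197.0)
    assert bic - aic == pytest.approx(26 * (math.log(328_529) - 2.0))
    # k = 0 degenerate case
    aic0, bic0, n20 = _ic(-10.0, 0, 100)
    assert aic0 == bic0 == n20
    # identity for random k, N
    rng = np.random.default_rng(0)
    for _ in range(5):
        k = int(rng.integers(1, 40))
        n = int(rng.integers(2, 10**6))
        a, b, _ = _ic(-123.4, k, n)
        assert b - a == pytest.approx(k * (math.log(n) - 2.0))


def test_information_criteria_accessor(fit_panel):
    res = fit(fit_panel, "poisson")
    aic, bic, neg2ll = information_criteria(res)
    assert aic == pytest.approx(neg2ll + 2 * res.k_free)
    assert bic == pytest.approx(neg2ll + res.k_free * math.log(res.n_obs))


def test_numeric_gradient_mode_agrees(tiny_panel):
    cfg_a = OptimizerConfig(gradient="analytic")
    cfg_n = OptimizerConfig(gradient="numeric")
    ra = fit(tiny_panel, "poisson", cfg_a, compute_se=False)
    rn = fit(tiny_panel, "poisson", cfg_n, compute_se=False)
    assert np.allclose(ra.theta, rn.theta, atol=1e-4)
    assert ra.loglik == pytest.approx(rn.loglik, abs=1e-6)


def test_alpha_boundary_flag_on_poisson_data():
    """Equidispersed data pushes alpha to its lower boundary; the fit is
    flagged, not an error."""
    rng = np.random.default_rng(3)
    counts = rng.poisson(0.3, 10_000)
    panel = intercept_only_panel(counts)
    res = fit(panel, "nb")
    assert res.params.alpha < 0.05 or "alpha" in res.boundary


def test_statsmodels_crosscheck_pooled_nb_and_zinb(fit_panel):
    """Independent oracle: statsmodels NB2 / ZINB on the same design reach
    the same maximized likelihood (within optimizer slack)."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
    from statsmodels.discrete.discrete_model import NegativeBinomialP

    y = fit_panel.counts
    Xnb = fit_panel.count_matrix()
    Xz = fit_panel.zero_matrix()

    ours_nb = fit(fit_panel, "nb", FAST, compute_se=False)
    sm_nb = NegativeBinomialP(y, Xnb, p=2).fit(disp=0, maxiter=500, method="bfgs")
    assert ours_nb.loglik == pytest.approx(sm_nb.llf, abs=0.51)
    assert ours_nb.loglik >= sm_nb.llf - 0.51

    ours_zinb = fit(fit_panel, "zinb", FAST, compute_se=False)
    sm_zinb = ZeroInflatedNegativeBinomialP(
        y, Xnb, exog_infl=Xz, p=2
    ).fit(disp=0, maxiter=1000, method="bfgs")
    # statsmodels may stop short on this flat likelihood; ours must not be worse
    assert ours_zinb.loglik >= sm_zinb.llf - 0.51
    assert ours_zinb.loglik == pytest.approx(sm_zinb.llf, abs=2.0)
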