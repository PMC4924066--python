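"""Probability-core tests: pmfs against analytic limits and sampling oracles,
quadrature against Monte-Carlo integration, and mixture-moment properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit, logsumexp

from zinbpanel import (
    ConfigError,
    PanelDataset,
    ZinbReParams,
    expected_count,
    linear_predictors,
    nb_pmf,
    site_marginal_loglik,
    total_loglik,
    zinb_logpmf,
    zinb_pmf,
)


# ---------------------------------------------------------------------------
# NB pmf
# ---------------------------------------------------------------------------


def test_nb_pmf_poisson_limit():
    """As alpha -> 0 the NB pmf converges to the Poisson pmf."""
    assert nb_pmf(0, 1.0, 1e-8) == pytest.approx(math.exp(-1), abs=1e-7)
    for lam in (0.1, 1.0, 5.0):
        y = np.arange(21)
        dev = np.abs(nb_pmf(y, lam, 1e-8) - stats.poisson.pmf(y, lam))
        assert dev.max() < 1e-6


@pytest.mark.parametrize("lam,alpha", [(0.5, 1.818), (0.004, 1.8), (3.0, 0.25)])
def test_nb_pmf_zero_closed_form(lam, alpha):
    """P(0) = (1/(1+alpha*lam))^(1/alpha) exactly."""
    expected = (1.0 / (1.0 + alpha * lam)) ** (1.0 / alpha)
    assert nb_pmf(0, lam, alpha) == pytest.approx(expected, rel=1e-12)


def test_nb_pmf_matches_gamma_poisson_sampling_oracle():
    """The pmf agrees with its generative story: a Poisson whose rate is
    lambda times a mean-one gamma with shape 1/alpha."""
    y, lam, alpha = 2, 0.5, 1.818
    rng = np.random.default_rng(20240915)
    n = 10**6
    g = rng.gamma(1.0 / alpha, alpha, n)
    draws = rng.poisson(lam * g)
    p_hat = np.mean(draws == y)
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    assert abs(nb_pmf(y, lam, alpha) - p_hat) < 3 * se


def test_nb_pmf_domain_errors():
    with pytest.raises(ValueError):
        nb_pmf(-1, 1.0, 1.0)
    with pytest.raises(ValueError):
        nb_pmf(1.5, 1.0, 1.0)
    with pytest.raises(ValueError):
        nb_pmf(1, -0.5, 1.0)
    with pytest.raises(ValueError):
        nb_pmf(1, 1.0, 0.0)


# ---------------------------------------------------------------------------
# ZINB pmf
# ---------------------------------------------------------------------------


def test_zinb_pmf_degenerate_states():
    assert zinb_pmf(0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
    assert zinb_pmf(3, 1.0, 1.0, 1.0) == pytest.approx(0.0)
    for y in range(5):
        assert zinb_pmf(y, 0.7, 0.0, 1.3) == pytest.approx(
            float(nb_pmf(y, 0.7, 1.3)), rel=1e-12
        )


def test_zinb_pmf_q_domain():
    with pytest.raises(ValueError):
        zinb_pmf(0, 1.0, 1.2, 1.0)


@given(
    lam=st.floats(0.01, 20.0),
    q=st.floats(0.0, 0.99),
    alpha=st.floats(0.01, 5.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_zinb_normalization(lam, q, alpha):
    """The mixture pmf sums to one over its support."""
    y = np.arange(0, 2001)
    total = np.exp(logsumexp(zinb_logpmf(y, lam, q, alpha)))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_zinb_overdispersion_of_mixture():
    """Var(n) > E(n) whenever alpha > 0 or q > 0 (truncated moments)."""
    y = np.arange(0, 4001)
    for lam in (0.1, 1.0, 4.0):
        for q, alpha in [(0.0, 0.5), (0.3, 1e-8), (0.4, 1.8)]:
            p = zinb_pmf(y, lam, q, alpha)
            mean = float(np.sum(y * p))
            var = float(np.sum((y - mean) ** 2 * p))
            assert var > mean


def test_expected_count():
    assert expected_count(0.7, 0.0) == pytest.approx(0.7)
    assert expected_count(0.7, 1.0) == pytest.approx(0.0)
    # sampling oracle for the mixture mean
    rng = np.random.default_rng(5)
    n = 10**6
    lam, q, alpha = 0.5, 0.4, 1.0
    active = rng.random(n) >= q
    g = rng.gamma(1.0 / alpha, alpha, n)
    draws = np.where(active, rng.poisson(lam * g), 0)
    se = draws.std() / math.sqrt(n)
    assert expected_count(lam, q) == pytest.approx(0.3, rel=1e-12)
    assert abs(draws.mean() - 0.3) < 3 * se


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------


def _one_site_panel(counts, x=None):
    n = len(counts)
    df = pd.DataFrame(
        {"site_id": ["s"] * n, "time_id": np.arange(n), "count": counts}
    )
    if x is not None:
        df["x"] = x
    return df


def test_linear_predictors_identity_case(tiny_panel):
    params = ZinbReParams(np.zeros(3), np.zeros(2), alpha=1.0)
    lp = linear_predictors(tiny_panel, params)
    assert np.allclose(lp.lambda_it, 1.0)
    assert np.allclose(lp.q_it, 0.5)
    assert np.allclose(lp.u_it, 0.5)


def test_linear_predictors_loglink_additivity():
    df = _one_site_panel([0, 0, 1])
    panel = PanelDataset(df, [], [])
    params = ZinbReParams(np.array([math.log(2.0)]), None, alpha=1.0)
    lp = linear_predictors(panel, params, sigma_i=[math.log(3.0)])
    assert np.allclose(lp.lambda_it, 6.0)


def test_linear_predictors_zero_state_constant():
    """The logit link at the zero-state constant alone."""
    df = _one_site_panel([0, 0])
    panel = PanelDataset(df, [], [])
    params = ZinbReParams(np.array([0.0]), np.array([-10.731]), alpha=1.0)
    lp = linear_predictors(panel, params)
    assert np.allclose(lp.q_it, expit(-10.731))
    assert lp.q_it[0] == pytest.approx(2.186e-5, rel=1e-3)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def _site_panel():
    df = _one_site_panel([0, 0, 1, 0, 2])
    return PanelDataset(df, [], [])


def test_site_marginal_collapses_when_phi_zero():
    panel = _site_panel()
    params = ZinbReParams(np.array([-0.5]), np.array([-0.8]), 1.8, 0.0, 0.0)
    pooled = float(
        np.sum(
            zinb_logpmf(
                panel.counts, math.exp(-0.5), expit(-0.8), 1.8
            )
        )
    )
    for order in (1, 5, 31):
        assert site_marginal_loglik(panel, params, order) == pytest.approx(
            pooled, abs=1e-12
        )


def test_site_marginal_single_node_is_pooled():
    """Order-1 Gauss-Hermite has its node at the origin: the pooled value."""
    panel = _site_panel()
    params = ZinbReParams(np.array([-0.5]), np.array([-0.8]), 1.8, 0.484, 0.0)
    pooled = ZinbReParams(np.array([-0.5]), np.array([-0.8]), 1.8, 0.0, 0.0)
    assert site_marginal_loglik(panel, params, 1) == pytest.approx(
        site_marginal_loglik(panel, pooled, 15), abs=1e-12
    )


def test_site_marginal_matches_mc_integration():
    """Gauss-Hermite vs 10^6-draw Monte-Carlo integration over sigma."""
    panel = _site_panel()
    params = ZinbReParams(np.array([-0.5]), np.array([-0.8]), 1.8, 0.484, 0.0)
    gh = site_marginal_loglik(panel, params, 31)
    rng = np.random.default_rng(11)
    sig = rng.normal(0.0, 0.484, 10**6)
    y = panel.counts
    ll = np.zeros(len(sig))
    for yi in y:
        ll += zinb_logpmf(
            int(yi), np.exp(-0.5 + sig), expit(-0.8), 1.8
        )
    mc = logsumexp(ll) - math.log(len(sig))
    assert gh == pytest.approx(mc, abs=1e-3)


def test_quadrature_convergence():
    panel = _site_panel()
    params = ZinbReParams(np.array([-0.5]), np.array([-0.8]), 1.8, 0.484, 0.3)
    a = site_marginal_loglik(panel, params, 31)
    b = site_marginal_loglik(panel, params, 63)
    assert abs(a - b) < 1e-8


def test_quad_order_validation():
    panel = _site_panel()
    params = ZinbReParams(np.array([-0.5]), None, 1.8)
    with pytest.raises(ConfigError):
        site_marginal_loglik(panel, params, 0)


def test_total_loglik_additivity_and_permutation(small_panel, small_sim):
    params = small_sim.truth
    # single-site equality
    sid = small_panel.site_labels[0]
    one = small_panel.site_slice(sid)
    assert total_loglik(one, params, 9) == pytest.approx(
        site_marginal_loglik(one, params, 9), abs=1e-10
    )
    # permutation invariance
    shuffled = small_panel.frame.sample(frac=1.0, random_state=3)
    p2 = PanelDataset(shuffled, small_panel.count_design, small_panel.zero_design)
    assert total_loglik(p2, params, 9) == pytest.approx(
        total_loglik(small_panel, params, 9), abs=1e-8
    )
    # duplicating a site doubles its contribution
    df = one.frame.copy()
    df2 = df.copy()
    df2["site_id"] = "copy"
    both = PanelDataset(
        pd.concat([df, df2]), small_panel.count_design, small_panel.zero_design
    )
    assert total_loglik(both, params, 9) == pytest.approx(
        2.0 * total_loglik(one, params, 9), abs=1e-9
    )


def test_zinb_reduces_to_nb_when_zero_state_vanishes(small_panel):
    """Zero-state intercept -> -inf gives the plain NB likelihood."""
    beta_nb = np.r_[-5.5, np.zeros(len(small_panel.count_design))]
    nb_params = ZinbReParams(beta_nb, None, 1.8)
    zi = ZinbReParams(
        beta_nb, np.r_[-40.0, np.zeros(len(small_panel.zero_design))], 1.8
    )
    assert total_loglik(small_panel, zi, 5) == pytest.approx(
        total_loglik(small_panel, nb_params, 5), abs=1e-8
    )
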