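"""Probability core: NB and zero-inflated NB pmfs, linear predictors, and the
marginal likelihood of the site-random-effects ZINB on unbalanced panels.

Model family
------------
Counts n_it (site i, hour t) follow a two-state mixture.  With probability
q_it the segment-hour is in a structurally safe zero state; otherwise the
count is negative binomial with mean lambda_it and overdispersion alpha
(gamma-mixed Poisson, Poisson in the limit alpha -> 0)::

    lambda_it = exp(beta_nb . x_nb_it + sigma_i)
    logit(q_it) = beta_z . x_z_it + psi_i

Site effects sigma_i ~ N(0, phi_sigma^2) and psi_i ~ N(0, phi_psi^2) are
independent normals capturing unobserved within-site correlation.  The
marginal likelihood of a site integrates them out; here by (product)
Gauss-Hermite quadrature, exactly collapsing to a point mass when a phi is 0.

All density arithmetic is done in log space (log-gamma, log-sum-exp):
the data are >99% zeros and alpha is large, so direct gamma ratios are
overflow-prone.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
import math
from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .data import PanelDataset

logger = logging.getLogger("zinbpanel")

#: clamp on linear predictors (log scale) before exponentiation
ETA_CLIP = 600.0


class ConfigError(ValueError):
    """Invalid model or quadrature configuration."""


class EstimationError(RuntimeError):
    """Numerical failure while evaluating the likelihood."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ZinbReParams:
    """Full parameter vector of the random-effects ZINB family.

    ``beta_nb`` and ``beta_z`` include the leading intercept.  ``alpha=None``
    denotes the Poisson limit (no overdispersion); ``beta_z=None`` denotes no
    zero state (q = 0).  ``phi_sigma`` / ``phi_psi`` are the standard
    deviations of the count-state and zero-state site effects; 0 disables the
    corresponding effect.
    """

    beta_nb: np.ndarray
    beta_z: Optional[np.ndarray] = None
    alpha: Optional[float] = None
    phi_sigma: float = 0.0
    phi_psi: float = 0.0

    def __post_init__(self) -> None:
        self.beta_nb = np.atleast_1d(np.asarray(self.beta_nb, dtype=float))
        if self.beta_z is not None:
            self.beta_z = np.atleast_1d(np.asarray(self.beta_z, dtype=float))
        if self.alpha is not None and not self.alpha > 0:
            raise ConfigError("alpha must be > 0 (use None for the Poisson limit)")
        if self.phi_sigma < 0 or self.phi_psi < 0:
            raise ConfigError("phi_sigma and phi_psi must be >= 0")

    @property
    def has_zero_state(self) -> bool:
        return self.beta_z is not None

    @property
    def has_nb(self) -> bool:
        return self.alpha is not None


@dataclasses.dataclass
class LinearPredictors:
    """Row-wise lambda_it, q_it and the derived ratio u_it = r/(r+lambda)."""

    lambda_it: np.ndarray
    q_it: np.ndarray
    u_it: Optional[np.ndarray]
    clipped: int = 0  # rows whose predictor hit the log-space clamp


# ---------------------------------------------------------------------------
# elementary pmfs
# ---------------------------------------------------------------------------


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    return y.astype(np.int64)


def nb_logpmf(y, lam, alpha):
    """Log pmf of the NB2 distribution with mean ``lam``, overdispersion ``alpha``.

    P(y) = Gamma(r+y) / (Gamma(r) Gamma(y+1)) * u^r * (1-u)^y with r = 1/alpha
    and u = r / (r + lam); the gamma-mixed Poisson with gamma shape r and mean 1.
    """
    y = _validate_counts(y)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be > 0")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    lnr = -np.log(alpha)
    llam = np.log(lam)
    lr_lam = np.logaddexp(lnr, llam)
    r = np.exp(lnr)
    return (
        gammaln(r + y)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * (lnr - lr_lam)
        + y * (llam - lr_lam)
    )


def nb_pmf(y, lam, alpha):
    """NB2 pmf (see :func:`nb_logpmf`)."""
    return np.exp(nb_logpmf(y, lam, alpha))


def zinb_logpmf(y, lam, q, alpha):
    """Log pmf of the zero-inflated NB mixture.

    y = 0 with probability q + (1-q) NB(0); y = j > 0 with (1-q) NB(j).
    """
    y = _validate_counts(y)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    nb = nb_logpmf(y, lam, alpha)
    with np.errstate(divide="ignore"):
        log_q = np.log(q)
        log_1mq = np.log1p(-q)
    out = np.where(
        y == 0,
        np.logaddexp(log_q, log_1mq + nb),
        log_1mq + nb,
    )
    return out


def zinb_pmf(y, lam, q, alpha):
    """ZINB pmf (see :func:`zinb_logpmf`)."""
    return np.exp(zinb_logpmf(y, lam, q, alpha))


def expected_count(lam, q):
    """Mixture mean E[n] = (1 - q) * lambda."""
    lam = np.asarray(lam, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(lam < 0) or np.any((q < 0) | (q > 1)):
        raise ValueError("invalid lam or q")
    return (1.0 - q) * lam


# ---------------------------------------------------------------------------
# linear predictors
# ---------------------------------------------------------------------------


def _clip_eta(eta: np.ndarray) -> tuple[np.ndarray, int]:
    n_clip = int(np.sum(np.abs(eta) > ETA_CLIP))
    if n_clip:
        logger.warning("clamped %d overflow-producing linear predictors", n_clip)
        eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    return eta, n_clip


def linear_predictors(
    data: PanelDataset,
    params: ZinbReParams,
    sigma_i=None,
    psi_i=None,
) -> LinearPredictors:
    """Evaluate lambda_it, q_it (and u_it) given site effects.

    ``sigma_i`` / ``psi_i`` are per-site effect values in site-label order;
    zero vectors (the default) give the pooled model.
    """
    Xnb = data.count_matrix()
    if len(params.beta_nb) != Xnb.shape[1]:
        raise ConfigError("beta_nb length does not match count design (+intercept)")
    eta_nb = Xnb @ params.beta_nb
    if sigma_i is not None:
        eta_nb = eta_nb + np.asarray(sigma_i, dtype=float)[data.site_codes]
    eta_nb, n_clip = _clip_eta(eta_nb)
    lam = np.exp(eta_nb)

    if params.has_zero_state:
        Xz = data.zero_matrix()
        if len(params.beta_z) != Xz.shape[1]:
            raise ConfigError("beta_z length does not match zero design (+intercept)")
        eta_z = Xz @ params.beta_z
        if psi_i is not None:
            eta_z = eta_z + np.asarray(psi_i, dtype=float)[data.site_codes]
        eta_z, c2 = _clip_eta(eta_z)
        n_clip += c2
        q = 1.0 / (1.0 + np.exp(-eta_z))
    else:
        q = np.zeros_like(lam)

    u = None
    if params.has_nb:
        r = 1.0 / params.alpha
        u = r / (r + lam)
    return LinearPredictors(lam, q, u, clipped=n_clip)


# ---------------------------------------------------------------------------
# log-density engine (vectorised over quadrature nodes x rows)
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _row_logf(y, llam, s, lnalpha, want_grad=False):
    """Per-row log density of the (possibly zero-inflated) count state.

    Parameters are broadcastable arrays: ``llam`` = log lambda, ``s`` = logit q
    (or None for no zero state), ``lnalpha`` = log alpha (or None for Poisson).
    Returns ``(logf, dA, dB, dC)`` where dA = d logf / d eta_nb,
    dB = d logf / d s, dC = d logf / d ln(alpha); gradient slots are None
    unless requested/applicable.

    The y = 0 branch uses the closed form NB(0) = u^r, so the dominant zero
    rows avoid log-gamma entirely.
    """
    y = np.asarray(y)
    iz = y == 0
    inz = ~iz
    llam = np.atleast_2d(llam)
    M = llam.shape[0]
    if s is not None:
        M = max(M, np.atleast_2d(s).shape[0])
    N = llam.shape[1]
    logf = np.empty((M, N))
    dA = np.empty((M, N)) if want_grad else None
    dB = None
    dC = None

    if lnalpha is not None:
        lnr = -lnalpha
        r = math.exp(lnr)
        lr_lam = np.logaddexp(lnr, llam)
        log_u = lnr - lr_lam
        lp0 = r * log_u[:, iz]  # log NB(0)
        yv = y[inz].astype(float)
        ll_nz = llam[:, inz]
        lrl_nz = lr_lam[:, inz]
        lp_nz = (
            gammaln(r + yv)
            - gammaln(r)
            - gammaln(yv + 1.0)
            + r * (lnr - lrl_nz)
            + yv * (ll_nz - lrl_nz)
        )
        if want_grad:
            dC = np.empty((M, N))
            # d log NB(0) / d eta_nb = -r*lam/(r+lam); / d ln a = -r*(log u + lam/(r+lam))
            lam_frac0 = np.exp(llam[:, iz] - lr_lam[:, iz])  # lam/(r+lam)
            g0_eta = -r * lam_frac0
            g0_lna = -r * (log_u[:, iz] + lam_frac0)
            lam_nz = np.exp(ll_nz)
            g_eta_nz = np.exp(lnr - lrl_nz) * (yv - lam_nz)  # r(y-lam)/(r+lam)
            g_lna_nz = -r * (
                digamma(r + yv)
                - digamma(r)
                + (lnr - lrl_nz)
                + (lam_nz - yv) / (r + lam_nz)
            )
    else:
        # Poisson limit
        lam = np.exp(llam)
        lp0 = -lam[:, iz]
        yv = y[inz].astype(float)
        lp_nz = yv * llam[:, inz] - lam[:, inz] - gammaln(yv + 1.0)
        if want_grad:
            g0_eta = -lam[:, iz]
            g_eta_nz = yv - lam[:, inz]

    if s is None:
        logf[:, iz] = lp0
        logf[:, inz] = lp_nz
        if want_grad:
            dA[:, iz] = g0_eta
            dA[:, inz] = g_eta_nz
            if lnalpha is not None:
                dC[:, iz] = g0_lna
                dC[:, inz] = g_lna_nz
        return logf, dA, dB, dC

    # s may be node-constant (shape (1, N)) when only the count state carries
    # a random effect; keep it narrow and let broadcasting do the work
    s = np.atleast_2d(s)
    log_q = -_softplus(-s)
    log_1mq = -_softplus(s)
    logf[:, iz] = np.logaddexp(log_q[:, iz], log_1mq[:, iz] + lp0)
    logf[:, inz] = log_1mq[:, inz] + lp_nz
    if want_grad:
        dB = np.empty((M, N))
        # weight of the count branch at y=0: (1-q)NB(0)/f
        w_cnt = np.exp(log_1mq[:, iz] + lp0 - logf[:, iz])
        dA[:, iz] = w_cnt * g0_eta
        dA[:, inz] = g_eta_nz
        # d logf/ds at y=0: df/ds = q(1-q)(1 - NB0); use -expm1(lp0) for (1-NB0)
        dB[:, iz] = (
            np.exp(log_q[:, iz] + log_1mq[:, iz] - logf[:, iz]) * (-np.expm1(lp0))
        )
        dB[:, inz] = -np.exp(log_q[:, inz])
        if lnalpha is not None:
            dC[:, iz] = w_cnt * g0_lna
            dC[:, inz] = g_lna_nz
    return logf, dA, dB, dC


# ---------------------------------------------------------------------------
# Gauss-Hermite quadrature over site effects
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=32)
def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Hermite nodes/log-weights for integrating against a standard normal.

    For z ~ N(0,1): E[g(z)] ~= sum_k w_k/sqrt(pi) g(sqrt(2) x_k).
    """
    if order < 1:
        raise ConfigError("quadrature order must be >= 1")
    x, w = np.polynomial.hermite.hermgauss(order)
    return np.sqrt(2.0) * x, np.log(w) - 0.5 * math.log(math.pi)


def _effect_nodes(params: ZinbReParams, quad_order: int):
    """Product-rule node grid (sigma_m, psi_m, logw_m) over the active effects.

    Each phi = 0 collapses the corresponding dimension to a point mass at 0
    exactly (single node, zero log-weight).
    """
    z, lw = _gh_nodes(quad_order)
    use_s = params.phi_sigma > 0
    use_p = params.has_zero_state and params.phi_psi > 0
    if use_s and use_p:
        sig = np.repeat(params.phi_sigma * z, len(z))
        psi = np.tile(params.phi_psi * z, len(z))
        logw = np.repeat(lw, len(z)) + np.tile(lw, len(z))
    elif use_s:
        sig, psi, logw = params.phi_sigma * z, np.zeros_like(z), lw
    elif use_p:
        sig, psi, logw = np.zeros_like(z), params.phi_psi * z, lw
    else:
        sig = np.zeros(1)
        psi = np.zeros(1)
        logw = np.zeros(1)
    return sig, psi, logw


def _marginal_core(
    y: np.ndarray,
    starts: np.ndarray,
    site_codes: np.ndarray,
    Xnb: np.ndarray,
    Xz,
    params: ZinbReParams,
    quad_order: int,
    want_grad: bool = False,
):
    """Marginal log-likelihood (and gradient) from raw design arrays.

    Returns ``(per_site_loglik, grad)`` where ``grad`` is a dict with keys
    ``beta_nb``, ``beta_z``, ``lnalpha``, ``lnphi_sigma``, ``lnphi_psi``
    (present only for active components) or None.  The gradient is taken with
    respect to the internal unconstrained scale (log alpha, log phi).
    """
    if quad_order < 1:
        raise ConfigError("quadrature order must be >= 1")
    eta_nb, _ = _clip_eta(Xnb @ params.beta_nb)
    if params.has_zero_state:
        eta_z, _ = _clip_eta(Xz @ params.beta_z)
    else:
        eta_z = None
    lnalpha = math.log(params.alpha) if params.has_nb else None

    sig, psi, logw = _effect_nodes(params, quad_order)
    llam = eta_nb[None, :] + sig[:, None] if np.any(sig) else eta_nb[None, :]
    s = None
    if eta_z is not None:
        s = eta_z[None, :] + psi[:, None] if np.any(psi) else eta_z[None, :]

    logf, dA, dB, dC = _row_logf(y, llam, s, lnalpha, want_grad)
    if not np.all(np.isfinite(logf) | (logf == -np.inf)):
        bad = np.argwhere(~(np.isfinite(logf) | (logf == -np.inf)))
        raise EstimationError(f"non-finite integrand at node/row {bad[0].tolist()}")

    # site sums S_mi, then log-sum-exp across nodes
    S = np.add.reduceat(logf, starts, axis=1)  # (M, I)
    Lw = logw[:, None] + S
    L_i = logsumexp(Lw, axis=0)  # (I,)
    if not want_grad:
        return L_i, None

    grad: dict[str, np.ndarray | float] = {}
    M = len(sig)
    if M == 1:
        a = dA[0]
        grad["beta_nb"] = Xnb.T @ a
        if dB is not None:
            grad["beta_z"] = Xz.T @ dB[0]
        if dC is not None:
            grad["lnalpha"] = float(np.sum(dC[0]))
    else:
        with np.errstate(under="ignore"):
            W = np.exp(Lw - L_i[None, :])  # posterior node weights (M, I)
        Wrow = W[:, site_codes]  # (M, N)
        a = np.einsum("mn,mn->n", Wrow, dA)
        grad["beta_nb"] = Xnb.T @ a
        if dB is not None:
            b = np.einsum("mn,mn->n", Wrow, dB)
            grad["beta_z"] = Xz.T @ b
        if dC is not None:
            grad["lnalpha"] = float(np.einsum("mn,mn->", Wrow, dC))
        if params.phi_sigma > 0:
            SA = np.add.reduceat(dA, starts, axis=1)
            grad["lnphi_sigma"] = float(np.einsum("m,mi,mi->", sig, W, SA))
        if params.has_zero_state and params.phi_psi > 0:
            SB = np.add.reduceat(dB, starts, axis=1)
            grad["lnphi_psi"] = float(np.einsum("m,mi,mi->", psi, W, SB))
    return L_i, grad


def _panel_loglik(
    data: PanelDataset,
    params: ZinbReParams,
    quad_order: int,
    want_grad: bool = False,
):
    """Marginal log-likelihood (and gradient) over a panel (see
    :func:`_marginal_core`)."""
    Xnb = data.count_matrix()
    if len(params.beta_nb) != Xnb.shape[1]:
        raise ConfigError("beta_nb length does not match count design (+intercept)")
    Xz = None
    if params.has_zero_state:
        Xz = data.zero_matrix()
        if len(params.beta_z) != Xz.shape[1]:
            raise ConfigError("beta_z length does not match zero design (+intercept)")
    return _marginal_core(
        data.counts,
        data.site_starts,
        data.site_codes,
        Xnb,
        Xz,
        params,
        quad_order,
        want_grad,
    )


def site_marginal_loglik(
    site_rows: PanelDataset, params: ZinbReParams, quad_order: int = 15
) -> float:
    """Marginal log-likelihood contribution of a single site.

    log Int Int prod_t ZINB(n_it | lambda_it(sigma), q_it(psi), alpha)
    N(sigma; 0, phi_sigma^2) N(psi; 0, phi_psi^2) d sigma d psi, by
    Gauss-Hermite product quadrature (point mass when a phi is 0).
    """
    if site_rows.n_sites != 1:
        raise ConfigError("site_marginal_loglik expects rows from a single site")
    L_i, _ = _panel_loglik(site_rows, params, quad_order)
    return float(L_i[0])


def total_loglik(
    data: PanelDataset, params: ZinbReParams, quad_order: int = 15
) -> float:
    """Sum of site marginal log-likelihoods over the panel."""
    try:
        L_i, _ = _panel_loglik(data, params, quad_order)
    except EstimationError as err:
        raise EstimationError(f"{err} (panel evaluation)") from err
    return float(np.sum(L_i))


def observation_logdensity(
    data: PanelDataset, params: ZinbReParams, quad_order: int = 15
) -> np.ndarray:
    """Per-observation marginal log density f(y_it | x_it).

    For random-effects parameters the site effect is integrated out at the
    observation level (each row treated as its own one-row site) — the
    marginal single-observation density used for per-row density ratios.
    Pooled parameters reduce to the plain ZINB/NB log pmf.
    """
    y = data.counts
    eta_nb, _ = _clip_eta(data.count_matrix() @ params.beta_nb)
    if params.has_zero_state:
        eta_z, _ = _clip_eta(data.zero_matrix() @ params.beta_z)
    else:
        eta_z = None
    lnalpha = math.log(params.alpha) if params.has_nb else None
    sig, psi, logw = _effect_nodes(params, quad_order)
    llam = eta_nb[None, :] + sig[:, None]
    s = eta_z[None, :] + psi[:, None] if eta_z is not None else None
    logf, *_ = _row_logf(y, llam, s, lnalpha)
    return logsumexp(logw[:, None] + logf, axis=0)
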