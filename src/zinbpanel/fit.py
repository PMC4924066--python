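"""Maximum (marginal) likelihood estimation of the count-model ladder
Poisson -> NB -> ZIP -> ZINB -> ZINB with site random effects.

Estimation is by quasi-Newton (L-BFGS-B) on an unconstrained internal scale:
ln(alpha), ln(phi_sigma), ln(phi_psi) guarantee positivity.  Initialization is
staged along the ladder — each model starts from the maximizer of its parent:

* Poisson: intercept at log(mean count), slopes 0;
* NB: Poisson solution, alpha from the method of moments;
* ZIP/ZINB: parent solution, zero-state intercept from the excess-zero
  fraction, zero-state slopes 0;
* ZINB-RE: ZINB solution, phi from the between-site spread of site-level
  residual log-means.

Zero-inflated likelihoods are multi-modal; the ladder keeps each start in the
basin of the interpretable optimum.  Gradients of the marginal likelihood are
analytic by default (exact, verified against finite differences in the test
suite); a central-difference numeric mode is available.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .data import PanelDataset
from .model import ConfigError, ZinbReParams, _marginal_core, linear_predictors

logger = logging.getLogger("zinbpanel")

MODEL_LABELS = ("poisson", "nb", "zip", "zinb", "zinb_re")

# internal-scale bounds keep quadrature nodes finite; hitting one is a
# boundary (degenerate) fit, flagged rather than erroring
LNALPHA_BOUNDS = (math.log(1e-6), 10.0)
LNPHI_BOUNDS = (math.log(1e-4), 3.0)


@dataclasses.dataclass
class OptimizerConfig:
    """Optimizer and quadrature settings for :func:`fit`."""

    max_iter: int = 500
    gradient: str = "analytic"  # or "numeric" (central differences)
    gtol: float = 1e-6
    ftol: float = 1e-12
    seed: int = 0
    quad_order: int = 15

    def __post_init__(self) -> None:
        if self.gtol <= 0 or self.ftol <= 0:
            raise ConfigError("tolerances must be > 0")
        if self.gradient not in ("analytic", "numeric"):
            raise ConfigError("gradient must be 'analytic' or 'numeric'")


class _Layout:
    """Mapping between the flat internal parameter vector and ZinbReParams."""

    def __init__(self, model_label: str, p_nb: int, p_z: int, re_mode: str):
        if model_label not in MODEL_LABELS:
            raise ConfigError(f"unknown model label {model_label!r}")
        self.model_label = model_label
        self.p_nb = p_nb
        self.has_zi = model_label in ("zip", "zinb", "zinb_re")
        self.p_z = p_z if self.has_zi else 0
        self.has_alpha = model_label in ("nb", "zinb", "zinb_re")
        if model_label == "zinb_re":
            if re_mode not in ("sigma", "psi", "both"):
                raise ConfigError("re_mode must be 'sigma', 'psi' or 'both'")
            self.has_phi_sigma = re_mode in ("sigma", "both")
            self.has_phi_psi = re_mode in ("psi", "both")
        else:
            self.has_phi_sigma = self.has_phi_psi = False
        names = [f"nb:{i}" for i in range(self.p_nb)]
        if self.has_zi:
            names += [f"zero:{i}" for i in range(self.p_z)]
        if self.has_alpha:
            names.append("alpha")
        if self.has_phi_sigma:
            names.append("phi_sigma")
        if self.has_phi_psi:
            names.append("phi_psi")
        self.names = names
        self.k = len(names)

    def pack(self, params: ZinbReParams) -> np.ndarray:
        theta = list(params.beta_nb)
        if self.has_zi:
            theta += list(params.beta_z)
        if self.has_alpha:
            theta.append(math.log(params.alpha))
        if self.has_phi_sigma:
            theta.append(math.log(max(params.phi_sigma, 1e-4)))
        if self.has_phi_psi:
            theta.append(math.log(max(params.phi_psi, 1e-4)))
        return np.asarray(theta, dtype=float)

    def unpack(self, theta: np.ndarray) -> ZinbReParams:
        i = self.p_nb
        beta_nb = theta[:i]
        beta_z = None
        if self.has_zi:
            beta_z = theta[i : i + self.p_z]
            i += self.p_z
        alpha = None
        if self.has_alpha:
            alpha = math.exp(theta[i])
            i += 1
        phi_s = phi_p = 0.0
        if self.has_phi_sigma:
            phi_s = math.exp(theta[i])
            i += 1
        if self.has_phi_psi:
            phi_p = math.exp(theta[i])
        return ZinbReParams(beta_nb, beta_z, alpha, phi_s, phi_p)

    def grad_vector(self, grad: dict) -> np.ndarray:
        g = list(grad["beta_nb"])
        if self.has_zi:
            g += list(grad["beta_z"])
        if self.has_alpha:
            g.append(grad["lnalpha"])
        if self.has_phi_sigma:
            g.append(grad.get("lnphi_sigma", 0.0))
        if self.has_phi_psi:
            g.append(grad.get("lnphi_psi", 0.0))
        return np.asarray(g, dtype=float)

    def bounds(self):
        b = [(None, None)] * (self.p_nb + self.p_z)
        if self.has_alpha:
            b.append(LNALPHA_BOUNDS)
        if self.has_phi_sigma:
            b.append(LNPHI_BOUNDS)
        if self.has_phi_psi:
            b.append(LNPHI_BOUNDS)
        return b


@dataclasses.dataclass
class FitResult:
    """A fitted model: estimates, uncertainty, fit statistics, diagnostics."""

    model_label: str
    params: ZinbReParams
    param_names: list
    theta: np.ndarray  # internal scale (ln alpha, ln phi)
    estimates: np.ndarray  # reported scale
    se: Optional[np.ndarray]
    tstats: Optional[np.ndarray]
    pvalues: Optional[np.ndarray]
    loglik: float
    neg2ll: float
    aic: float
    bic: float
    k_free: int
    n_obs: int
    n_sites: int
    converged: bool
    n_iter: int
    message: str
    boundary: list
    se_flag: str  # "ok", "pseudo_inverse", "unavailable"
    re_mode: Optional[str]
    quad_order: int
    count_design: list
    zero_design: list

    def coef_table(self):
        """Estimates with SEs, t-statistics and p-values as a DataFrame."""
        import pandas as pd

        def label(n):
            state, _, idx = n.partition(":")
            if state == "nb":
                names = ["const"] + list(self.count_design)
                return ("count-state", names[int(idx)])
            if state == "zero":
                names = ["const"] + list(self.zero_design)
                return ("zero-state", names[int(idx)])
            return ("dispersion/effects", n)

        rows = []
        for j, n in enumerate(self.param_names):
            state, name = label(n)
            rows.append(
                {
                    "state": state,
                    "variable": name,
                    "estimate": self.estimates[j],
                    "se": self.se[j] if self.se is not None else np.nan,
                    "t": self.tstats[j] if self.tstats is not None else np.nan,
                    "p": self.pvalues[j] if self.pvalues is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def information_criteria(fit: FitResult) -> tuple[float, float, float]:
    """(AIC, BIC, -2LL) with AIC = -2LL + 2k and BIC = -2LL + k ln N."""
    return fit.aic, fit.bic, fit.neg2ll


def _ic(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    neg2ll = -2.0 * loglik
    return neg2ll + 2.0 * k, neg2ll + k * math.log(n) if n > 0 else neg2ll, neg2ll


# ---------------------------------------------------------------------------
# staged initialization
# ---------------------------------------------------------------------------


def _excess_zero_logit(y: np.ndarray, p0_model: np.ndarray) -> float:
    p0_obs = float(np.mean(y == 0))
    p0_fit = float(np.mean(p0_model))
    q0 = (p0_obs - p0_fit) / max(1.0 - p0_fit, 1e-12)
    q0 = min(max(q0, 0.01), 0.95)
    return math.log(q0 / (1.0 - q0))


def _initial_theta(
    data: PanelDataset, layout: _Layout, config: OptimizerConfig, re_mode: str
) -> np.ndarray:
    y = data.counts
    label = layout.model_label
    if label == "poisson":
        theta = np.zeros(layout.k)
        theta[0] = math.log(max(float(np.mean(y)), 1e-8))
        return theta
    if label == "nb":
        parent = fit(data, "poisson", config, compute_se=False)
        m = float(np.mean(y))
        v = float(np.var(y, ddof=1))
        alpha0 = min(max((v - m) / max(m * m, 1e-12), 0.01), 50.0)
        return np.r_[parent.params.beta_nb, math.log(alpha0)]
    if label in ("zip", "zinb"):
        parent_label = "poisson" if label == "zip" else "nb"
        parent = fit(data, parent_label, config, compute_se=False)
        lp = linear_predictors(data, parent.params)
        if label == "zip":
            p0 = np.exp(-lp.lambda_it)
        else:
            r = 1.0 / parent.params.alpha
            p0 = np.exp(r * (np.log(r) - np.log(r + lp.lambda_it)))
        bz0 = np.zeros(layout.p_z)
        bz0[0] = _excess_zero_logit(y, p0)
        theta = np.r_[parent.params.beta_nb, bz0]
        if layout.has_alpha:
            theta = np.r_[theta, math.log(parent.params.alpha)]
        return theta
    # zinb_re: start from the pooled ZINB, phi from between-site residual spread
    parent = fit(data, "zinb", config, compute_se=False)
    lp = linear_predictors(data, parent.params)
    mu = (1.0 - lp.q_it) * lp.lambda_it
    # site-level residual log-mean: log of (observed+c)/(expected+c) per site
    sums_y = np.add.reduceat(y.astype(float), data.site_starts)
    sums_mu = np.add.reduceat(mu, data.site_starts)
    ratio = np.log((sums_y + 0.5) / (sums_mu + 0.5))
    phi0 = min(max(float(np.std(ratio, ddof=1)), 0.05), 2.0)
    theta = parent.theta.copy()
    if layout.has_phi_sigma:
        theta = np.r_[theta, math.log(phi0)]
    if layout.has_phi_psi:
        theta = np.r_[theta, math.log(phi0)]
    return theta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed arrays for optimization: design matrices with non-binary
    columns mean-centered (conditioning only; estimates are mapped back to
    and reported on the original scale)."""

    def __init__(self, data: PanelDataset, layout: _Layout):
        self.y = data.counts
        self.starts = data.site_starts
        self.codes = data.site_codes
        self.Xnb, self.m_nb = self._centered(data.count_matrix())
        if layout.has_zi:
            self.Xz, self.m_z = self._centered(data.zero_matrix())
        else:
            self.Xz, self.m_z = None, None
        self.layout = layout
        # theta_original = A @ theta_centered (intercepts absorb the means)
        k = layout.k
        A = np.eye(k)
        A[0, 1 : layout.p_nb] = -self.m_nb[1:]
        if layout.has_zi:
            j0 = layout.p_nb
            A[j0, j0 + 1 : j0 + layout.p_z] = -self.m_z[1:]
        self.A = A
        self.A_inv = np.linalg.inv(A)

    @staticmethod
    def _centered(X):
        X = X.copy()
        m = np.zeros(X.shape[1])
        for j in range(1, X.shape[1]):
            col = X[:, j]
            if not np.all(np.isin(col, (0.0, 1.0))):  # leave indicators alone
                m[j] = col.mean()
                X[:, j] = col - m[j]
        return X, m

    def to_original(self, theta_c):
        return self.A @ theta_c

    def to_centered(self, theta):
        return self.A_inv @ theta

    def loglik(self, theta_c, quad_order, want_grad=False):
        params = self.layout.unpack(theta_c)
        return _marginal_core(
            self.y, self.starts, self.codes, self.Xnb, self.Xz,
            params, quad_order, want_grad,
        )


def _neg_loglik_factory(ws: _Workspace, quad_order, want_grad):
    if want_grad:

        def fun(theta_c):
            L_i, grad = ws.loglik(theta_c, quad_order, want_grad=True)
            return -float(np.sum(L_i)), -ws.layout.grad_vector(grad)

        return fun

    def fun(theta_c):
        L_i, _ = ws.loglik(theta_c, quad_order)
        return -float(np.sum(L_i))

    return fun


def fit(
    data: PanelDataset,
    model_label: str,
    config: Optional[OptimizerConfig] = None,
    re_mode: str = "sigma",
    start_params: Optional[np.ndarray] = None,
    compute_se: bool = True,
) -> FitResult:
    """Fit one model of the ladder by maximum (marginal) likelihood.

    Parameters
    ----------
    model_label
        One of ``poisson``, ``nb``, ``zip``, ``zinb``, ``zinb_re``.
    re_mode
        Which site effects the ``zinb_re`` model carries: ``sigma``
        (count state only, the default), ``psi`` or ``both``.
    start_params
        Optional internal-scale start vector; otherwise staged initialization.
    """
    config = config or OptimizerConfig()
    if model_label == "zinb_re" and not np.any(data.site_sizes >= 2):
        raise ConfigError("random effects need at least one site with >= 2 rows")
    layout = _Layout(
        model_label, len(data.count_design) + 1, len(data.zero_design) + 1, re_mode
    )
    theta0 = (
        np.asarray(start_params, dtype=float)
        if start_params is not None
        else _initial_theta(data, layout, config, re_mode)
    )
    ws = _Workspace(data, layout)

    analytic = config.gradient == "analytic"
    fun = _neg_loglik_factory(ws, config.quad_order, analytic)
    res = optimize.minimize(
        fun,
        ws.to_centered(theta0),
        method="L-BFGS-B",
        jac=True if analytic else "3-point",
        bounds=layout.bounds(),
        options={
            "maxiter": config.max_iter,
            "ftol": config.ftol,
            "gtol": config.gtol,
            "maxcor": 20,
        },
    )
    theta = ws.to_original(res.x)
    params = layout.unpack(theta)
    loglik = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        logger.warning("fit(%s) did not converge: %s", model_label, res.message)

    boundary = []
    idx = layout.p_nb + layout.p_z
    if layout.has_alpha and theta[idx] <= LNALPHA_BOUNDS[0] + 1e-6:
        boundary.append("alpha")
    j = idx + int(layout.has_alpha)
    if layout.has_phi_sigma and theta[j] <= LNPHI_BOUNDS[0] + 1e-6:
        boundary.append("phi_sigma")
    if layout.has_phi_psi and theta[-1] <= LNPHI_BOUNDS[0] + 1e-6:
        boundary.append("phi_psi")

    estimates = _reported_scale(theta, layout)
    aic, bic, neg2ll = _ic(loglik, layout.k, data.n_obs)
    out = FitResult(
        model_label=model_label,
        params=params,
        param_names=layout.names,
        theta=theta,
        estimates=estimates,
        se=None,
        tstats=None,
        pvalues=None,
        loglik=loglik,
        neg2ll=neg2ll,
        aic=aic,
        bic=bic,
        k_free=layout.k,
        n_obs=data.n_obs,
        n_sites=data.n_sites,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        boundary=boundary,
        se_flag="unavailable",
        re_mode=re_mode if model_label == "zinb_re" else None,
        quad_order=config.quad_order,
        count_design=list(data.count_design),
        zero_design=list(data.zero_design),
    )
    if compute_se:
        standard_errors(out, data)
    return out


def _reported_scale(theta: np.ndarray, layout: _Layout) -> np.ndarray:
    est = theta.copy()
    i = layout.p_nb + layout.p_z
    for flag in (layout.has_alpha, layout.has_phi_sigma, layout.has_phi_psi):
        if flag:
            est[i] = math.exp(theta[i])
            i += 1
    return est


def _jacobian_internal_to_reported(theta: np.ndarray, layout: _Layout) -> np.ndarray:
    # d reported / d internal is diagonal: identity for betas, e^theta for ln-params
    d = np.ones_like(theta)
    i = layout.p_nb + layout.p_z
    for flag in (layout.has_alpha, layout.has_phi_sigma, layout.has_phi_psi):
        if flag:
            d[i] = math.exp(theta[i])
            i += 1
    return d


def _fit_layout(fit_result: FitResult) -> _Layout:
    return _Layout(
        fit_result.model_label,
        len(fit_result.count_design) + 1,
        len(fit_result.zero_design) + 1,
        fit_result.re_mode or "sigma",
    )


def loglik_hessian(
    data: PanelDataset, fit_result: FitResult, step: float = 1e-4
) -> np.ndarray:
    """Numerical Hessian of the marginal log-likelihood, internal scale.

    Central differences of the analytic gradient, taken on the centered
    design (well-conditioned) and mapped back; symmetrized.
    """
    layout = _fit_layout(fit_result)
    ws = _Workspace(data, layout)
    theta_c = ws.to_centered(fit_result.theta)
    k = len(theta_c)

    def grad(t):
        _, g = ws.loglik(t, fit_result.quad_order, want_grad=True)
        return layout.grad_vector(g)

    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta_c[j]))
        tp = theta_c.copy()
        tm = theta_c.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    # d theta_orig = A d theta_c  =>  H_orig = A^-T H_c A^-1
    return ws.A_inv.T @ H @ ws.A_inv


def standard_errors(
    fit_result: FitResult, data: PanelDataset, step: float = 1e-4
) -> np.ndarray:
    """Standard errors from the inverse observed information.

    SEs are square roots of the diagonal of the inverse negative Hessian of
    the marginal log-likelihood, delta-method-mapped from the internal scale
    (ln alpha, ln phi) to the reported scale.  A non-positive-definite
    Hessian falls back to a pseudo-inverse and is flagged, never fabricated.
    Updates and returns ``fit_result.se``.
    """
    layout = _fit_layout(fit_result)
    ws = _Workspace(data, layout)
    theta_c = ws.to_centered(fit_result.theta)
    k = len(theta_c)

    def grad(t):
        _, g = ws.loglik(t, fit_result.quad_order, want_grad=True)
        return layout.grad_vector(g)

    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(theta_c[j]))
        tp = theta_c.copy()
        tm = theta_c.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2.0 * h)
    info = -0.5 * (H + H.T)  # observed information, centered scale
    flag = "ok"
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variances")
    except np.linalg.LinAlgError:
        logger.warning(
            "observed information not positive definite; pseudo-inverse SEs"
        )
        cov = np.linalg.pinv(info)
        flag = "pseudo_inverse"
    cov = ws.A @ cov @ ws.A.T  # back to the original (uncentered) scale
    var = np.diag(cov).copy()
    bad = var <= 0
    var[bad] = np.nan
    d = _jacobian_internal_to_reported(fit_result.theta, layout)
    se = np.sqrt(var) * d
    fit_result.se = se
    fit_result.se_flag = flag if not np.any(bad) else "unavailable"
    with np.errstate(invalid="ignore", divide="ignore"):
        fit_result.tstats = fit_result.estimates / se
        fit_result.pvalues = 2.0 * stats.norm.sf(np.abs(fit_result.tstats))
    return se
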