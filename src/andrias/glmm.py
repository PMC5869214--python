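"""Mixed-effects model battery for county-level survey summaries.

Implements, by direct maximization of the marginal likelihood with adaptive
Gauss-Hermite quadrature, the four model families the survey analysis
needs:

- binomial GLMM for counts of reporting respondents per county, with a
  province random intercept and an optional observation-level random
  effect (OLRE) absorbing extra-binomial variance;
- Poisson and negative-binomial (NB2, variance mu + mu^2/theta) GLMMs for
  the years-since-most-recent-sighting response;
- Tweedie compound Poisson-gamma GLMM (power 1 < p < 2, log link) for the
  zero-inflated nonnegative mean-years response, with the exact series
  density and the power profiled.

The marginal likelihood integrates each province intercept with adaptive
(mode- and curvature-centred) Gauss-Hermite quadrature; with an OLRE a
second, nested quadrature integrates each county's effect, exploiting the
conditional independence of counties given their province effect. Adaptive
quadrature is used rather than a Laplace approximation because provinces
here contain few counties, exactly where Laplace is least accurate.

Overdispersion is diagnosed as the sum of squared Pearson residuals
(conditional on the estimated random effects) over the residual degrees of
freedom; nested models are compared by likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import expit, gammaln, logsumexp

__all__ = [
    "ModelFit",
    "fit_binomial_glmm",
    "fit_count_glmm",
    "fit_tweedie_glmm",
    "tweedie_log_density",
    "overdispersion_ratio",
    "conditional_random_effects",
    "lr_test",
]

_SIGMA_FLOOR = 1e-8       # below this the random effect is integrated out as exactly 0
_SIGMA_REPORT_ZERO = 1e-4  # estimates below this are reported as 0
_LOG_SIGMA_BOUNDS = (-10.0, 3.0)
_LOG_DISP_BOUNDS = (-6.0, 14.0)


# ---------------------------------------------------------------------------
# Tweedie compound Poisson-gamma density (exact series)
# ---------------------------------------------------------------------------

def _tweedie_series_logbase(y: np.ndarray, phi: float, p: float) -> np.ndarray:
    """log of the mu-free series factor a(y, phi, p) for y > 0.

    The Tweedie density factorises as a(y, phi, p) * exp((y*theta - kappa)/phi)
    with theta = mu^(1-p)/(1-p), kappa = mu^(2-p)/(2-p); the series
    a(y, phi, p) = (1/y) * sum_j z^j / (Gamma(j+1) Gamma(j*alpha)),
    z = y^alpha / ((p-1)^alpha phi^(1+alpha) (2-p)), alpha = (2-p)/(p-1),
    is summed with adaptive truncation (relative tail bound 1e-10 on the
    largest term, extended until the boundary terms are negligible).
    """
    alpha = (2.0 - p) / (p - 1.0)
    logz = alpha * np.log(y) - alpha * np.log(p - 1.0) - (1.0 + alpha) * np.log(phi) \
        - np.log(2.0 - p)
    # index of the largest term (Dunn-Smyth): j* ~ y^(2-p) / (phi (2-p))
    jstar = np.maximum(y ** (2.0 - p) / (phi * (2.0 - p)), 1.0)
    jmax = int(np.ceil(jstar.max() + 10.0 * np.sqrt(jstar.max()) + 40.0))
    while True:
        j = np.arange(1, jmax + 1, dtype=float)
        terms = (
            j[None, :] * logz[:, None]
            - gammaln(j + 1.0)[None, :]
            - gammaln(j[None, :] * alpha)
        )
        peak = terms.max(axis=1, keepdims=True)
        # extend if the final term still contributes beyond the tail bound
        if np.all(terms[:, -1] - peak[:, 0] < np.log(1e-10)) or jmax > 100_000:
            break
        jmax *= 2
    return logsumexp(terms, axis=1) - np.log(y)


def tweedie_log_density(y, mu, phi: float, p: float) -> np.ndarray | float:
    """Exact log-density of the Tweedie(p) compound Poisson-gamma law.

    ``y >= 0`` observation(s), ``mu > 0`` mean(s), ``phi > 0`` dispersion,
    ``1 < p < 2`` power. At y = 0 the point mass gives
    log f = -mu^(2-p) / (phi (2-p)) exactly; for y > 0 the series
    representation is summed with adaptive truncation.
    """
    if not (1.0 < p < 2.0):
        raise ValueError(f"tweedie power must lie strictly in (1, 2), got {p}")
    if phi <= 0:
        raise ValueError(f"dispersion phi must be positive, got {phi}")
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), y_arr.shape).copy()
    if (y_arr < 0).any():
        raise ValueError("tweedie observations must be nonnegative")
    if (mu_arr <= 0).any():
        raise ValueError("tweedie means must be positive")
    out = np.empty_like(y_arr)
    zero = y_arr == 0.0
    out[zero] = -mu_arr[zero] ** (2.0 - p) / (phi * (2.0 - p))
    if (~zero).any():
        yp = y_arr[~zero]
        mp = mu_arr[~zero]
        base = _tweedie_series_logbase(yp, phi, p)
        canon = (yp * mp ** (1.0 - p) / (1.0 - p) - mp ** (2.0 - p) / (2.0 - p)) / phi
        out[~zero] = base + canon
    return out if np.ndim(y) else float(out[0])


# ---------------------------------------------------------------------------
# county-level log-density families (value and derivatives wrt linear pred.)
# ---------------------------------------------------------------------------

class _BinomialFamily:
    """Grouped binomial; eta is the logit of the per-respondent probability."""

    nodata_response = False

    def __init__(self, y: np.ndarray, n: np.ndarray):
        self.y, self.n = y, n
        self.logcoef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)

    def _yn(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        extra = eta.ndim - 1
        sh = self.y.shape + (1,) * extra
        return self.y.reshape(sh), self.n.reshape(sh), self.logcoef.reshape(sh)

    def all(self, eta: np.ndarray):
        y, n, lc = self._yn(eta)
        p = expit(eta)
        ll = lc + y * eta - n * np.logaddexp(0.0, eta)
        d1 = y - n * p
        d2 = -n * p * (1.0 - p)
        return ll, d1, d2


class _OlreBinomialFamily:
    """Binomial marginalised over a county-level normal effect (the OLRE).

    Each call integrates the OLRE by inner adaptive Gauss-Hermite
    quadrature; derivatives wrt eta come from the same quadrature nodes
    (posterior-weighted moments of the conditional score).
    """

    def __init__(self, y, n, sigma_olre: float, nodes: np.ndarray, weights: np.ndarray):
        self.base = _BinomialFamily(y, n)
        self.sigma = sigma_olre
        self.x, self.w = nodes, weights

    def all(self, eta: np.ndarray):
        if self.sigma < _SIGMA_FLOOR:
            return self.base.all(eta)
        s2 = self.sigma**2
        # inner mode of e |-> log Bin(eta + e) - e^2 / (2 s2), by damped Newton
        e = np.zeros_like(eta)
        for _ in range(40):
            _, d1, d2 = self.base.all(eta + e)
            g1 = d1 - e / s2
            g2 = d2 - 1.0 / s2
            step = np.clip(-g1 / g2, -3.0, 3.0)
            e = e + step
            if np.max(np.abs(step)) < 1e-10:
                break
        _, _, d2m = self.base.all(eta + e)
        tau = 1.0 / np.sqrt(1.0 / s2 - d2m)
        enodes = e[..., None] + np.sqrt(2.0) * tau[..., None] * self.x
        ll_n, d1_n, d2_n = self.base.all(eta[..., None] + enodes)
        integrand = ll_n - enodes**2 / (2.0 * s2) - 0.5 * np.log(2.0 * np.pi * s2)
        lw = np.log(self.w) + self.x**2 + integrand
        m = lw.max(axis=-1, keepdims=True)
        omega = np.exp(lw - m)
        z = omega.sum(axis=-1)
        logg = np.log(np.sqrt(2.0) * tau) + m[..., 0] + np.log(z)
        om = omega / z[..., None]
        d1 = (om * d1_n).sum(axis=-1)
        # the marginal is log-concave in eta, so d2 <= 0; clip quadrature
        # round-off that would otherwise flip the curvature sign
        d2 = np.minimum((om * (d1_n**2 + d2_n)).sum(axis=-1) - d1**2, 0.0)
        return logg, d1, d2


class _PoissonFamily:
    def __init__(self, y: np.ndarray):
        self.y = y
        self.logcoef = -gammaln(y + 1)

    def _y(self, eta):
        extra = eta.ndim - 1
        sh = self.y.shape + (1,) * extra
        return self.y.reshape(sh), self.logcoef.reshape(sh)

    def all(self, eta):
        y, lc = self._y(eta)
        mu = np.exp(eta)
        ll = lc + y * eta - mu
        return ll, y - mu, -mu


class _NegBinomialFamily:
    """NB2: variance mu + mu^2/theta; log link.

    The eta-independent part is cached and the eta-dependent part is kept
    on the log1p scale, so huge theta (the Poisson limit) never feeds
    cancellation noise into finite-difference gradients.
    """

    def __init__(self, y: np.ndarray, theta: float):
        self.y, self.theta = y, theta
        self.logcoef = (
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            - y * np.log(theta)
        )

    def all(self, eta):
        extra = eta.ndim - 1
        sh = self.y.shape + (1,) * extra
        y = self.y.reshape(sh)
        lc = self.logcoef.reshape(sh)
        th = self.theta
        mu = np.exp(eta)
        ll = lc + y * eta - (y + th) * np.log1p(mu / th)
        d1 = y - (y + th) * mu / (th + mu)
        d2 = -(y + th) * th * mu / (th + mu) ** 2
        return ll, d1, d2


class _TweedieFamily:
    """Tweedie(p) with log link; the mu-free series factor is cached."""

    def __init__(self, y: np.ndarray, phi: float, p: float):
        self.y, self.phi, self.p = y, phi, p
        self.logbase = np.zeros_like(y)
        pos = y > 0
        if pos.any():
            self.logbase[pos] = _tweedie_series_logbase(y[pos], phi, p)
        self.logbase[~pos] = 0.0  # point mass handled in the canonical part

    def all(self, eta):
        extra = eta.ndim - 1
        sh = self.y.shape + (1,) * extra
        y = self.y.reshape(sh)
        lb = self.logbase.reshape(sh)
        p, phi = self.p, self.phi
        mu = np.exp(eta)
        mu1 = mu ** (1.0 - p)
        mu2 = mu ** (2.0 - p)
        ll = lb + (y * mu1 / (1.0 - p) - mu2 / (2.0 - p)) / phi
        d1 = (y * mu1 - mu2) / phi
        d2 = ((1.0 - p) * y * mu1 - (2.0 - p) * mu2) / phi
        return ll, d1, d2


# ---------------------------------------------------------------------------
# marginal likelihood with adaptive Gauss-Hermite quadrature over provinces
# ---------------------------------------------------------------------------

def _province_modes(eta, pidx, n_prov, sigma_p, fam, u0=None):
    """Posterior modes (and curvatures) of the province intercepts."""
    s2 = sigma_p**2
    u = np.zeros(n_prov) if u0 is None else u0.copy()
    for _ in range(60):
        _, d1, d2 = fam.all(eta + u[pidx])
        g1 = np.bincount(pidx, weights=d1, minlength=n_prov) - u / s2
        g2 = np.bincount(pidx, weights=d2, minlength=n_prov) - 1.0 / s2
        step = np.clip(-g1 / g2, -3.0, 3.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    _, _, d2 = fam.all(eta + u[pidx])
    h = 1.0 / s2 - np.bincount(pidx, weights=d2, minlength=n_prov)
    return u, np.maximum(h, 1e-10)


def _marginal_loglik(eta, pidx, n_prov, sigma_p, fam, nodes, weights) -> float:
    """log marginal likelihood, province intercepts integrated by AGQ."""
    if sigma_p < _SIGMA_FLOOR:
        ll, _, _ = fam.all(eta)
        return float(ll.sum())
    s2 = sigma_p**2
    u, h = _province_modes(eta, pidx, n_prov, sigma_p, fam)
    tau = 1.0 / np.sqrt(h)
    unodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes  # (P, K)
    ll_nodes, _, _ = fam.all(eta[:, None] + unodes[pidx, :])   # (C, K)
    prov_sum = np.zeros((n_prov, len(nodes)))
    np.add.at(prov_sum, pidx, ll_nodes)
    integrand = (
        prov_sum - unodes**2 / (2.0 * s2) - 0.5 * np.log(2.0 * np.pi * s2)
    )
    lw = np.log(weights) + nodes**2 + integrand
    per_prov = np.log(np.sqrt(2.0) * tau) + logsumexp(lw, axis=1)
    return float(per_prov.sum())


# ---------------------------------------------------------------------------
# fitted-model container and fitting machinery
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted hierarchical model.

    ``beta1`` is None when the county-selection-method effect is excluded
    (null models). ``dispersion`` is theta for the negative binomial and
    phi for the Tweedie. SD estimates below 1e-4 are reported as 0.
    """

    family: str
    response: str
    include_method: bool
    beta0: float
    beta1: float | None
    sigma_province: float
    sigma_olre: float | None
    dispersion: float | None
    tweedie_power: float | None
    log_likelihood: float
    n_parameters: int
    n_obs: int
    converged: bool
    quadrature_points: int

    def linear_predictor(self, method: np.ndarray) -> np.ndarray:
        eta = np.full(method.shape, self.beta0, dtype=float)
        if self.include_method and self.beta1 is not None:
            eta = eta + self.beta1 * method.astype(float)
        return eta


def _design(counties: pd.DataFrame, response: str):
    prov_codes, _ = pd.factorize(counties["province"], sort=True)
    method = counties["selection_method"].to_numpy(dtype=float)
    return method, prov_codes.astype(int), int(prov_codes.max()) + 1


def _report_sigma(s: float) -> float:
    return 0.0 if s < _SIGMA_REPORT_ZERO else float(s)


def _optimize(nll, x0_list, bounds):
    best = None
    for x0 in x0_list:
        try:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7},
            )
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:  # pragma: no cover - all starts failed
        raise RuntimeError("all optimizer starts failed")
    return best


def _starts(base: np.ndarray, n_starts: int) -> list[np.ndarray]:
    """Deterministic multi-start: the data-driven start plus variance-
    component pushes toward and away from the boundary (dodges local optima
    at sigma = 0)."""
    starts = [base]
    if n_starts >= 2:
        lo = base.copy()
        lo[-1] -= 1.5
        starts.append(lo)
    if n_starts >= 3:
        hi = base.copy()
        hi[-1] += 1.5
        if len(base) >= 3:
            hi[-2] += 0.75
        starts.append(hi)
    return starts[:n_starts]


def fit_binomial_glmm(
    counties: pd.DataFrame,
    olre: bool = False,
    include_method: bool = True,
    quadrature_points: int = 15,
    n_starts: int = 3,
    fixed_sigma_province: float | None = None,
) -> ModelFit:
    """Binomial GLMM for (n_reported, n_respondents) with a province
    random intercept and, with ``olre``, a county-level observation-level
    random effect absorbing extra-binomial variance.

    ``fixed_sigma_province`` pins the province SD instead of estimating it
    (0 gives the fixed-effects limit through the same engine).
    """
    if counties["province"].nunique() < 2:
        raise ValueError("need at least 2 provinces for a province random intercept")
    y = counties["n_reported"].to_numpy(dtype=float)
    n = counties["n_respondents"].to_numpy(dtype=float)
    method, pidx, n_prov = _design(counties, "n_reported")
    nodes, weights = np.polynomial.hermite.hermgauss(quadrature_points)

    est_sig = fixed_sigma_province is None
    pooled = np.clip(y.sum() / n.sum(), 1e-3, 1 - 1e-3)
    base = [special.logit(pooled)]
    if include_method:
        base.append(0.0)
    if est_sig:
        base.append(np.log(0.4))
    if olre:
        base.append(np.log(0.4))
    nb = 2 if include_method else 1
    olre_idx = nb + (1 if est_sig else 0)
    bounds = [(-20, 20)] * nb + [_LOG_SIGMA_BOUNDS] * (len(base) - nb)

    def nll(params):
        beta0 = params[0]
        beta1 = params[1] if include_method else 0.0
        sig_p = np.exp(params[nb]) if est_sig else float(fixed_sigma_province)
        eta = beta0 + beta1 * method
        if olre:
            sig_o = np.exp(params[olre_idx])
            fam = _OlreBinomialFamily(y, n, sig_o, nodes, weights)
        else:
            fam = _BinomialFamily(y, n)
        return -_marginal_loglik(eta, pidx, n_prov, sig_p, fam, nodes, weights)

    res = _optimize(nll, _starts(np.array(base), n_starts), bounds)
    sig_p = float(np.exp(res.x[nb])) if est_sig else float(fixed_sigma_province)
    sig_o = float(np.exp(res.x[olre_idx])) if olre else None
    n_params = nb + (1 if est_sig else 0) + (1 if olre else 0)
    return ModelFit(
        family="binomial",
        response="n_reported",
        include_method=include_method,
        beta0=float(res.x[0]),
        beta1=float(res.x[1]) if include_method else None,
        sigma_province=_report_sigma(sig_p),
        sigma_olre=_report_sigma(sig_o) if olre else None,
        dispersion=None,
        tweedie_power=None,
        log_likelihood=float(-res.fun),
        n_parameters=n_params,
        n_obs=len(counties),
        converged=bool(res.success),
        quadrature_points=quadrature_points,
    )


def fit_count_glmm(
    counties: pd.DataFrame,
    response: str = "min_years_ago",
    family: str = "poisson",
    include_method: bool = True,
    quadrature_points: int = 15,
    n_starts: int = 3,
    fixed_theta: float | None = None,
    fixed_sigma_province: float | None = None,
) -> ModelFit:
    """Poisson or NB2 GLMM (log link) with a province random intercept.

    Counties with missing response are excluded. ``fixed_theta`` pins the
    NB2 size parameter instead of estimating it (useful for checking the
    NB -> Poisson limit); ``fixed_sigma_province`` pins the province SD.
    """
    if family not in {"poisson", "negbinomial"}:
        raise ValueError(f"family must be 'poisson' or 'negbinomial', got {family!r}")
    keep = counties[response].notna()
    sub = counties.loc[keep]
    if sub["province"].nunique() < 2:
        raise ValueError("need at least 2 provinces for a province random intercept")
    y = sub[response].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError(f"{response!r} must be nonnegative integers for {family}")
    method, pidx, n_prov = _design(sub, response)
    nodes, weights = np.polynomial.hermite.hermgauss(quadrature_points)

    est_theta = family == "negbinomial" and fixed_theta is None
    est_sig = fixed_sigma_province is None
    base = [np.log(max(y.mean(), 0.1))]
    if include_method:
        base.append(0.0)
    if est_sig:
        base.append(np.log(0.4))
    if est_theta:
        base.append(np.log(1.0))
    nb = 2 if include_method else 1
    theta_idx = nb + (1 if est_sig else 0)
    bounds = [(-20, 20)] * nb + ([_LOG_SIGMA_BOUNDS] if est_sig else []) \
        + ([_LOG_DISP_BOUNDS] if est_theta else [])

    def nll(params):
        beta0 = params[0]
        beta1 = params[1] if include_method else 0.0
        sig_p = np.exp(params[nb]) if est_sig else float(fixed_sigma_province)
        eta = beta0 + beta1 * method
        if family == "poisson":
            fam = _PoissonFamily(y)
        else:
            theta = np.exp(params[theta_idx]) if est_theta else float(fixed_theta)
            fam = _NegBinomialFamily(y, theta)
        return -_marginal_loglik(eta, pidx, n_prov, sig_p, fam, nodes, weights)

    res = _optimize(nll, _starts(np.array(base), n_starts), bounds)
    theta_hat = None
    if family == "negbinomial":
        theta_hat = float(np.exp(res.x[theta_idx])) if est_theta else float(fixed_theta)
    sig_p = float(np.exp(res.x[nb])) if est_sig else float(fixed_sigma_province)
    n_params = nb + (1 if est_sig else 0) + (1 if est_theta else 0)
    return ModelFit(
        family=family,
        response=response,
        include_method=include_method,
        beta0=float(res.x[0]),
        beta1=float(res.x[1]) if include_method else None,
        sigma_province=_report_sigma(sig_p),
        sigma_olre=None,
        dispersion=theta_hat,
        tweedie_power=None,
        log_likelihood=float(-res.fun),
        n_parameters=n_params,
        n_obs=int(keep.sum()),
        converged=bool(res.success),
        quadrature_points=quadrature_points,
    )


def fit_tweedie_glmm(
    counties: pd.DataFrame,
    response: str = "mean_years_ago",
    include_method: bool = True,
    quadrature_points: int = 15,
    n_starts: int = 2,
    power_grid: tuple[float, ...] = (1.2, 1.35, 1.5, 1.65, 1.8),
    refine_power: bool = True,
    fixed_sigma_province: float | None = None,
) -> ModelFit:
    """Tweedie GLMM (log link) with a province random intercept.

    The Tweedie power p is profiled: (beta, sigma, phi) are maximized at
    each grid value of p, then p is refined by bounded scalar search
    between the best grid point's neighbours (bounds clipped to
    (1.05, 1.95)). ``fixed_sigma_province`` pins the province SD.
    """
    keep = counties[response].notna()
    sub = counties.loc[keep]
    if sub["province"].nunique() < 2:
        raise ValueError("need at least 2 provinces for a province random intercept")
    y = sub[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError(f"{response!r} must be nonnegative for a Tweedie model")
    method, pidx, n_prov = _design(sub, response)
    nodes, weights = np.polynomial.hermite.hermgauss(quadrature_points)
    nb = 2 if include_method else 1
    est_sig = fixed_sigma_province is None
    phi_idx = nb + (1 if est_sig else 0)
    bounds = [(-20, 20)] * nb + ([_LOG_SIGMA_BOUNDS] if est_sig else []) \
        + [_LOG_DISP_BOUNDS]
    base = [np.log(max(y.mean(), 0.1))]
    if include_method:
        base.append(0.0)
    if est_sig:
        base.append(np.log(0.4))
    base.append(np.log(1.0))

    def fit_at_p(p: float):
        def nll(params):
            beta0 = params[0]
            beta1 = params[1] if include_method else 0.0
            sig_p = np.exp(params[nb]) if est_sig else float(fixed_sigma_province)
            phi = np.exp(params[phi_idx])
            fam = _TweedieFamily(y, phi, p)
            eta = beta0 + beta1 * method
            return -_marginal_loglik(eta, pidx, n_prov, sig_p, fam, nodes, weights)

        return _optimize(nll, _starts(np.array(base), n_starts), bounds)

    grid = sorted(power_grid)
    profile = [(p, fit_at_p(p)) for p in grid]
    k = int(np.argmin([r.fun for _, r in profile]))
    p_best, res_best = profile[k]
    if refine_power:
        lo = grid[k - 1] if k > 0 else max(1.05, grid[0] - 0.15)
        hi = grid[k + 1] if k < len(grid) - 1 else min(1.95, grid[-1] + 0.15)
        cache: dict[float, optimize.OptimizeResult] = {p_best: res_best}

        def prof(p: float) -> float:
            p = float(np.clip(p, 1.05, 1.95))
            if p not in cache:
                cache[p] = fit_at_p(p)
            return cache[p].fun

        scal = optimize.minimize_scalar(
            prof, bounds=(lo, hi), method="bounded",
            options={"xatol": 5e-3, "maxiter": 20},
        )
        p_ref = float(np.clip(scal.x, 1.05, 1.95))
        if prof(p_ref) < res_best.fun:
            p_best, res_best = p_ref, cache[p_ref]

    return ModelFit(
        family="tweedie",
        response=response,
        include_method=include_method,
        beta0=float(res_best.x[0]),
        beta1=float(res_best.x[1]) if include_method else None,
        sigma_province=_report_sigma(
            float(np.exp(res_best.x[nb])) if est_sig else float(fixed_sigma_province)
        ),
        sigma_olre=None,
        dispersion=float(np.exp(res_best.x[phi_idx])),
        tweedie_power=float(p_best),
        log_likelihood=float(-res_best.fun),
        n_parameters=(nb + 3) if est_sig else (nb + 2),  # sigma, phi, p
        n_obs=int(keep.sum()),
        converged=bool(res_best.success),
        quadrature_points=quadrature_points,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _family_for_fit(fit: ModelFit, counties: pd.DataFrame):
    if fit.family == "binomial":
        y = counties["n_reported"].to_numpy(dtype=float)
        n = counties["n_respondents"].to_numpy(dtype=float)
        return _BinomialFamily(y, n), y, n
    y = counties[fit.response].to_numpy(dtype=float)
    if fit.family == "poisson":
        return _PoissonFamily(y), y, None
    if fit.family == "negbinomial":
        return _NegBinomialFamily(y, fit.dispersion), y, None
    raise ValueError(f"no residual support for family {fit.family!r}")


def conditional_random_effects(fit: ModelFit, counties: pd.DataFrame):
    """Posterior modes of the province intercepts (and OLRE values) at the
    fitted parameters; used for conditional Pearson residuals."""
    sub = counties
    if fit.family in {"poisson", "negbinomial"}:
        sub = counties[counties[fit.response].notna()]
    fam, y, n = _family_for_fit(fit, sub)
    method, pidx, n_prov = _design(sub, fit.response)
    eta = fit.linear_predictor(method)
    sig_p = max(fit.sigma_province, 0.0)
    sig_o = fit.sigma_olre if fit.sigma_olre is not None else 0.0
    u = np.zeros(n_prov)
    e = np.zeros(len(sub))
    for _ in range(80):
        # block coordinate ascent on the joint posterior mode
        if sig_p >= _SIGMA_FLOOR:
            u_new, _ = _province_modes(eta + e, pidx, n_prov, sig_p, fam, u0=u)
        else:
            u_new = u
        if sig_o >= _SIGMA_FLOOR:
            et = eta + u_new[pidx]
            e_new = e.copy()
            for _ in range(40):
                _, d1, d2 = fam.all(et + e_new)
                g1 = d1 - e_new / sig_o**2
                g2 = d2 - 1.0 / sig_o**2
                step = np.clip(-g1 / g2, -3.0, 3.0)
                e_new = e_new + step
                if np.max(np.abs(step)) < 1e-10:
                    break
        else:
            e_new = e
        delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(e_new - e)))
        u, e = u_new, e_new
        if delta < 1e-9:
            break
    return u, e, pidx


def overdispersion_ratio(fit: ModelFit, counties: pd.DataFrame) -> float:
    """Sum of squared Pearson residuals (conditional on the estimated
    random effects) over the residual degrees of freedom
    n - n_fixed - n_variance_components. Values near 1 indicate the
    assumed variance function holds; values well above 1, overdispersion.
    """
    sub = counties
    if fit.family in {"poisson", "negbinomial"}:
        sub = counties[counties[fit.response].notna()]
    fam, y, n = _family_for_fit(fit, sub)
    u, e, pidx = conditional_random_effects(fit, sub)
    method = sub["selection_method"].to_numpy(dtype=float)
    eta = fit.linear_predictor(method) + u[pidx] + e
    n_fixed = 2 if fit.include_method else 1
    n_varcomp = 1 + (1 if fit.sigma_olre is not None else 0)
    rdf = len(sub) - n_fixed - n_varcomp
    if rdf <= 0:
        raise ValueError(f"residual degrees of freedom {rdf} <= 0")
    if fit.family == "binomial":
        p = expit(eta)
        resid = (y - n * p) / np.sqrt(n * p * (1.0 - p))
    elif fit.family == "poisson":
        mu = np.exp(eta)
        resid = (y - mu) / np.sqrt(mu)
    else:  # negbinomial
        mu = np.exp(eta)
        resid = (y - mu) / np.sqrt(mu + mu**2 / fit.dispersion)
    return float((resid**2).sum() / rdf)


def pearson_dispersion(residuals, residual_df: int) -> float:
    """Dispersion ratio from precomputed Pearson residuals."""
    if residual_df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    r = np.asarray(residuals, dtype=float)
    return float((r**2).sum() / residual_df)


def lr_test(fit_null: ModelFit, fit_alt: ModelFit) -> dict:
    """Likelihood-ratio test of nested fits.

    chi2 = max(0, 2 (ll_alt - ll_null)); df is the parameter-count
    difference; p from the chi-squared tail. When the test concerns a
    variance component the naive reference is anti-conservative at the
    boundary, so the 50:50 mixture p is also reported (``p_boundary``).
    """
    df = fit_alt.n_parameters - fit_null.n_parameters
    if df <= 0:
        raise ValueError(
            f"models are not nested: alt has {fit_alt.n_parameters} parameters, "
            f"null has {fit_null.n_parameters}"
        )
    if not (fit_null.converged and fit_alt.converged):
        warnings.warn("likelihood-ratio test on a non-converged fit", RuntimeWarning)
    delta = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if delta < 0:
        if delta < -1e-6:
            warnings.warn(
                f"alternative log-likelihood below null by {-delta/2:.3g}; "
                "chi2 clamped to 0", RuntimeWarning,
            )
        delta = 0.0
    p = float(stats.chi2.sf(delta, df)) if delta > 0 else 1.0
    p_boundary = 0.5 * float(stats.chi2.sf(delta, df)) + (0.5 if delta == 0.0 else 0.0)
    return {"chi2": float(delta), "df": int(df), "p": p, "p_boundary": p_boundary}
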