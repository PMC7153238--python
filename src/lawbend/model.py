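"""Piecewise negative-binomial mixed model for policy-aligned injury rates.

The model for the event count ``y_{sm}`` of state ``s`` in standardized
month ``m`` (months since the state's law-passage month) with
athlete-exposure denominator ``AE_{sm}`` is

    y_{sm} | b_s ~ NB2(mu_{sm}, alpha)
    log mu_{sm} = log AE_{sm} + beta0 + b_s
                  + beta1 * m + gamma1 * (m - tau1)+ + gamma2 * (m - tau2)+
    b_s ~ Normal(0, sigma_b^2)

where ``(x)+ = max(x, 0)`` are truncated-line (knot) terms: the log-linear
trend keeps slope ``beta1`` up to the first change point ``tau1``, slope
``beta1 + gamma1`` between the change points, and ``beta1 + gamma1 + gamma2``
after ``tau2``.  NB2 means ``Var(y|b) = mu + alpha * mu^2``; ``alpha = 0``
degenerates to Poisson.

The state random intercept is integrated out by adaptive Gauss-Hermite
quadrature: per state the integrand is recentred at its mode and rescaled by
its curvature before applying the Hermite rule, which keeps 15 nodes
accurate even when states carry many cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import FitConfig

__all__ = [
    "KnotPair",
    "ModelParams",
    "PiecewiseNBFit",
    "knot_basis",
    "nb_glmm_loglik",
    "fit_piecewise_model",
]

_MIN_SIGMA = 1e-6  # below this the random intercept is treated as absent


@dataclass(frozen=True, order=True)
class KnotPair:
    """Ordered candidate change points on the STDM axis (``tau1 < tau2``)."""

    tau1: int
    tau2: int

    def __post_init__(self) -> None:
        if not self.tau1 < self.tau2:
            raise ValueError("KnotPair requires tau1 < tau2")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the mixed model."""

    beta0: float
    beta1: float
    gamma1: float
    gamma2: float
    dispersion: float  # NB2 alpha >= 0; 0 means Poisson
    sigma_b: float  # random-intercept SD >= 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")

    @property
    def fixed(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.gamma1, self.gamma2])


def knot_basis(stdm, knots: KnotPair):
    """Truncated-line basis ``(stdm, (stdm - tau1)+, (stdm - tau2)+)``.

    The knot terms are zero at and below their knot and grow linearly
    above it, so the fitted trend is continuous with slope breaks only.
    Accepts scalars or arrays.
    """
    m = np.asarray(stdm, dtype=float)
    h1 = np.maximum(0.0, m - knots.tau1)
    h2 = np.maximum(0.0, m - knots.tau2)
    if np.isscalar(stdm):
        return float(m), float(h1), float(h2)
    return m, h1, h2


class _CellData:
    """Canonically ordered per-state arrays extracted from an analysis table.

    Rows are sorted by (state label, stdm, count, AE) so the likelihood is
    bit-identical under any permutation of the input rows, and per-state
    log-likelihood contributions are summed in value order so relabelling
    states cannot change the total either.
    """

    def __init__(self, cells: pd.DataFrame):
        required = {"state", "stdm", "event_count", "athlete_exposures"}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"analysis table missing columns: {sorted(missing)}")
        state = cells["state"].to_numpy(dtype=object)
        stdm = cells["stdm"].to_numpy(dtype=float)
        y = cells["event_count"].to_numpy(dtype=float)
        ae = cells["athlete_exposures"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ae)) or np.any(ae <= 0):
            bad = int(np.flatnonzero(~(np.isfinite(ae) & (ae > 0)))[0])
            raise ValueError(
                f"athlete_exposures must be positive and finite; offending cell: "
                f"state={state[bad]!r} stdm={stdm[bad]:g}"
            )
        if np.any(y < 0) or np.any(~np.isfinite(y)):
            raise ValueError("event_count must be finite and non-negative")
        order = np.lexsort((ae, y, stdm, state.astype(str)))
        self.state = state[order]
        self.stdm = stdm[order]
        self.y = y[order]
        self.log_ae = np.log(ae[order])
        labels, idx = np.unique(self.state.astype(str), return_index=True)
        self.n_states = len(labels)
        self.n_cells = len(self.y)
        self.starts = np.sort(idx)
        sizes = np.diff(np.append(self.starts, self.n_cells))
        self.sizes = sizes
        self._gammaln_y1 = gammaln(self.y + 1.0)
        # Warm start for the per-state mode search; the Newton solve always
        # iterates to 1e-11 so the cached start never changes the value.
        self._b_cache: np.ndarray | None = None

    def segsum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts)

    def expand(self, per_state: np.ndarray) -> np.ndarray:
        return np.repeat(per_state, self.sizes, axis=0)


def _cell_logpmf(y, log_mu, alpha, gammaln_y1):
    """NB2 (or Poisson when alpha == 0) log pmf, elementwise."""
    mu = np.exp(log_mu)
    if alpha == 0.0:
        return y * log_mu - mu - gammaln_y1
    r = 1.0 / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln_y1
        + r * math.log(r)
        - (y + r) * np.log(r + mu)
        + y * log_mu
    )


def _cell_d1_d2(y, log_mu, alpha):
    """First and second derivatives of the cell log pmf in the intercept."""
    mu = np.exp(log_mu)
    if alpha == 0.0:
        return y - mu, -mu
    r = 1.0 / alpha
    frac = mu / (r + mu)
    return y - (y + r) * frac, -(y + r) * r * mu / (r + mu) ** 2


def _linear_predictor(fixed: np.ndarray, data: _CellData, knots: KnotPair) -> np.ndarray:
    m, h1, h2 = knot_basis(data.stdm, knots)
    return data.log_ae + fixed[0] + fixed[1] * m + fixed[2] * h1 + fixed[3] * h2


from functools import lru_cache


@lru_cache(maxsize=8)
def _hermgauss(nodes: int):
    return np.polynomial.hermite.hermgauss(nodes)


def _design(data: _CellData, knots: KnotPair) -> np.ndarray:
    m, h1, h2 = knot_basis(data.stdm, knots)
    return np.column_stack([np.ones_like(m), m, h1, h2])


def _dlogpmf_dr(y, mu, r):
    """Derivative of the NB2 cell log pmf in r = 1/alpha."""
    from scipy.special import digamma

    return (
        digamma(y + r)
        - digamma(r)
        + math.log(r)
        + 1.0
        - np.log(r + mu)
        - (y + r) / (r + mu)
    )


def _marginal_loglik(
    fixed: np.ndarray,
    alpha: float,
    sigma_b: float,
    data: _CellData,
    knots: KnotPair,
    nodes: int,
    return_grad: bool = False,
    X: np.ndarray | None = None,
):
    """Marginal log likelihood; optionally its gradient.

    The gradient is in (beta0, beta1, gamma1, gamma2, log alpha, log
    sigma_b) and is computed as the posterior-weighted score, with the
    posterior over each state's random intercept approximated on the same
    adaptive Gauss-Hermite nodes as the likelihood itself — consistent
    with the quadrature objective to quadrature accuracy.
    """
    if X is None:
        X = _design(data, knots)
    eta0 = X @ fixed + data.log_ae
    if not np.all(np.isfinite(eta0)):
        bad = int(np.flatnonzero(~np.isfinite(eta0))[0])
        raise FloatingPointError(
            f"non-finite linear predictor at cell state={data.state[bad]!r} "
            f"stdm={data.stdm[bad]:g}"
        )
    y = data.y

    if sigma_b < _MIN_SIGMA:
        per_cell = _cell_logpmf(y, eta0, alpha, data._gammaln_y1)
        ll = float(np.sum(np.sort(data.segsum(per_cell))))
        if not return_grad:
            return ll
        mu = np.exp(eta0)
        d1, _ = _cell_d1_d2(y, eta0, alpha)
        g_beta = X.T @ d1
        if alpha > 0:
            r = 1.0 / alpha
            g_la = -r * float(np.sum(_dlogpmf_dr(y, mu, r)))
        else:
            g_la = 0.0
        return ll, np.concatenate([g_beta, [g_la, 0.0]])

    s2 = sigma_b * sigma_b
    # Per-state mode of b -> Newton on a strictly concave 1-D function.
    if data._b_cache is not None and len(data._b_cache) == data.n_states:
        b = data._b_cache.copy()
    else:
        b = np.zeros(data.n_states)
    for _ in range(60):
        b_cell = data.expand(b)
        d1, d2 = _cell_d1_d2(y, eta0 + b_cell, alpha)
        grad = data.segsum(d1) - b / s2
        hess = data.segsum(d2) - 1.0 / s2
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b -= step
        if np.max(np.abs(step)) < 1e-11:
            break
    data._b_cache = b.copy()
    b_cell = data.expand(b)
    _, d2 = _cell_d1_d2(y, eta0 + b_cell, alpha)
    curv = -(data.segsum(d2) - 1.0 / s2)  # > 0
    omega = 1.0 / np.sqrt(curv)

    x, w = _hermgauss(nodes)
    z = b[:, None] + math.sqrt(2.0) * omega[:, None] * x[None, :]  # (S, K)
    z_cell = data.expand(z)  # (n, K)
    eta = eta0[:, None] + z_cell
    log_norm = -0.5 * math.log(2.0 * math.pi) - math.log(sigma_b)
    ll_cells = _cell_logpmf(y[:, None], eta, alpha, data._gammaln_y1[:, None])
    f = np.add.reduceat(ll_cells, data.starts, axis=0)  # (S, K)
    contrib = np.log(w)[None, :] + (x * x)[None, :] + f + log_norm - 0.5 * z * z / s2
    per_state = logsumexp(contrib, axis=1) + 0.5 * math.log(2.0) + np.log(omega)
    ll = float(np.sum(np.sort(per_state)))
    if not return_grad:
        return ll

    # Posterior node weights per state.
    W = np.exp(contrib - per_state[:, None] + 0.5 * math.log(2.0) + np.log(omega)[:, None])
    W_cell = data.expand(W)  # (n, K)
    mu = np.exp(eta)
    if alpha > 0:
        r = 1.0 / alpha
        frac = mu / (r + mu)
        d1 = y[:, None] - (y[:, None] + r) * frac
        g_la = -r * float(np.sum(W_cell * _dlogpmf_dr(y[:, None], mu, r)))
    else:
        d1 = y[:, None] - mu
        g_la = 0.0
    d1bar = np.sum(W_cell * d1, axis=1)  # (n,)
    g_beta = X.T @ d1bar
    g_ls = float(np.sum(W * (z * z / s2 - 1.0)))
    return ll, np.concatenate([g_beta, [g_la, g_ls]])


def nb_glmm_loglik(
    params: ModelParams,
    cells: pd.DataFrame,
    knots: KnotPair,
    config: FitConfig | None = None,
) -> float:
    """Marginal log likelihood of the piecewise NB2 mixed model.

    The state random intercept is integrated out with adaptive
    Gauss-Hermite quadrature (``config.quadrature_nodes`` nodes, default
    15). With ``sigma_b = 0`` this is exactly the sum of independent NB2
    log pmfs; with ``dispersion = 0`` the NB2 kernel degenerates to
    Poisson.
    """
    config = config or FitConfig()
    data = cells if isinstance(cells, _CellData) else _CellData(cells)
    return _marginal_loglik(
        params.fixed,
        params.dispersion,
        params.sigma_b,
        data,
        knots,
        config.quadrature_nodes,
    )


@dataclass
class PiecewiseNBFit:
    """Maximum-likelihood fit of the piecewise NB2 mixed model."""

    knots: KnotPair
    beta0: float
    beta1: float
    gamma1: float
    gamma2: float
    dispersion: float
    sigma_b: float
    loglik: float
    vcov: np.ndarray  # 4x4 covariance of (beta0, beta1, gamma1, gamma2)
    converged: bool
    n_cells: int
    n_states: int
    degenerate: bool = False
    n_function_evals: int = 0
    message: str = ""

    _COEF_INDEX = {"beta0": 0, "beta1": 1, "gamma1": 2, "gamma2": 3}

    def coef(self, name: str) -> float:
        return float(getattr(self, name))

    def se(self, name: str) -> float:
        i = self._COEF_INDEX[name]
        return float(math.sqrt(max(self.vcov[i, i], 0.0)))

    @property
    def params(self) -> ModelParams:
        return ModelParams(
            self.beta0, self.beta1, self.gamma1, self.gamma2,
            self.dispersion, self.sigma_b,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "knots": [self.knots.tau1, self.knots.tau2],
            "beta0": self.beta0,
            "beta1": self.beta1,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "dispersion": self.dispersion,
            "sigma_b": self.sigma_b,
            "loglik": self.loglik,
            "vcov": np.asarray(self.vcov).tolist(),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
            "n_cells": self.n_cells,
            "n_states": self.n_states,
            "message": self.message,
            "note": "Wald covariance; intervals unadjusted for knot selection",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PiecewiseNBFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            knots=KnotPair(*payload["knots"]),
            beta0=payload["beta0"],
            beta1=payload["beta1"],
            gamma1=payload["gamma1"],
            gamma2=payload["gamma2"],
            dispersion=payload["dispersion"],
            sigma_b=payload["sigma_b"],
            loglik=payload["loglik"],
            vcov=np.asarray(payload["vcov"], dtype=float),
            converged=payload["converged"],
            degenerate=payload.get("degenerate", False),
            n_cells=payload["n_cells"],
            n_states=payload["n_states"],
            message=payload.get("message", ""),
        )


def _poisson_start(data: _CellData, knots: KnotPair) -> np.ndarray:
    """Fixed-effect starting values from a Poisson fixed-effects GLM."""
    m, h1, h2 = knot_basis(data.stdm, knots)
    X = np.column_stack([np.ones_like(m), m, h1, h2])
    try:
        import statsmodels.api as sm

        res = sm.GLM(
            data.y, X, family=sm.families.Poisson(), offset=data.log_ae
        ).fit(maxiter=50)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return beta
    except Exception:
        pass
    # Fallback: least squares on the smoothed log rate.
    z = np.log((data.y + 0.5)) - data.log_ae
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def _start_values(data: _CellData, knots: KnotPair) -> np.ndarray:
    beta = _poisson_start(data, knots)
    eta = _linear_predictor(beta, data, knots)
    mu = np.exp(np.clip(eta, -40, 40))
    # Method-of-moments NB2 dispersion from Poisson residuals.
    num = float(np.sum((data.y - mu) ** 2 - mu))
    den = float(np.sum(mu**2))
    alpha0 = min(max(num / den if den > 0 else 0.1, 1e-3), 10.0)
    return np.concatenate([beta, [math.log(alpha0), math.log(0.3)]])


_BOUNDS = [(-40.0, 20.0), (-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0), (-12.0, 5.0), (-8.0, 3.0)]


def _check_degenerate(data: _CellData, knots: KnotPair) -> bool:
    m = data.stdm
    for tau in (knots.tau1, knots.tau2):
        if not (np.any(m <= tau) and np.any(m > tau)):
            return True
    return False


def fit_piecewise_model(
    cells: pd.DataFrame,
    knots: KnotPair,
    config: FitConfig | None = None,
    start: np.ndarray | None = None,
    compute_vcov: bool = True,
) -> PiecewiseNBFit:
    """Maximize the marginal likelihood at fixed knots.

    All six parameters (four fixed effects, NB2 dispersion, random-intercept
    SD) are estimated jointly; dispersion and SD are optimized on the log
    scale.  Starting values come from a Poisson fixed-effects fit.  The
    covariance of the fixed effects is the corresponding block of the
    inverse observed information (numerical Hessian over all six
    parameters), so slope uncertainty reflects dispersion and variance
    estimation.  Non-convergence after the configured restarts is reported
    via ``converged=False``, never silently.
    """
    config = config or FitConfig()
    data = cells if isinstance(cells, _CellData) else _CellData(cells)
    degenerate = _check_degenerate(data, knots) or data.n_states < 2
    X = _design(data, knots)

    evals = 0

    def negloglik(theta: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        fixed = theta[:4]
        alpha = math.exp(theta[4])
        sigma = math.exp(theta[5])
        try:
            ll = _marginal_loglik(
                fixed, alpha, sigma, data, knots, config.quadrature_nodes, X=X
            )
        except FloatingPointError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def negloglik_grad(theta: np.ndarray):
        nonlocal evals
        evals += 1
        fixed = theta[:4]
        alpha = math.exp(theta[4])
        sigma = math.exp(theta[5])
        try:
            with np.errstate(all="ignore"):
                ll, grad = _marginal_loglik(
                    fixed, alpha, sigma, data, knots,
                    config.quadrature_nodes, return_grad=True, X=X,
                )
        except FloatingPointError:
            return 1e12, np.zeros(6)
        if not (np.isfinite(ll) and np.all(np.isfinite(grad))):
            return 1e12, np.zeros(6)
        return -ll, -grad

    if degenerate:
        zeros = np.zeros((4, 4))
        return PiecewiseNBFit(
            knots=knots, beta0=math.nan, beta1=math.nan, gamma1=math.nan,
            gamma2=math.nan, dispersion=math.nan, sigma_b=math.nan,
            loglik=-math.inf, vcov=zeros, converged=False,
            n_cells=data.n_cells, n_states=data.n_states, degenerate=True,
            message="degenerate knots: no data strictly on both sides of a knot",
        )

    from scipy.optimize import minimize

    theta0 = np.asarray(start, dtype=float) if start is not None else _start_values(data, knots)
    theta0 = np.clip(theta0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
    rng = np.random.default_rng(config.seed)

    best = None
    attempt_start = theta0
    for attempt in range(config.n_restarts + 1):
        res = minimize(
            negloglik_grad,
            attempt_start,
            method="L-BFGS-B",
            jac=True,
            bounds=_BOUNDS,
            options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            break
        jitter = rng.normal(scale=0.3, size=6)
        attempt_start = np.clip(
            theta0 + jitter, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS]
        )

    theta = best.x.copy()
    fun = float(best.fun)
    success = bool(best.success and np.isfinite(fun))

    if config.polish and np.isfinite(fun):
        pol = minimize(
            negloglik,
            theta,
            method="Nelder-Mead",
            options={
                "maxiter": 4000,
                "xatol": 1e-8,
                "fatol": 1e-10,
                "adaptive": True,
            },
        )
        if np.isfinite(pol.fun) and pol.fun <= fun:
            theta, fun = pol.x.copy(), float(pol.fun)
            success = success or bool(pol.success)

    vcov = _fixed_effects_vcov(negloglik, theta) if compute_vcov else np.zeros((4, 4))
    return PiecewiseNBFit(
        knots=knots,
        beta0=float(theta[0]),
        beta1=float(theta[1]),
        gamma1=float(theta[2]),
        gamma2=float(theta[3]),
        dispersion=float(math.exp(theta[4])),
        sigma_b=float(math.exp(theta[5])),
        loglik=-fun,
        vcov=vcov,
        converged=success,
        n_cells=data.n_cells,
        n_states=data.n_states,
        n_function_evals=evals,
        message=str(best.message),
    )


def _fixed_effects_vcov(negloglik, theta: np.ndarray) -> np.ndarray:
    """Fixed-effects block of the inverse observed information.

    Central-difference Hessian of the negative log likelihood over all six
    parameters; the inverse is taken jointly so the reported slope variances
    account for dispersion / variance-component estimation, then the 4x4
    fixed-effects block is extracted and eigenvalue-clipped to be PSD.
    """
    n = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.empty((n, n))
    f0 = negloglik(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = negloglik(theta + ei)
                fmm = negloglik(theta - ei)
                H[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] * h[i])
            else:
                fpp = negloglik(theta + ei + ej)
                fpm = negloglik(theta + ei - ej)
                fmp = negloglik(theta - ei + ej)
                fmm = negloglik(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    block = cov_full[:4, :4]
    block = 0.5 * (block + block.T)
    vals, vecs = np.linalg.eigh(block)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T
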