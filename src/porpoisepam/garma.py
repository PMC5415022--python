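"""Generalized autoregressive moving-average (GARMA) count models.

The hourly number of detection-positive minutes is an over-dispersed,
zero-heavy, serially correlated count series.  A GARMA model couples a
GLM-style regression with autoregressive and moving-average feedback on
the link scale:

    g(mu_t) = x_t' beta
              + sum_{j=1..p} phi_j [ g(y*_{t-j}) - x_{t-j}' beta ]
              + sum_{j=1..q} theta_j [ g(y*_{t-j}) - g(mu_{t-j}) ]

with natural-log link g, conditional law Poisson, Poisson
inverse-Gaussian (PIG) or zero-inflated Poisson (ZIP), and the usual
zero-guard y* = max(y, c) so that g(0) is defined.  Cyclic daily and
annual structure enters through pairs of sinusoidal covariates
sin(2*pi*t/d), cos(2*pi*t/d) with d = 24 hours or the calendar length of
the year.

Estimation is conditional maximum likelihood: the mean recursion is run
over the observed series (restarting after recording gaps, where lagged
terms contribute zero) and the conditional log-likelihood is maximized
by quasi-Newton iterations from several seeded starting points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import lfilter
from scipy.special import ndtri

from .distributions import (
    pig_logpmf,
    pig_pmf,
    poisson_logpmf,
    zip_logpmf,
    zip_pmf,
)

__all__ = [
    "harmonic_design",
    "garma_mean_recursion",
    "simulate_garma",
    "fit_garma",
    "aic_select",
    "residual_diagnostics",
    "GarmaFit",
    "acf",
    "pacf",
]

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0  # |log-mean| bound inside the optimizer; exp(30) >> any count


def _year_length(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def harmonic_design(
    timestamps,
    terms: tuple[str, ...] = ("hour", "jday"),
) -> tuple[np.ndarray, list[str]]:
    """Build the sinusoidal design matrix for a sequence of EST timestamps.

    One sin/cos pair per requested term: ``"hour"`` uses t = hour of day
    (0..23) with period 24; ``"jday"`` uses t = Julian day (1..365/366)
    with period equal to the calendar length of that year.  An intercept
    column is always included first.

    Returns ``(X, column_names)``.
    """
    ts = pd.DatetimeIndex(timestamps)
    cols = [np.ones(len(ts))]
    names = ["intercept"]
    for term in terms:
        if term == "hour":
            t = ts.hour.to_numpy(dtype=float)
            d = 24.0
        elif term == "jday":
            t = ts.dayofyear.to_numpy(dtype=float)
            d = np.array([_year_length(y) for y in ts.year], dtype=float)
        else:
            raise ValueError(f"unknown harmonic term {term!r}")
        ang = 2.0 * np.pi * t / d
        cols += [np.sin(ang), np.cos(ang)]
        names += [f"sin_{term}", f"cos_{term}"]
    return np.column_stack(cols), names


def _shift_within_segments(x: np.ndarray, lag: int, seg_starts: np.ndarray) -> np.ndarray:
    """Shift x forward by `lag`, inserting zeros at (and after) segment starts."""
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    # positions whose lagged index falls in a different segment get zero
    idx = np.arange(len(x))
    bad = idx - lag < seg_starts[idx]
    out[bad] = 0.0
    return out


def _segment_starts(n: int, segment_ids) -> np.ndarray:
    """For each position, the index at which its contiguous segment begins."""
    if segment_ids is None:
        return np.zeros(n, dtype=int)
    seg = np.asarray(segment_ids)
    new = np.ones(n, dtype=bool)
    new[1:] = seg[1:] != seg[:-1]
    starts = np.where(new, np.arange(n), 0)
    return np.maximum.accumulate(starts)


def garma_mean_recursion(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    phi=(),
    theta=(),
    c: float = 0.1,
    segment_ids=None,
) -> np.ndarray:
    """Run the GARMA conditional-mean recursion and return mu_t.

    Lagged terms that would cross a segment boundary (a recording gap)
    contribute zero, i.e. the recursion restarts cold in each contiguous
    block of hours.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    phi = np.atleast_1d(np.asarray(phi, dtype=float)) if len(np.atleast_1d(phi)) else np.empty(0)
    theta = (
        np.atleast_1d(np.asarray(theta, dtype=float)) if len(np.atleast_1d(theta)) else np.empty(0)
    )
    n = len(y)
    starts = _segment_starts(n, segment_ids)
    eta0 = X @ beta
    gy = np.log(np.maximum(y, c))
    eta = eta0.copy()
    resid_link = gy - eta0
    for j, ph in enumerate(phi, start=1):
        eta += ph * _shift_within_segments(resid_link, j, starts)
    if len(theta):
        u = eta.copy()
        for j, th in enumerate(theta, start=1):
            u += th * _shift_within_segments(gy, j, starts)
        # g(mu_t) = u_t - sum_j theta_j g(mu_{t-j}): a linear IIR filter,
        # run independently over each contiguous segment
        a = np.concatenate(([1.0], theta))
        eta_out = np.empty(n)
        seg_bounds = np.flatnonzero(starts == np.arange(n))
        seg_bounds = np.append(seg_bounds, n)
        for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
            eta_out[s:e] = lfilter([1.0], a, u[s:e])
        eta = eta_out
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def simulate_garma(
    X: np.ndarray,
    beta,
    phi=(),
    theta=(),
    dist: str = "poisson",
    sigma: float = 0.0,
    pi: float = 0.0,
    c: float = 0.1,
    rng=None,
) -> np.ndarray:
    """Draw a count series from the GARMA data-generating process."""
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    phi = np.atleast_1d(np.asarray(phi, dtype=float)) if np.size(phi) else np.empty(0)
    theta = np.atleast_1d(np.asarray(theta, dtype=float)) if np.size(theta) else np.empty(0)
    n = X.shape[0]
    eta0 = X @ beta
    p, q = len(phi), len(theta)
    y = np.zeros(n)
    gy = np.zeros(n)
    geta = np.zeros(n)
    if dist == "pig" and sigma > 0:
        frailty = rng.wald(1.0, 1.0 / sigma, size=n)
    for t in range(n):
        eta = eta0[t]
        for j in range(1, min(p, t) + 1):
            eta += phi[j - 1] * (gy[t - j] - eta0[t - j])
        for j in range(1, min(q, t) + 1):
            eta += theta[j - 1] * (gy[t - j] - geta[t - j])
        eta = min(max(eta, -_ETA_CLIP), _ETA_CLIP)
        mu = np.exp(eta)
        if dist == "poisson":
            y[t] = rng.poisson(mu)
        elif dist == "pig":
            y[t] = rng.poisson(mu * frailty[t]) if sigma > 0 else rng.poisson(mu)
        elif dist == "zip":
            y[t] = 0 if rng.random() < pi else rng.poisson(mu)
        else:
            raise ValueError(f"unknown distribution {dist!r}")
        gy[t] = np.log(max(y[t], c))
        geta[t] = eta
    return y.astype(int)


@dataclass
class GarmaFit:
    """A fitted GARMA model."""

    dist: str
    p: int
    q: int
    beta: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    sigma: float | None
    pi: float | None
    mu: np.ndarray
    loglik: float
    aic: float
    n_params: int
    converged: bool
    se: np.ndarray
    colnames: list[str] = field(default_factory=list)
    c: float = 0.1
    quantile_residuals: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        extra = []
        if self.dist == "pig":
            extra = [self.sigma]
        elif self.dist == "zip":
            extra = [self.pi]
        return np.concatenate([self.beta, self.phi, self.theta, extra])

    def summary(self) -> dict:
        out = {
            "dist": self.dist,
            "p": self.p,
            "q": self.q,
            "beta": dict(zip(self.colnames, np.round(self.beta, 6))) if self.colnames else list(self.beta),
            "phi": list(np.round(self.phi, 6)),
            "theta": list(np.round(self.theta, 6)),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
        }
        if self.sigma is not None:
            out["sigma"] = float(self.sigma)
        if self.pi is not None:
            out["pi"] = float(self.pi)
        return out


def _loglik_terms(y, mu, dist, extra):
    if dist == "poisson":
        return poisson_logpmf(y, mu)
    if dist == "pig":
        return pig_logpmf(y, mu, extra)
    if dist == "zip":
        return zip_logpmf(y, mu, extra)
    raise ValueError(f"unknown distribution {dist!r}")


def _poisson_irls(y, X, max_iter=50, tol=1e-10):
    """Plain Poisson GLM by iteratively reweighted least squares (for inits)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.mean(y), 1e-3))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = mu
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def fit_garma(
    y,
    X,
    dist: str = "poisson",
    p: int = 0,
    q: int = 0,
    c: float = 0.1,
    segment_ids=None,
    colnames=None,
    n_restarts: int = 5,
    seed: int = 0,
    compute_residuals: bool = True,
) -> GarmaFit:
    """Fit a GARMA(p, q) model by conditional maximum likelihood.

    Parameters
    ----------
    y : integer count series (>= 50 observations)
    X : design matrix, intercept first column
    dist : "poisson", "pig" or "zip"
    p, q : autoregressive and moving-average orders
    c : zero-guard for the log link, y* = max(y, c)
    segment_ids : per-observation labels of contiguous recording blocks;
        the mean recursion restarts at each new label
    n_restarts : number of quasi-Newton starts (1 deterministic + random)
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if len(y) != n:
        raise ValueError("y and X lengths differ")
    if n < 50:
        raise ValueError("need at least 50 observations to fit a GARMA model")
    if not np.all(y >= 0):
        raise ValueError("counts must be non-negative")
    if np.all(y == 0):
        raise ValueError("degenerate all-zero series: no mean structure to estimate")

    n_extra = 1 if dist in ("pig", "zip") else 0
    k = m + p + q + n_extra

    def unpack(params):
        beta = params[:m]
        phi = params[m : m + p]
        theta = params[m + p : m + p + q]
        extra = None
        if dist == "pig":
            extra = np.exp(params[-1])
        elif dist == "zip":
            extra = 1.0 / (1.0 + np.exp(-params[-1]))
        return beta, phi, theta, extra

    def nll(params):
        beta, phi, theta, extra = unpack(params)
        mu = garma_mean_recursion(y, X, beta, phi, theta, c=c, segment_ids=segment_ids)
        ll = _loglik_terms(y, mu, dist, extra)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(np.sum(ll))

    # deterministic start: Poisson GLM betas, zero feedback, moment dispersion
    beta0 = _poisson_irls(y, X)
    start = np.concatenate([beta0, np.zeros(p + q)])
    if dist == "pig":
        ybar, s2 = np.mean(y), np.var(y)
        sig0 = max((s2 / max(ybar, 1e-6) - 1.0) / max(ybar, 1e-6), 0.01)
        start = np.append(start, np.log(sig0))
    elif dist == "zip":
        start = np.append(start, np.log(0.1 / 0.9))

    bounds = [(None, None)] * m + [(-0.95, 0.95)] * (p + q)
    if dist == "pig":
        bounds.append((-15.0, 3.0))
    elif dist == "zip":
        bounds.append((-10.0, 6.0))

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        x0 = start.copy()
        if r > 0:
            x0[:m] += rng.normal(0.0, 0.1, size=m)
            x0[m : m + p + q] = rng.uniform(-0.4, 0.4, size=p + q)
            if n_extra:
                x0[-1] += rng.normal(0.0, 0.5)
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    beta, phi, theta, extra = unpack(best.x)
    mu = garma_mean_recursion(y, X, beta, phi, theta, c=c, segment_ids=segment_ids)
    loglik = -best.fun
    aic = 2.0 * k - 2.0 * loglik
    se = _numerical_se(nll, best.x)
    if not best.success:
        logger.warning("GARMA optimizer did not report convergence: %s", best.message)

    fit = GarmaFit(
        dist=dist,
        p=p,
        q=q,
        beta=beta,
        phi=np.asarray(phi),
        theta=np.asarray(theta),
        sigma=float(extra) if dist == "pig" else None,
        pi=float(extra) if dist == "zip" else None,
        mu=mu,
        loglik=loglik,
        aic=aic,
        n_params=k,
        converged=bool(best.success),
        se=se,
        colnames=list(colnames) if colnames is not None else [],
        c=c,
    )
    if compute_residuals:
        fit.quantile_residuals = _quantile_residuals(y, mu, dist, extra, seed=seed)
    return fit


def _numerical_se(fun, x, step=1e-4):
    """Standard errors from a central-difference Hessian of the negative loglik."""
    k = len(x)
    H = np.zeros((k, k))
    h = step * (1.0 + np.abs(x))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                4.0 * h[i] * h[j]
            )
    try:
        cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(k, np.nan)


def _cdf_counts(y, mu, dist, extra):
    """CDF at y and at y-1 for a vector of counts with per-t means."""
    ymax = int(np.max(y))
    grid = np.arange(ymax + 1)
    # matrix of pmfs: n x (ymax+1)
    if dist == "poisson":
        pm = np.exp(poisson_logpmf(grid[None, :], mu[:, None]))
    elif dist == "pig":
        pm = pig_pmf(grid[None, :], mu[:, None], extra)
    else:
        pm = zip_pmf(grid[None, :], mu[:, None], extra)
    cdf = np.cumsum(pm, axis=1)
    yi = y.astype(int)
    rows = np.arange(len(y))
    F_y = cdf[rows, yi]
    F_ym1 = np.where(yi > 0, cdf[rows, np.maximum(yi - 1, 0)], 0.0)
    return F_ym1, F_y


def _quantile_residuals(y, mu, dist, extra, seed=0):
    """Randomized quantile residuals for a discrete response."""
    rng = np.random.default_rng(seed + 10_007)
    lo, hi = _cdf_counts(np.asarray(y), np.asarray(mu), dist, extra)
    u = rng.uniform(lo, np.maximum(hi, lo + 1e-12))
    u = np.clip(u, 1e-10, 1.0 - 1e-10)
    return ndtri(u)


def aic_select(fits: list[GarmaFit]) -> GarmaFit:
    """Return the minimum-AIC fit; near-ties go to the fit with fewest parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    amin = min(f.aic for f in fits)
    contenders = [f for f in fits if f.aic <= amin + 1e-9]
    return min(contenders, key=lambda f: f.n_params)


def acf(x, nlags: int) -> np.ndarray:
    """Sample autocorrelation function, lags 1..nlags."""
    x = np.asarray(x, dtype=float)
    x = x - np.mean(x)
    denom = float(np.sum(x * x))
    if denom == 0:
        return np.full(nlags, np.nan)
    return np.array([np.sum(x[k:] * x[:-k]) / denom for k in range(1, nlags + 1)])


def pacf(x, nlags: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion."""
    r = acf(x, nlags)
    if np.any(~np.isfinite(r)):
        return np.full(nlags, np.nan)
    pac = np.zeros(nlags)
    phi_prev = np.zeros(nlags + 1)
    phi_cur = np.zeros(nlags + 1)
    pac[0] = r[0]
    phi_prev[1] = r[0]
    for k in range(2, nlags + 1):
        num = r[k - 1] - np.sum(phi_prev[1:k] * r[k - 2 :: -1][: k - 1])
        den = 1.0 - np.sum(phi_prev[1:k] * r[: k - 1])
        a = num / den if den != 0 else 0.0
        phi_cur[1:k] = phi_prev[1:k] - a * phi_prev[k - 1 : 0 : -1]
        phi_cur[k] = a
        pac[k - 1] = a
        phi_prev = phi_cur.copy()
    return pac


def residual_diagnostics(fit: GarmaFit, max_lag: int = 40) -> dict:
    """ACF/PACF of the quantile residuals with the +-1.96/sqrt(n) band."""
    r = fit.quantile_residuals
    if r is None:
        raise ValueError("fit has no residuals")
    n = len(r)
    if np.std(r) == 0:
        return {"acf": np.full(max_lag, np.nan), "pacf": np.full(max_lag, np.nan),
                "band": np.nan, "degenerate": True, "n": n}
    return {
        "acf": acf(r, max_lag),
        "pacf": pacf(r, max_lag),
        "band": 1.96 / np.sqrt(n),
        "degenerate": False,
        "n": n,
    }
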