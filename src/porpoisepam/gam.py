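"""Penalized regression-spline GAMs with cyclic smoothers.

Hour-of-day and day-of-year act circularly, so their smooth effects are
represented with cyclic cubic regression splines: value-based cubic
splines on evenly spaced knots whose value, first and second derivative
match at the two ends of the period.  Non-circular covariates (sea
surface temperature, log chlorophyll, moon fraction) use natural cubic
regression splines on the same value-based construction.

Fitting is penalized iteratively reweighted least squares (PIRLS) for
binomial-logit and Gaussian-identity families.  Each smooth carries a
second-derivative penalty ``lambda * g' S g``; the smoothing parameters
are chosen by minimizing the generalized cross-validation score

    GCV = n * D / (n - EDF)^2

over a log-spaced grid, coordinate-wise across terms.  Effective degrees
of freedom are the per-term traces of the influence matrix, matching the
usual penalized-GLM definitions.

The sum-to-zero identifiability constraint on each smooth is absorbed by
reparameterizing onto the orthogonal complement of the constant knot
vector, so a fully penalized term shrinks to zero (EDF -> 0) rather than
to an unidentifiable constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SmoothTerm",
    "GamFit",
    "cyclic_basis",
    "natural_basis",
    "fit_gam",
    "confusion_matrix",
    "roc_auc",
]

logger = logging.getLogger(__name__)


@dataclass
class SmoothTerm:
    """One model term: a cyclic smooth, a natural-spline smooth, or linear."""

    name: str
    kind: str = "cyclic"  # "cyclic" | "spline" | "linear"
    period: float | None = None
    k: int = 10

    def __post_init__(self):
        if self.kind == "cyclic":
            if self.period is None or self.period <= 0:
                raise ValueError(f"cyclic term {self.name!r} needs a positive period")
        if self.kind in ("cyclic", "spline") and self.k < 4:
            raise ValueError("basis dimension k must be >= 4")


# ---------------------------------------------------------------------------
# value-based cubic regression spline machinery (Wood-style construction)
# ---------------------------------------------------------------------------


def _cyclic_matrices(knots: np.ndarray):
    """Band matrices linking knot values to knot second derivatives (cyclic)."""
    m = len(knots) - 1  # free coefficients; knot m wraps onto knot 0
    h = np.diff(knots)
    B = np.zeros((m, m))
    D = np.zeros((m, m))
    for i in range(m):
        hi = h[i]
        him1 = h[i - 1]  # wraps for i = 0
        B[i, i] = (him1 + hi) / 3.0
        B[i, (i + 1) % m] += hi / 6.0
        B[i, (i - 1) % m] += him1 / 6.0
        D[i, i] = -(1.0 / him1 + 1.0 / hi)
        D[i, (i + 1) % m] += 1.0 / hi
        D[i, (i - 1) % m] += 1.0 / him1
    return B, D


def cyclic_basis(x, period: float, k: int = 10):
    """Cyclic cubic regression spline design and penalty.

    ``k`` evenly spaced knots span ``[0, period]`` with the last knot
    identified with the first, giving ``k - 1`` coefficients equal to the
    spline's values at the free knots.  Returns ``(X, S, knots)`` where
    ``S`` is the integrated squared-second-derivative penalty.
    """
    if k < 4:
        raise ValueError("basis dimension k must be >= 4")
    x = np.asarray(x, dtype=float)
    knots = np.linspace(0.0, period, k)
    m = k - 1
    B, D = _cyclic_matrices(knots)
    Binv = np.linalg.inv(B)
    F = Binv @ D  # second derivatives at knots = F @ gamma
    S = D.T @ Binv @ D
    S = 0.5 * (S + S.T)

    xw = np.mod(x, period)
    h = period / m
    j = np.minimum((xw / h).astype(int), m - 1)
    x_j = knots[j]
    dxr = knots[j + 1] - xw  # distance to right knot
    dxl = xw - x_j
    am = dxr / h
    ap = dxl / h
    cm = (dxr**3 / h - h * dxr) / 6.0
    cp = (dxl**3 / h - h * dxl) / 6.0

    n = len(x)
    X = np.zeros((n, m))
    rows = np.arange(n)
    X[rows, j % m] += am
    X[rows, (j + 1) % m] += ap
    X += cm[:, None] * F[j % m] + cp[:, None] * F[(j + 1) % m]
    return X, S, knots


def _natural_matrices(knots: np.ndarray):
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -(1.0 / h[i] + 1.0 / h[i + 1])
        D[i, i + 2] = 1.0 / h[i + 1]
    return B, D


def natural_basis(x, knots):
    """Natural cubic regression spline design and penalty on given knots.

    Coefficients are the spline values at the ``k`` knots (natural
    boundary conditions: zero second derivative at the end knots).
    Evaluation points beyond the knot range are clamped to the range.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    B, D = _natural_matrices(knots)
    Binv = np.linalg.inv(B)
    Fint = Binv @ D
    F = np.vstack([np.zeros(k), Fint, np.zeros(k)])  # 2nd derivs incl. natural ends
    S = D.T @ Binv @ D
    S = 0.5 * (S + S.T)

    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = knots[j + 1] - knots[j]
    dxr = knots[j + 1] - xc
    dxl = xc - knots[j]
    am = dxr / hj
    ap = dxl / hj
    cm = (dxr**3 / hj - hj * dxr) / 6.0
    cp = (dxl**3 / hj - hj * dxl) / 6.0

    n = len(x)
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    return X, S


def _constraint_null(m: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^m."""
    Q, _ = np.linalg.qr(np.ones((m, 1)), mode="complete")
    return Q[:, 1:]


class _TermBlock:
    """Constructed basis for one term, able to rebuild rows on new data."""

    def __init__(self, term: SmoothTerm, x: np.ndarray):
        self.term = term
        if term.kind == "cyclic":
            X, S, self.knots = cyclic_basis(x, term.period, term.k)
            self.Z = _constraint_null(X.shape[1])
            self.X = X @ self.Z
            self.S = self.Z.T @ S @ self.Z
            self.penalized = True
        elif term.kind == "spline":
            self.knots = np.linspace(np.min(x), np.max(x), term.k)
            if self.knots[0] == self.knots[-1]:
                raise ValueError(f"covariate {term.name!r} is constant")
            X, S = natural_basis(x, self.knots)
            self.Z = _constraint_null(X.shape[1])
            self.X = X @ self.Z
            self.S = self.Z.T @ S @ self.Z
            self.penalized = True
        elif term.kind == "linear":
            self.center = float(np.mean(x))
            self.X = (x - self.center)[:, None]
            self.S = np.zeros((1, 1))
            self.Z = None
            self.penalized = False
        else:
            raise ValueError(f"unknown term kind {term.kind!r}")
        self.ncol = self.X.shape[1]

    def design(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        if self.term.kind == "cyclic":
            X, _, _ = cyclic_basis(x_new, self.term.period, self.term.k)
            return X @ self.Z
        if self.term.kind == "spline":
            X, _ = natural_basis(x_new, self.knots)
            return X @ self.Z
        return (x_new - self.center)[:, None]


@dataclass
class GamFit:
    """A fitted penalized-spline GAM."""

    family: str
    terms: list[SmoothTerm]
    beta: np.ndarray
    lambdas: dict[str, float]
    edf: dict[str, float]
    edf_total: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    r2_adj: float
    fitted: np.ndarray
    scale: float
    aic: float
    gcv: float
    converged: bool
    separation: bool = False
    Vb: np.ndarray | None = None
    blocks: list = field(default_factory=list, repr=False)
    slices: dict[str, slice] = field(default_factory=dict, repr=False)
    data_cols: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC (Hurvich-Tsai).

        With weekly records the sample-to-parameter ratio is small and
        plain AIC is known to favour overfitted smooths; the correction
        uses k = total EDF plus one scale parameter for the Gaussian
        family.
        """
        n = len(self.fitted)
        k = self.edf_total + (1.0 if self.family == "gaussian" else 0.0)
        denom = n - k - 1.0
        if denom <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1.0) / denom

    def predict(self, data: dict) -> np.ndarray:
        """Linear predictor on new data (response scale)."""
        n = len(next(iter(data.values())))
        eta = np.full(n, self.beta[0], dtype=float)
        for blk in self.blocks:
            G = blk.design(np.asarray(data[blk.term.name], dtype=float))
            eta += G @ self.beta[self.slices[blk.term.name]]
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def term_effect(self, name: str, grid: np.ndarray):
        """Uncentered partial effect of one term on a grid, with SEs."""
        blk = next((b for b in self.blocks if b.term.name == name), None)
        if blk is None:
            raise KeyError(f"term {name!r} not in fit")
        G = blk.design(np.asarray(grid, dtype=float))
        sl = self.slices[name]
        f = G @ self.beta[sl]
        se = None
        if self.Vb is not None:
            V = self.Vb[sl, sl]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, V, G), 0.0))
        return f, se

    def summary(self) -> dict:
        return {
            "family": self.family,
            "terms": [t.name for t in self.terms],
            "edf": {k: round(v, 4) for k, v in self.edf.items()},
            "lambda": {k: float(v) for k, v in self.lambdas.items()},
            "deviance_explained": float(self.deviance_explained),
            "r2_adj": float(self.r2_adj),
            "aic": float(self.aic),
            "intercept": float(self.beta[0]),
            "n": int(len(self.fitted)),
        }


def _binomial_deviance(y, mu):
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def _pirls(y, X, S, family, max_iter=200, tol=1e-9):
    """Penalized IRLS for a fixed total penalty matrix S."""
    n, ncol = X.shape
    if family == "gaussian":
        A = X.T @ X + S
        beta = np.linalg.solve(A, X.T @ y)
        fitted = X @ beta
        dev = float(np.sum((y - fitted) ** 2))
        XtWX = X.T @ X
        F = np.linalg.solve(XtWX + S, XtWX)
        return beta, fitted, dev, F, XtWX, True

    # binomial-logit
    mu = np.clip((y + 0.5) / 2.0, 0.01, 0.99)
    eta = np.log(mu / (1.0 - mu))
    beta = np.zeros(ncol)
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / W
        XtW = X.T * W
        XtWX = XtW @ X
        beta_new = np.linalg.solve(XtWX + S, XtW @ z)
        # step-halving on the penalized deviance
        step = 1.0
        for _half in range(30):
            b_try = beta + step * (beta_new - beta) if np.isfinite(dev) else beta_new
            eta_try = np.clip(X @ b_try, -30, 30)
            mu_try = 1.0 / (1.0 + np.exp(-eta_try))
            dev_try = _binomial_deviance(y, mu_try) + float(b_try @ S @ b_try)
            if dev_try <= dev + 1e-12 or not np.isfinite(dev):
                break
            step /= 2.0
        improved = dev - dev_try
        beta, eta, mu, dev = b_try, eta_try, mu_try, dev_try
        if np.isfinite(improved) and abs(improved) < tol * (abs(dev) + 0.1):
            converged = True
            break
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    XtWX = (X.T * W) @ X
    F = np.linalg.solve(XtWX + S, XtWX)
    dev_unpen = _binomial_deviance(y, mu)
    return beta, mu, dev_unpen, F, XtWX, converged


def _assemble(blocks):
    ncols = 1 + sum(b.ncol for b in blocks)
    slices = {}
    start = 1
    for b in blocks:
        slices[b.term.name] = slice(start, start + b.ncol)
        start += b.ncol
    return ncols, slices


def _total_penalty(blocks, slices, lambdas, ncols):
    S = np.zeros((ncols, ncols))
    for b in blocks:
        if b.penalized:
            sl = slices[b.term.name]
            S[sl, sl] = lambdas[b.term.name] * b.S
    return S


def fit_gam(
    data,
    response: str,
    terms: list[SmoothTerm],
    family: str = "gaussian",
    lambda_grid=None,
    n_sweeps: int = 2,
    select_lambda: bool = True,
) -> GamFit:
    """Fit a GAM with penalized cyclic / natural spline smooths.

    Parameters
    ----------
    data : mapping of column name -> array (e.g. a DataFrame)
    response : name of the response column (binary for binomial)
    terms : list of :class:`SmoothTerm`
    family : "gaussian" or "binomial"
    lambda_grid : candidate smoothing parameters (default: 41-point log
        grid from 1e-6 to 1e8); chosen per term by GCV, coordinate-wise
        with ``n_sweeps`` sweeps.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    if family == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial response must be binary 0/1")
    for t in terms:
        if t.kind in ("cyclic", "spline") and n < 10:
            raise ValueError("need >= 10 observations per smooth term")

    blocks = [_TermBlock(t, np.asarray(data[t.name], dtype=float)) for t in terms]
    ncols, slices = _assemble(blocks)
    X = np.column_stack([np.ones(n)] + [b.X for b in blocks])
    if np.linalg.matrix_rank(X) < ncols:
        raise np.linalg.LinAlgError("singular GAM design matrix")

    if lambda_grid is None:
        lambda_grid = np.logspace(-6, 8, 41)
    lambdas = {b.term.name: 1.0 for b in blocks if b.penalized}

    def gcv_at(lam):
        S = _total_penalty(blocks, slices, lam, ncols)
        out = _pirls(y, X, S, family)
        dev, F = out[2], out[3]
        edf = float(np.trace(F))
        return n * dev / max(n - edf, 1e-3) ** 2, out

    if select_lambda and lambdas:
        for _sweep in range(n_sweeps):
            for name in lambdas:
                best_g, best_l = np.inf, lambdas[name]
                for lam_try in lambda_grid:
                    trial = dict(lambdas)
                    trial[name] = lam_try
                    g, _ = gcv_at(trial)
                    if g < best_g:
                        best_g, best_l = g, lam_try
                lambdas[name] = best_l

    gcv, (beta, fitted, dev, F, XtWX, converged) = gcv_at(lambdas)

    # per-term EDF = trace of the influence-matrix block for that term
    dF = np.diag(F)
    edf = {b.term.name: float(np.sum(dF[slices[b.term.name]])) for b in blocks}
    edf_total = float(np.trace(F))

    if family == "gaussian":
        null_dev = float(np.sum((y - np.mean(y)) ** 2))
        scale = dev / max(n - edf_total, 1e-3)
        sigma2 = dev / n
        aic = n * np.log(2.0 * np.pi * max(sigma2, 1e-300)) + n + 2.0 * (edf_total + 1.0)
        separation = False
    else:
        pbar = np.clip(np.mean(y), 1e-10, 1 - 1e-10)
        null_dev = _binomial_deviance(y, np.full(n, pbar))
        scale = 1.0
        aic = dev + 2.0 * edf_total
        separation = bool(np.any(fitted < 1e-8) or np.any(fitted > 1 - 1e-8))
        if separation:
            logger.warning("binomial GAM shows (quasi-)separation in fitted values")

    dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0
    r2_adj = 1.0 - (dev / max(n - edf_total, 1e-3)) / (null_dev / max(n - 1, 1)) if null_dev > 0 else 0.0
    S_tot = _total_penalty(blocks, slices, lambdas, ncols)
    Vb = scale * np.linalg.inv(XtWX + S_tot)

    return GamFit(
        family=family,
        terms=list(terms),
        beta=beta,
        lambdas={k: float(v) for k, v in lambdas.items()},
        edf=edf,
        edf_total=edf_total,
        deviance=float(dev),
        null_deviance=float(null_dev),
        deviance_explained=float(dev_expl),
        r2_adj=float(r2_adj),
        fitted=np.asarray(fitted),
        scale=float(scale),
        aic=float(aic),
        gcv=float(gcv),
        converged=bool(converged),
        separation=separation,
        Vb=Vb,
        blocks=blocks,
        slices=slices,
        data_cols={t.name: np.asarray(data[t.name], dtype=float) for t in terms},
    )


def select_by_aic(fits: list["GamFit"], margin: float = 2.0, corrected: bool = False) -> "GamFit":
    """AIC model choice with the usual parsimony margin.

    Candidates within ``margin`` AIC units of the minimum are regarded as
    statistically indistinguishable, and the one with the fewest terms
    (then lowest criterion value) is returned.  Without the margin a
    covariate with no real effect, shrunk to near-zero EDF, would tie the
    smaller model and be retained or dropped by sampling noise alone.
    With ``corrected=True`` the small-sample AICc is used instead.
    """
    if not fits:
        raise ValueError("no fits to select from")
    crit = (lambda f: f.aicc) if corrected else (lambda f: f.aic)
    amin = min(crit(f) for f in fits)
    contenders = [f for f in fits if crit(f) <= amin + margin]
    return min(contenders, key=lambda f: (len(f.terms), crit(f)))


def confusion_matrix(observed, predicted_prob, threshold: float = 0.5) -> dict:
    """2x2 confusion counts and per-class correct-classification rates."""
    obs = np.asarray(observed, dtype=float)
    if not np.all(np.isin(obs, (0.0, 1.0))):
        raise ValueError("observed must be binary 0/1")
    pred = np.asarray(predicted_prob, dtype=float) >= threshold
    obs = obs.astype(bool)
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    fn = int(np.sum(~pred & obs))
    tn = int(np.sum(~pred & ~obs))
    n_pos, n_neg = tp + fn, tn + fp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "threshold": threshold,
        "correct_presence": tp / n_pos if n_pos else np.nan,
        "correct_absence": tn / n_neg if n_neg else np.nan,
        "accuracy": (tp + tn) / max(len(obs), 1),
    }


def roc_auc(observed, scores) -> float:
    """Area under the ROC curve by the midrank (Mann-Whitney) statistic."""
    obs = np.asarray(observed, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(obs == 1))
    n_neg = int(np.sum(obs == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(s)  # midranks for ties
    r_pos = float(np.sum(ranks[obs == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
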