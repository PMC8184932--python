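"""Negative-binomial GLM background model for Hi-C/HiChIP contact counts.

The expected count of a bin pair (i, j) at genomic distance d is modeled on
the log scale as

    log mu_ij = beta0 + sum_k beta_k B_k(d) + beta_gc x_gc + beta_map x_map
                + beta_len x_len

where B_k are cubic B-spline basis functions of linear genomic distance
(6 degrees of freedom, inner knots at the distance quartiles of the fitted
pairs) and the pair covariates are the anchor-averaged GC content,
mappability and effective bin size, standardized per chromosome.  Counts
follow a negative binomial with variance mu + alpha * mu**2.

Fitting is a two-step procedure: fit on a distance-stratified subsample,
flag pairs whose count exceeds the 97.5% quantile of their fitted null
distribution as positive outliers (candidate non-random contacts), and
refit on the remainder.  The refit is the background used for significance
testing.

Model families: ``nb`` (default), ``ztnb`` (zero-truncated NB, fit on
positive counts only) and ``hurdle`` (logistic zero part + ZTNB positive
part).  Dispersion may be a single alpha per chromosome or a
distance-dependent lookup estimated on equal-occupancy distance strata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.interpolate import BSpline
from scipy.stats import nbinom

__all__ = [
    "SplineSpec",
    "CovariateScaler",
    "FitResult",
    "ChromFit",
    "BackgroundFit",
    "DistanceDispersion",
    "bspline_basis",
    "choose_knots",
    "fit_nb_glm",
    "two_step_fit",
    "predict_mu",
    "predict_table",
    "estimate_distance_dispersion",
    "fit_hurdle",
    "pair_covariates",
    "build_design",
    "nb_loglik",
]

# Numerical knobs (module-wide constants, surfaced here rather than a config
# module so the fitting code has a single source of truth).
MAX_OUTER_ITER = 25          # outer beta/alpha alternation
MAX_IRLS_ITER = 50           # inner IRLS iterations for beta at fixed alpha
DEVIANCE_RTOL = 1e-8         # outer convergence on relative deviance change
ALPHA_FLOOR = 1e-8           # lower bound of the dispersion search
ALPHA_POISSON = 1e-5         # below this the fit falls back to Poisson
ALPHA_CEIL = 100.0
TRIM_QUANTILE = 0.975        # null quantile above which counts are outliers
DEFAULT_SUBSAMPLE_FRAC = 0.25
DEFAULT_MIN_SUBSAMPLE = 100_000


# ---------------------------------------------------------------------------
# distance spline
# ---------------------------------------------------------------------------

@dataclass
class SplineSpec:
    """Cubic B-spline specification for the distance covariate.

    ``df`` columns are produced by dropping the first function of the full
    clamped basis (the remaining intercept direction is carried by the GLM
    constant), so with three inner knots the full basis has df + 1 = 7
    functions and satisfies the partition of unity.
    """

    inner_knots: tuple[float, ...]
    boundary: tuple[float, float]
    degree: int = 3
    df: int = 6

    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.r_[
            [lo] * (self.degree + 1),
            list(self.inner_knots),
            [hi] * (self.degree + 1),
        ]

    def to_dict(self) -> dict:
        return {
            "inner_knots": list(self.inner_knots),
            "boundary": list(self.boundary),
            "degree": self.degree,
            "df": self.df,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            inner_knots=tuple(d["inner_knots"]),
            boundary=tuple(d["boundary"]),
            degree=int(d["degree"]),
            df=int(d["df"]),
        )


def full_bspline_basis(distances: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Full clamped B-spline basis (df + 1 columns, rows sum to one).

    Distances outside the boundary knots are clamped to the boundary.
    """
    x = np.atleast_1d(np.asarray(distances, dtype=float))
    lo, hi = spec.boundary
    # clamp: strictly inside hi so the right-closed end point evaluates
    x = np.clip(x, lo, np.nextafter(hi, lo))
    t = spec.knot_vector()
    dm = BSpline.design_matrix(x, t, spec.degree, extrapolate=False).toarray()
    return dm


def bspline_basis(distances: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Distance basis used in the design matrix: full basis minus column 0."""
    return full_bspline_basis(distances, spec)[:, 1:]


def choose_knots(distances: np.ndarray, df: int = 6, degree: int = 3) -> SplineSpec:
    """Place inner knots at the 25/50/75% quantiles of linear distance.

    Quantiles use linear interpolation between order statistics.  Ties are
    deduplicated; if fewer than three distinct knots survive, knots fall back
    to equal spacing on log distance between the observed boundaries.
    """
    x = np.asarray(distances, dtype=float)
    distinct = np.unique(x)
    if distinct.size < 4:
        raise ValueError("need at least 4 distinct distances to place knots")
    lo, hi = float(distinct[0]), float(distinct[-1])
    knots = np.quantile(x, [0.25, 0.50, 0.75], method="linear")
    knots = np.unique(knots)
    knots = knots[(knots > lo) & (knots < hi)]
    if knots.size < 3:
        # heavily tied distances: log-spaced fallback
        knots = np.exp(np.linspace(np.log(max(lo, 1.0)), np.log(hi), 5))[1:-1]
    return SplineSpec(inner_knots=tuple(float(k) for k in knots), boundary=(lo, hi),
                      degree=degree, df=df)


# ---------------------------------------------------------------------------
# covariates and design
# ---------------------------------------------------------------------------

@dataclass
class CovariateScaler:
    """Per-chromosome centering/scaling of the pair covariates."""

    mean: dict[str, float]
    sd: dict[str, float]

    @classmethod
    def fit(cls, cov: pd.DataFrame, cols=("gc", "mappability", "effective_size")) -> "CovariateScaler":
        mean, sd = {}, {}
        for c in cols:
            v = cov[c].to_numpy(dtype=float)
            mean[c] = float(np.nanmean(v))
            s = float(np.nanstd(v))
            sd[c] = s if s > 0 else 1.0
        return cls(mean=mean, sd=sd)

    def transform(self, cov: pd.DataFrame) -> pd.DataFrame:
        out = cov.copy()
        for c in self.mean:
            out[c] = (cov[c] - self.mean[c]) / self.sd[c]
        return out

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateScaler":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]))


def pair_covariates(table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Anchor-averaged covariates for every bin pair of ``table``.

    ``features`` must carry columns bin_id, gc, mappability, effective_size
    and a boolean ``flagged`` column; pairs with a flagged anchor get
    ``ok = False`` and are excluded from fitting and testing.
    """
    feat = features.set_index("bin_id")
    cols = ["gc", "mappability", "effective_size"]
    fi = feat.loc[table["bin_i"].to_numpy(), cols].to_numpy(dtype=float)
    fj = feat.loc[table["bin_j"].to_numpy(), cols].to_numpy(dtype=float)
    out = pd.DataFrame(
        (fi + fj) / 2.0, columns=cols, index=table.index)
    if "flagged" in features.columns:
        flg = feat["flagged"].to_numpy(dtype=bool)
        idx = feat.index.get_indexer(table["bin_i"]), feat.index.get_indexer(table["bin_j"])
        out["ok"] = ~(flg[idx[0]] | flg[idx[1]])
    else:
        out["ok"] = True
    out["ok"] &= np.isfinite(out[cols].to_numpy(dtype=float)).all(axis=1)
    return out


DESIGN_COLS_SPLINE = ["const"] + [f"s{k}" for k in range(1, 7)] + ["gc", "map", "len"]
DESIGN_COLS_POWER = ["const", "logd", "gc", "map", "len"]


def build_design(
    distances: np.ndarray,
    cov: pd.DataFrame,
    spline: SplineSpec | None,
    scaler: CovariateScaler,
    distance_form: str = "spline",
) -> np.ndarray:
    """Assemble the GLM design matrix (constant, distance terms, covariates)."""
    n = len(distances)
    sc = scaler.transform(cov)
    covm = sc[["gc", "mappability", "effective_size"]].to_numpy(dtype=float)
    if distance_form == "spline":
        if spline is None:
            raise ValueError("spline spec required for distance_form='spline'")
        B = bspline_basis(distances, spline)
        return np.column_stack([np.ones(n), B, covm])
    elif distance_form == "power":
        logd = np.log(np.asarray(distances, dtype=float))
        logd = logd - np.mean(logd)
        return np.column_stack([np.ones(n), logd, covm])
    raise ValueError(f"unknown distance_form {distance_form!r}")


# ---------------------------------------------------------------------------
# NB likelihood machinery
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Total NB log-likelihood with var = mu + alpha mu^2 (Poisson at alpha=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    ll = (
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    )
    return float(np.sum(ll))


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        if alpha <= 0:
            dev = 2.0 * np.sum(t1 - (y - mu))
        else:
            r = 1.0 / alpha
            dev = 2.0 * np.sum(t1 - (y + r) * np.log((y + r) / (mu + r)))
    return float(dev)


def _irls_beta(
    y: np.ndarray,
    X: np.ndarray,
    alpha: float,
    beta0: np.ndarray,
    offset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for beta at fixed alpha; returns (beta, mu, converged)."""
    off = 0.0 if offset is None else offset
    beta = beta0.copy()
    eta = X @ beta + off
    mu = np.exp(np.clip(eta, -30, 30))
    dev = nb_deviance(y, mu, alpha)
    ok = False
    for _ in range(MAX_IRLS_ITER):
        w = mu / (1.0 + alpha * mu)
        z = (eta - off) + (y - mu) / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)[0]
        # step halving against divergence
        step = 1.0
        for _h in range(6):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand + off
            mu_c = np.exp(np.clip(eta_c, -30, 30))
            dev_c = nb_deviance(y, mu_c, alpha)
            if np.isfinite(dev_c) and dev_c <= dev + 1e-8 * abs(dev):
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        if abs(dev - dev_c) <= 1e-10 * (abs(dev) + 0.1):
            ok = True
            dev = dev_c
            break
        dev = dev_c
    return beta, mu, ok


def _ml_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile ML of the dispersion at fixed mu (on the log-alpha scale)."""
    def nll(loga: float) -> float:
        return -nb_loglik(y, mu, float(np.exp(loga)))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(ALPHA_FLOOR), np.log(ALPHA_CEIL)), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _trunc_logF(T: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """log P(Y <= T) under NB(mu, alpha) (Poisson at alpha = 0)."""
    if alpha <= 0:
        return np.log(np.maximum(special.pdtr(T, mu), 1e-300))
    r = 1.0 / alpha
    F = special.betainc(r, T + 1.0, r / (r + mu))
    return np.log(np.maximum(F, 1e-300))


def fit_truncated_nb(
    y: np.ndarray,
    X: np.ndarray,
    T: np.ndarray,
    init: "FitResult",
    offset: np.ndarray | None = None,
) -> "FitResult":
    """NB regression under right truncation at per-observation thresholds T.

    Maximizes sum_i [log f(y_i) - log F(T_i)] by alternating an L-BFGS beta
    update (analytic gradient) with a bounded scalar dispersion search.
    This is the consistent refit for outlier-trimmed data: the retained
    counts are exactly the sub-threshold portion of the null, and ignoring
    the truncation biases both the mean and the dispersion downward.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    off = 0.0 if offset is None else np.asarray(offset, dtype=float)

    def nll_beta(beta, alpha):
        eta = np.clip(X @ beta + off, -30, 30)
        mu = np.exp(eta)
        ll = nb_loglik(y, mu, alpha) - float(np.sum(_trunc_logF(T, mu, alpha)))
        # score wrt eta: NB score + truncation correction (pushes mu back up)
        if alpha <= 0:
            score = y - mu
            corr = np.exp(T * np.log(mu) - mu - special.gammaln(T + 1.0))
            F = np.maximum(special.pdtr(T, mu), 1e-300)
        else:
            r = 1.0 / alpha
            score = (y - mu) / (1.0 + alpha * mu)
            logq = np.log(r) - np.log(r + mu)
            log1mq = np.log(mu) - np.log(r + mu)
            logB = special.gammaln(r) + special.gammaln(T + 1.0) - special.gammaln(r + T + 1.0)
            corr = np.exp(r * logq + (T + 1.0) * log1mq - logB)
            F = np.maximum(special.betainc(r, T + 1.0, r / (r + mu)), 1e-300)
        grad = -(X.T @ (score + corr / F))
        return -ll, grad

    def nll_alpha(loga, beta):
        a = float(np.exp(loga))
        mu = np.exp(np.clip(X @ beta + off, -30, 30))
        return -(nb_loglik(y, mu, a) - float(np.sum(_trunc_logF(T, mu, a))))

    beta = init.beta.copy()
    alpha = max(init.alpha, ALPHA_FLOOR * 10)
    prev = np.inf
    converged = False
    it = 0
    for it in range(1, MAX_OUTER_ITER + 1):
        res = optimize.minimize(nll_beta, beta, args=(alpha,), jac=True,
                                method="L-BFGS-B", options={"maxiter": 100, "ftol": 1e-12})
        beta = res.x
        ares = optimize.minimize_scalar(
            nll_alpha, args=(beta,), method="bounded",
            bounds=(np.log(ALPHA_FLOOR), np.log(ALPHA_CEIL)), options={"xatol": 1e-8})
        alpha = float(np.exp(ares.x))
        cur = float(ares.fun)
        if abs(prev - cur) <= DEVIANCE_RTOL * (abs(cur) + 0.1):
            converged = True
            break
        prev = cur
    fallback = alpha <= ALPHA_POISSON
    if fallback:
        alpha = 0.0
        res = optimize.minimize(nll_beta, beta, args=(0.0,), jac=True,
                                method="L-BFGS-B", options={"maxiter": 100, "ftol": 1e-12})
        beta = res.x
    mu = np.exp(np.clip(X @ beta + off, -30, 30))
    w = mu / (1.0 + alpha * mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return FitResult(
        beta=beta, alpha=alpha, cov=cov, converged=converged, n_iter=it,
        deviance=nb_deviance(y, mu, alpha), loglik=nb_loglik(y, mu, alpha),
        poisson_fallback=fallback, n_obs=len(y),
    )


@dataclass
class FitResult:
    """One NB GLM fit: coefficients, dispersion, covariance, diagnostics."""

    beta: np.ndarray
    alpha: float
    cov: np.ndarray
    converged: bool
    n_iter: int
    deviance: float
    loglik: float
    poisson_fallback: bool = False
    n_obs: int = 0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    init: FitResult | None = None,
    offset: np.ndarray | None = None,
) -> FitResult:
    """Fit an NB regression with log link by alternating IRLS / dispersion ML.

    Beta is updated by iteratively reweighted least squares at fixed alpha;
    alpha by univariate likelihood maximization at fixed mean.  Convergence:
    relative deviance change below 1e-8 or 25 outer iterations.  If the
    dispersion collapses to the lower boundary the fit falls back to Poisson
    (alpha = 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 10 * p:
        raise ValueError(f"need at least {10 * p} observations for {p} parameters, got {n}")
    if not np.any(y > 0):
        raise ValueError("all-zero response: NB MLE does not exist")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    off = 0.0 if offset is None else np.asarray(offset, dtype=float)
    if init is not None:
        beta = init.beta.copy()
        alpha = max(init.alpha, ALPHA_FLOOR * 10)
    else:
        # moment start: regress log(y + 0.5) on X
        z0 = np.log(y + 0.5) - off
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
        alpha = 0.1

    dev_prev = np.inf
    converged = False
    fallback = False
    it = 0
    for it in range(1, MAX_OUTER_ITER + 1):
        beta, mu, _ = _irls_beta(y, X, alpha, beta, offset)
        alpha = _ml_alpha(y, mu)
        if alpha <= ALPHA_POISSON:
            alpha = 0.0
            fallback = True
            beta, mu, _ = _irls_beta(y, X, 0.0, beta, offset)
            converged = True
            break
        dev = nb_deviance(y, mu, alpha)
        if abs(dev_prev - dev) <= DEVIANCE_RTOL * (abs(dev) + 0.1):
            converged = True
            dev_prev = dev
            break
        dev_prev = dev
    eta = X @ beta + off
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    XtWX = (X.T * w) @ X
    cov = np.linalg.inv(XtWX)
    return FitResult(
        beta=beta, alpha=float(alpha), cov=cov, converged=converged, n_iter=it,
        deviance=nb_deviance(y, mu, alpha), loglik=nb_loglik(y, mu, alpha),
        poisson_fallback=fallback, n_obs=n,
    )


# ---------------------------------------------------------------------------
# zero-truncated NB and hurdle parts
# ---------------------------------------------------------------------------

def _ztnb_nll_grad(params, y, X):
    """Negative truncated log-likelihood and gradient in (beta, log alpha)."""
    beta, loga = params[:-1], params[-1]
    a = float(np.exp(loga))
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    r = 1.0 / a
    amu = a * mu
    log1p = np.log1p(amu)
    p0 = np.exp(-r * log1p)             # P(Y = 0)
    one_m = 1.0 - p0
    ll = (
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        - r * log1p + y * (np.log(mu) - log1p)
        - np.log(one_m)
    )
    # gradients
    dl_dmu = (y - mu) / (mu * (1.0 + amu)) * mu  # wrt eta after chain rule
    dtrunc_deta = mu * p0 / (one_m * (1.0 + amu))
    g_beta = -X.T @ (dl_dmu - dtrunc_deta)
    dl_da = (
        r * r * (log1p - special.digamma(y + r) + special.digamma(r))
        + (y - mu) / (a * (1.0 + amu))
    )
    dp0_da = p0 * (r * r * log1p - mu * r / (1.0 + amu))
    dl_da = dl_da + dp0_da / one_m
    g_loga = -float(np.sum(dl_da)) * a
    return -float(np.sum(ll)), np.r_[g_beta, g_loga]


def fit_ztnb_glm(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Zero-truncated NB regression (positive counts only, log link)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 1):
        raise ValueError("zero-truncated fit requires strictly positive counts")
    # warm start from the untruncated fit
    start = fit_nb_glm(y, X)
    x0 = np.r_[start.beta, np.log(max(start.alpha, 1e-4))]
    res = optimize.minimize(
        _ztnb_nll_grad, x0, args=(y, X), jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    beta, loga = res.x[:-1], res.x[-1]
    alpha = float(np.exp(loga))
    # observed-information covariance by finite differences of the gradient
    eps = 1e-5
    k = len(res.x)
    H = np.zeros((k, k))
    for i in range(k):
        xp = res.x.copy(); xp[i] += eps
        xm = res.x.copy(); xm[i] -= eps
        H[:, i] = (_ztnb_nll_grad(xp, y, X)[1] - _ztnb_nll_grad(xm, y, X)[1]) / (2 * eps)
    H = (H + H.T) / 2
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    return FitResult(
        beta=beta, alpha=alpha, cov=cov_full[:-1, :-1], converged=bool(res.success),
        n_iter=int(res.nit), deviance=np.nan, loglik=-float(res.fun), n_obs=len(y),
    )


def fit_logistic(y01: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, bool]:
    """Logistic IRLS for the hurdle zero part; ridge-stabilized on separation."""
    y01 = np.asarray(y01, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y01.mean() + 1e-6) / (1 - y01.mean() + 1e-6))
    separated = False
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1 - pi)
        if np.max(np.abs(eta)) > 25:
            separated = True
            ridge = max(ridge, 1e-4)
        z = eta + (y01 - pi) / np.maximum(w, 1e-10)
        XtW = X.T * w
        A = XtW @ X + ridge * np.eye(p)
        beta_new = np.linalg.solve(A, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta, separated


# ---------------------------------------------------------------------------
# distance-dependent dispersion
# ---------------------------------------------------------------------------

@dataclass
class DistanceDispersion:
    """Monotone-smoothed dispersion-vs-distance lookup (log-log interpolated)."""

    log_d: np.ndarray       # stratum centers, log bp
    log_alpha: np.ndarray   # isotonic-smoothed log dispersion per stratum

    def __call__(self, distances: np.ndarray) -> np.ndarray:
        ld = np.log(np.asarray(distances, dtype=float))
        return np.exp(np.interp(ld, self.log_d, self.log_alpha))

    def to_dict(self) -> dict:
        return {"log_d": self.log_d.tolist(), "log_alpha": self.log_alpha.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceDispersion":
        return cls(np.asarray(d["log_d"]), np.asarray(d["log_alpha"]))


def estimate_distance_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    distances: np.ndarray,
    n_strata: int = 10,
    min_stratum: int = 200,
) -> DistanceDispersion:
    """Per-stratum dispersion ML with fitted means held fixed.

    Distances are cut into ``n_strata`` equal-occupancy strata; strata with
    fewer than ``min_stratum`` pairs are merged into their left neighbor.
    The per-stratum estimates are smoothed by isotonic regression of
    log alpha on log distance (direction chosen by the data) and returned as
    an interpolating lookup.
    """
    from sklearn.isotonic import IsotonicRegression

    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d = np.asarray(distances, dtype=float)
    qs = np.quantile(d, np.linspace(0, 1, n_strata + 1))
    qs = np.unique(qs)
    idx = np.clip(np.searchsorted(qs, d, side="right") - 1, 0, len(qs) - 2)
    # merge small strata leftward
    order = []
    members: list[np.ndarray] = []
    for s in range(len(qs) - 1):
        m = np.where(idx == s)[0]
        if len(members) > 0 and m.size < min_stratum:
            members[-1] = np.r_[members[-1], m]
        else:
            members.append(m)
            order.append(s)
    centers, alphas = [], []
    for m in members:
        if m.size == 0:
            continue
        centers.append(float(np.exp(np.mean(np.log(d[m])))))
        alphas.append(max(_ml_alpha(y[m], mu[m]), ALPHA_FLOOR))
    centers = np.asarray(centers)
    alphas = np.asarray(alphas)
    if len(centers) == 1:
        return DistanceDispersion(np.log(centers), np.log(alphas))
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    smoothed = iso.fit_transform(np.log(centers), np.log(alphas))
    return DistanceDispersion(np.log(centers), np.asarray(smoothed))


# ---------------------------------------------------------------------------
# per-chromosome fit container and the two-step procedure
# ---------------------------------------------------------------------------

@dataclass
class ChromFit:
    """Fitted background for one chromosome."""

    chrom: str
    family: str                      # nb | ztnb | hurdle
    distance_form: str               # spline | power
    beta: np.ndarray                 # coefficients for build_design columns
    alpha: float                     # constant dispersion (ZT part for hurdle)
    spline: SplineSpec | None
    scaler: CovariateScaler
    cov: np.ndarray | None = None
    pi_beta: np.ndarray | None = None   # hurdle zero-part coefficients
    dispersion: DistanceDispersion | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def design_cols(self) -> list[str]:
        return DESIGN_COLS_SPLINE if self.distance_form == "spline" else DESIGN_COLS_POWER

    def design(self, distances: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        return build_design(distances, cov, self.spline, self.scaler, self.distance_form)

    def mu(self, distances: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        X = self.design(distances, cov)
        return np.exp(np.clip(X @ self.beta, -30, 30))

    def pair_alpha(self, distances: np.ndarray) -> np.ndarray:
        if self.dispersion is not None:
            return self.dispersion(distances)
        return np.full(len(distances), self.alpha)

    def pi(self, distances: np.ndarray, cov: pd.DataFrame) -> np.ndarray | None:
        if self.pi_beta is None:
            return None
        X = self.design(distances, cov)
        return 1.0 / (1.0 + np.exp(-np.clip(X @ self.pi_beta, -30, 30)))

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "family": self.family,
            "distance_form": self.distance_form,
            "beta": self.beta.tolist(),
            "alpha": self.alpha,
            "spline": self.spline.to_dict() if self.spline else None,
            "scaler": self.scaler.to_dict(),
            "pi_beta": self.pi_beta.tolist() if self.pi_beta is not None else None,
            "dispersion": self.dispersion.to_dict() if self.dispersion else None,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromFit":
        return cls(
            chrom=d["chrom"], family=d["family"], distance_form=d["distance_form"],
            beta=np.asarray(d["beta"]), alpha=float(d["alpha"]),
            spline=SplineSpec.from_dict(d["spline"]) if d["spline"] else None,
            scaler=CovariateScaler.from_dict(d["scaler"]),
            pi_beta=np.asarray(d["pi_beta"]) if d.get("pi_beta") is not None else None,
            dispersion=DistanceDispersion.from_dict(d["dispersion"]) if d.get("dispersion") else None,
            diagnostics=d.get("diagnostics", {}),
        )


@dataclass
class BackgroundFit:
    """Background fits per chromosome plus global fitting options."""

    fits: dict[str, ChromFit]
    options: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "options": self.options,
            "fits": {c: f.to_dict() for c, f in self.fits.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BackgroundFit":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            fits={c: ChromFit.from_dict(d) for c, d in payload["fits"].items()},
            options=payload.get("options", {}),
        )


def _stratified_subsample(
    distances: np.ndarray, frac: float, min_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Distance-stratified subsample of row indices (all rows if small)."""
    n = len(distances)
    target = max(int(np.ceil(frac * n)), min_n)
    if target >= n:
        return np.arange(n)
    order = np.argsort(distances, kind="stable")
    # systematic sampling along the distance ordering keeps strata balanced
    pos = np.linspace(0, n - 1, target)
    jitter = rng.uniform(-0.5, 0.5, size=target) * (n - 1) / target
    take = np.unique(np.clip(np.round(pos + jitter).astype(int), 0, n - 1))
    return np.sort(order[take])


def two_step_fit(
    table: pd.DataFrame,
    features: pd.DataFrame,
    family: str = "nb",
    distance_form: str = "spline",
    dispersion: str = "constant",
    n_strata: int = 10,
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC,
    min_subsample: int = DEFAULT_MIN_SUBSAMPLE,
    seed: int = 0,
    trim_quantile: float = TRIM_QUANTILE,
    trim_refit: str = "truncated",
) -> BackgroundFit:
    """Two-step outlier-trimmed background fit, independently per chromosome.

    Step 1 fits the model on a distance-stratified subsample; pairs whose
    count exceeds the ``trim_quantile`` quantile of their fitted null NB are
    flagged as positive outliers; step 2 refits without them and is the
    returned background.  Raises if more than half of all pairs are trimmed
    (a misspecification signal).

    ``trim_refit`` chooses the step-2 estimator: "truncated" (default)
    maximizes the right-truncated NB likelihood, conditioning each retained
    pair on its count not exceeding its trim threshold — the consistent
    refit for trimmed data; "plain" refits an ordinary NB likelihood to the
    remainder, which underestimates both mean and dispersion on null data.
    """
    fits: dict[str, ChromFit] = {}
    rng = np.random.default_rng(seed)
    for chrom, sub in table.groupby("chrom", sort=True):
        chrom_rng = np.random.default_rng(rng.integers(2**31))
        # canonical order: the fit must not depend on input row order
        sub = sub.sort_values(["bin_i", "bin_j"], kind="stable", ignore_index=True)
        feats = features[features["chrom"] == chrom] if "chrom" in features.columns else features
        cov = pair_covariates(sub, feats)
        ok = cov["ok"].to_numpy()
        d_all = sub["distance"].to_numpy(dtype=float)
        y_all = sub["count"].to_numpy(dtype=float)
        d, y, cov_ok = d_all[ok], y_all[ok], cov.loc[ok]

        spline = choose_knots(d) if distance_form == "spline" else None
        scaler = CovariateScaler.fit(cov_ok)
        X = build_design(d, cov_ok, spline, scaler, distance_form)

        take = _stratified_subsample(d, subsample_frac, min_subsample, chrom_rng)

        if family == "nb":
            fit1 = fit_nb_glm(y[take], X[take])
            mu_all = np.exp(np.clip(X @ fit1.beta, -30, 30))
            thr = _nb_threshold(mu_all, fit1.alpha, trim_quantile)
            trimmed = y > thr
            frac_trim = float(np.mean(trimmed))
            if frac_trim > 0.5:
                raise ValueError(
                    f"{chrom}: {frac_trim:.0%} of pairs flagged as outliers; "
                    "background model misspecified")
            keep = take[~trimmed[take]]
            if trim_refit == "truncated":
                fit2 = fit_truncated_nb(y[keep], X[keep], thr[keep], init=fit1)
            elif trim_refit == "plain":
                fit2 = fit_nb_glm(y[keep], X[keep], init=fit1)
            else:
                raise ValueError(f"unknown trim_refit {trim_refit!r}")
            cf = ChromFit(
                chrom=str(chrom), family=family, distance_form=distance_form,
                beta=fit2.beta, alpha=fit2.alpha, spline=spline, scaler=scaler,
                cov=fit2.cov,
                diagnostics={
                    "converged": fit2.converged, "n_iter": fit2.n_iter,
                    "n_fit": int(len(keep)), "n_pairs": int(len(y)),
                    "n_trimmed": int(trimmed.sum()),
                    "trimmed_fraction": frac_trim,
                    "poisson_fallback": fit2.poisson_fallback,
                    "seed": int(seed),
                },
            )
            if not fit2.converged:
                warnings.warn(f"{chrom}: background fit did not converge; flagged")
        elif family in ("ztnb", "hurdle"):
            cf = _fit_positive_family(
                str(chrom), family, y, X, take, spline, scaler, distance_form,
                trim_quantile)
        else:
            raise ValueError(f"unknown family {family!r}")

        if dispersion == "distance":
            mu_all = np.exp(np.clip(X @ cf.beta, -30, 30))
            cf.dispersion = estimate_distance_dispersion(y, mu_all, d, n_strata=n_strata)
        fits[str(chrom)] = cf
    return BackgroundFit(
        fits=fits,
        options={
            "family": family, "distance_form": distance_form,
            "dispersion": dispersion, "seed": int(seed),
            "subsample_frac": subsample_frac, "min_subsample": min_subsample,
            "trim_quantile": trim_quantile, "trim_refit": trim_refit,
            "covariates_standardized": True,
        },
    )


def _nb_threshold(mu, alpha, q) -> np.ndarray:
    """Per-pair NB null quantile used as the outlier-trim threshold."""
    if alpha <= 0:
        from scipy.stats import poisson
        return poisson.ppf(q, mu)
    r = 1.0 / alpha
    return nbinom.ppf(q, r, r / (r + mu))


def _nb_outliers(y, mu, alpha, q) -> np.ndarray:
    """Counts exceeding the per-pair NB null quantile."""
    return y > _nb_threshold(mu, alpha, q)


def _fit_positive_family(chrom, family, y, X, take, spline, scaler, distance_form, trim_q):
    """ZTNB / hurdle two-step fit on positive counts."""
    pos = y > 0
    if not np.any(pos):
        raise ValueError(f"{chrom}: all counts are zero; cannot fit {family} model")
    take_pos = take[pos[take]]
    fit1 = fit_ztnb_glm(y[take_pos], X[take_pos])
    mu_all = np.exp(np.clip(X @ fit1.beta, -30, 30))
    trimmed = _nb_outliers(y, mu_all, fit1.alpha, trim_q) & pos
    keep = take_pos[~trimmed[take_pos]]
    fit2 = fit_ztnb_glm(y[keep], X[keep])
    pi_beta = None
    separated = False
    if family == "hurdle":
        pi_beta, separated = fit_logistic((y > 0).astype(float), X[:, :])
    return ChromFit(
        chrom=chrom, family=family, distance_form=distance_form,
        beta=fit2.beta, alpha=fit2.alpha, spline=spline, scaler=scaler,
        cov=fit2.cov, pi_beta=pi_beta,
        diagnostics={
            "converged": fit2.converged, "n_fit": int(len(keep)),
            "n_pairs": int(len(y)), "n_trimmed": int(trimmed.sum()),
            "trimmed_fraction": float(np.mean(trimmed)),
            "logistic_ridge_stabilized": bool(separated),
        },
    )


def fit_hurdle(table: pd.DataFrame, features: pd.DataFrame, **kwargs) -> BackgroundFit:
    """Hurdle background: logistic P(y > 0) + zero-truncated NB for y | y > 0,
    both on the standard design.  Convenience wrapper over two_step_fit."""
    kwargs.pop("family", None)
    return two_step_fit(table, features, family="hurdle", **kwargs)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_mu(fit: BackgroundFit, table: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Expected count for every pair of ``table`` (flagged anchors -> NaN)."""
    return predict_table(fit, table, features)["mu"].to_numpy()


def predict_table(fit: BackgroundFit, table: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Attach mu, alpha (and pi for hurdle fits) columns to a copy of ``table``.

    Distances outside the training boundary knots are clamped to the
    boundary; pairs with a flagged anchor get NaN and ``ok = False``.
    """
    out = table.copy()
    out["mu"] = np.nan
    out["alpha"] = np.nan
    out["ok"] = False
    any_pi = any(f.pi_beta is not None for f in fit.fits.values())
    if any_pi:
        out["pi"] = np.nan
    for chrom, sub in table.groupby("chrom", sort=True):
        cf = fit.fits.get(str(chrom))
        if cf is None:
            raise KeyError(f"no background fit for chromosome {chrom!r}")
        feats = features[features["chrom"] == chrom] if "chrom" in features.columns else features
        cov = pair_covariates(sub, feats)
        ok = cov["ok"].to_numpy()
        idx = sub.index[ok]
        d = sub.loc[idx, "distance"].to_numpy(dtype=float)
        mu = cf.mu(d, cov.loc[idx])
        out.loc[idx, "mu"] = mu
        out.loc[idx, "alpha"] = cf.pair_alpha(d)
        out.loc[idx, "ok"] = True
        if cf.pi_beta is not None:
            out.loc[idx, "pi"] = cf.pi(d, cov.loc[idx])
    return out
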