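"""Significance calling and matrix normalization from a fitted background.

P-values follow the survival convention P(Y > y) = 1 - F(y): one minus the
CDF of the fitted count distribution at the observed count.  This is
conservative for small counts (p = 1 is unattainable, and a zero count can
never be significant).  Benjamini-Hochberg correction is genome-wide by
default across all tested pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .background import BackgroundFit, predict_table

__all__ = [
    "pvalue_survival",
    "adjust_bh",
    "normalize",
    "call_interactions",
    "call_significant",
]


def _nb_sf(y, mu, alpha):
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), y.shape)
    out = np.empty_like(y)
    pois = alpha <= 0
    if pois.any():
        out[pois] = poisson.sf(y[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / alpha[nb]
        out[nb] = nbinom.sf(y[nb], r, r / (r + mu[nb]))
    return out


def _nb_pmf0(mu, alpha):
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty_like(mu)
    pois = alpha <= 0
    out[pois] = np.exp(-mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / alpha[nb]
        out[nb] = np.exp(r * np.log(r / (r + mu[nb])))
    return out


def pvalue_survival(y, mu, alpha, family: str = "nb", pi=None) -> np.ndarray:
    """Upper-tail P-value P(Y > y) under the fitted family.

    nb:     plain NB (Poisson when alpha = 0) survival.
    ztnb:   survival of the zero-truncated NB; defined as 1 at y = 0.
    hurdle: pi * (1 - F_trunc(y)) for y >= 1 and pi at y = 0, with pi the
            fitted P(Y > 0).

    Computed with scipy's regularized-incomplete-beta survival function
    (numerically stable), which agrees with direct pmf summation.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y != np.floor(y)) or np.any(y < 0):
        raise ValueError("counts must be non-negative integers")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu[np.isfinite(mu)] <= 0):
        raise ValueError("mu must be positive")
    if family == "nb":
        return _nb_sf(y, mu, alpha)
    if family in ("ztnb", "hurdle"):
        p0 = _nb_pmf0(mu, alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            surv_trunc = np.where(y < 1, 1.0, _nb_sf(y, mu, alpha) / (1.0 - p0))
        surv_trunc = np.clip(surv_trunc, 0.0, 1.0)
        if family == "ztnb":
            return surv_trunc
        if pi is None:
            raise ValueError("hurdle survival needs pi = P(Y > 0)")
        pi = np.asarray(pi, dtype=float)
        return np.where(y < 1, pi, pi * surv_trunc)
    raise ValueError(f"unknown family {family!r}")


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def normalize(table: pd.DataFrame, fit: BackgroundFit, features: pd.DataFrame,
              mode: str = "oe") -> pd.DataFrame:
    """Observed/expected or NB Z-score normalization of a contact table."""
    if mode not in ("oe", "zscore"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    pred = predict_table(fit, table, features)
    mu = pred["mu"].to_numpy()
    y = pred["count"].to_numpy(dtype=float)
    out = pred[["chrom", "bin_i", "bin_j", "distance", "count"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "oe":
            out["value"] = np.where(mu > 0, y / mu, np.nan)
        else:
            a = pred["alpha"].to_numpy()
            sd = np.sqrt(mu + a * mu**2)
            out["value"] = np.where(sd > 0, (y - mu) / sd, np.nan)
    return out


def call_interactions(table: pd.DataFrame, fit: BackgroundFit, features: pd.DataFrame,
                      bh_scope: str = "genome") -> pd.DataFrame:
    """Score every expanded pair: mu, P-value, BH q-value, O/E and Z-score.

    Pairs excluded from testing (flagged anchor features) carry NaN, never
    p = 1.  ``bh_scope`` is "genome" (default, across all chromosomes) or
    "chrom".
    """
    pred = predict_table(fit, table, features)
    y = pred["count"].to_numpy(dtype=float)
    mu = pred["mu"].to_numpy()
    alpha = pred["alpha"].to_numpy()
    ok = pred["ok"].to_numpy()
    family = fit.options.get("family", "nb")
    pv = np.full(len(pred), np.nan)
    pi = pred["pi"].to_numpy() if "pi" in pred.columns else None
    pv[ok] = pvalue_survival(y[ok], mu[ok], alpha[ok], family=family,
                             pi=None if pi is None else pi[ok])
    out = pred[["chrom", "bin_i", "bin_j", "distance", "count", "mu"]].copy()
    out["pvalue"] = pv
    if bh_scope == "genome":
        out["qvalue"] = adjust_bh(pv)
    elif bh_scope == "chrom":
        out["qvalue"] = np.nan
        for _, idx in out.groupby("chrom", sort=False).groups.items():
            out.loc[idx, "qvalue"] = adjust_bh(out.loc[idx, "pvalue"].to_numpy())
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["oe"] = np.where(np.isfinite(mu) & (mu > 0), y / mu, np.nan)
        sd = np.sqrt(mu + alpha * mu**2)
        out["zscore"] = np.where(np.isfinite(sd) & (sd > 0), (y - mu) / sd, np.nan)
    return out


def call_significant(calls: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Subset of calls with q-value below the FDR threshold."""
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    if fdr_threshold == 1.0:
        return calls[np.isfinite(calls["qvalue"])].copy()
    return calls[calls["qvalue"] < fdr_threshold].copy()
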