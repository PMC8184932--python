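"""Differential interaction testing between two conditions with replicates.

The testing universe is the union atlas of pairs significant (FDR < 0.1 by
default) in at least one condition, called on pooled replicate counts.
Counts are normalized with per-sample, per-genomic-distance size factors
s_d = median count at distance d; the per-pair NB GLM is fit to the
normalized counts y/s_d (continuous NB quasi-likelihood), which makes every
statistic exactly invariant to rescaling any single sample.  Testing is a
shrinkage NB Wald test: per-pair Cox-Reid adjusted dispersion MLEs, a
parametric trend alpha(m) = a0 + a1/m across pairs, empirical-Bayes
shrinkage of log-dispersions toward the trend, and a Wald test of the
condition coefficient, BH-corrected over the atlas.

The engine is vectorized across pairs (the per-pair design has only an
intercept and a condition indicator, so IRLS reduces to 2x2 solves).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import norm

from .calling import adjust_bh

__all__ = [
    "build_union_atlas",
    "distance_size_factors",
    "assemble_counts",
    "nb_wald_test",
    "filter_differential",
]

PAIR_KEY = ["chrom", "bin_i", "bin_j"]
MIN_PRIOR_VAR = 0.25
ALPHA_LO, ALPHA_HI = 1e-8, 30.0


def build_union_atlas(calls_by_condition: dict[str, pd.DataFrame], fdr: float = 0.1) -> pd.DataFrame:
    """Pairs significant in at least one condition's pooled calls.

    All conditions must share the same tested pair universe (same binning).
    """
    conds = list(calls_by_condition)
    if len(conds) < 2:
        raise ValueError("need calls for at least two conditions")
    universe = None
    sig_parts = []
    for c in conds:
        calls = calls_by_condition[c]
        key = set(map(tuple, calls[PAIR_KEY].itertuples(index=False)))
        if universe is None:
            universe = key
        elif key != universe:
            raise ValueError("conditions were called on different pair universes (binning mismatch)")
        sig_parts.append(calls[calls["qvalue"] < fdr][PAIR_KEY + ["distance"]])
    atlas = (pd.concat(sig_parts, ignore_index=True)
             .drop_duplicates(subset=PAIR_KEY)
             .sort_values(PAIR_KEY, kind="stable", ignore_index=True))
    if not len(atlas):
        import warnings
        warnings.warn("union atlas is empty: no significant pairs in any condition")
    return atlas


def distance_size_factors(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample, per-distance size factors s_d.

    The raw factor s_hat is the median count at distance d over pairs with a
    nonzero count in at least one sample at that distance (the all-pairs
    median is zero on sparse long-range diagonals); a stratum whose median is
    still zero inherits the sample's nearest valid shorter-distance factor.
    The factor actually divided out ("rel") is s_hat centered by the
    cross-sample MEDIAN of s_hat at that distance, so normalized counts stay
    on the raw count scale (the NB mean-variance relationship needs the
    count magnitude) while per-distance medians are equalized across
    samples.  Median centering also makes the normalized counts of the other
    samples exactly invariant when any single sample is rescaled.
    """
    samples = list(tables)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    base = tables[samples[0]][PAIR_KEY + ["distance"]]
    counts = np.column_stack([
        _aligned_counts(tables[s], base) for s in samples])
    d = base["distance"].to_numpy()
    dist_vals = np.unique(d)
    any_nonzero = counts.max(axis=1) > 0
    rows = []
    for s_idx, s in enumerate(samples):
        prev = np.nan
        col = counts[:, s_idx]
        for dv in dist_vals:
            m = (d == dv) & any_nonzero
            med = float(np.median(col[m])) if m.any() else 0.0
            flagged = med <= 0
            if flagged:
                med = prev if np.isfinite(prev) and prev > 0 else 1.0
            else:
                prev = med
            rows.append((s, int(dv), med, flagged))
    sf = pd.DataFrame(rows, columns=["sample", "distance", "s_hat", "flagged"])
    center = sf.groupby("distance")["s_hat"].transform("median")
    sf["rel"] = sf["s_hat"] / center
    return sf


def _aligned_counts(table: pd.DataFrame, base: pd.DataFrame) -> np.ndarray:
    merged = base.merge(table[PAIR_KEY + ["count"]], on=PAIR_KEY, how="left")
    if merged["count"].isna().any():
        raise ValueError("sample tables do not share the same pair universe")
    return merged["count"].to_numpy(dtype=float)


def assemble_counts(tables: dict[str, pd.DataFrame], atlas: pd.DataFrame
                    ) -> tuple[np.ndarray, list[str]]:
    """Atlas-pairs x samples raw count matrix."""
    samples = list(tables)
    counts = np.column_stack([_aligned_counts(tables[s], atlas) for s in samples])
    return counts, samples


# ---------------------------------------------------------------------------
# vectorized per-pair NB GLM (design: intercept + condition)
# ---------------------------------------------------------------------------

def _irls_2param(y, cvec, alpha, n_iter=100, tol=1e-13):
    """Vectorized IRLS for log mu = b0 + b1*c per pair (rows of y).

    y: (G, S) normalized counts; cvec: (S,); alpha: (G,) or scalar.
    Returns b0, b1, se1 (Wald SE of b1), mu.
    """
    y = np.asarray(y, dtype=float)
    G, S = y.shape
    off = 0.0
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (G,))[:, None]
    c = np.broadcast_to(cvec, (G, S))
    # start from group means
    m1 = np.maximum(y[:, cvec == 1].mean(axis=1), 1e-8)
    m0 = np.maximum(y[:, cvec == 0].mean(axis=1), 1e-8)
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)
    for _ in range(n_iter):
        eta = np.clip(off + b0[:, None] + b1[:, None] * c, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - off) + (y - mu) / mu
        A11 = w.sum(axis=1)
        A12 = (w * c).sum(axis=1)
        A22 = (w * c * c).sum(axis=1)
        r1 = (w * z).sum(axis=1)
        r2 = (w * z * c).sum(axis=1)
        det = A11 * A22 - A12 * A12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        nb0 = (A22 * r1 - A12 * r2) / det
        nb1 = (A11 * r2 - A12 * r1) / det
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if np.all(delta < tol):
            break
    eta = np.clip(off + b0[:, None] + b1[:, None] * c, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    A11 = w.sum(axis=1)
    A12 = (w * c).sum(axis=1)
    A22 = (w * c * c).sum(axis=1)
    det = np.maximum(A11 * A22 - A12 * A12, 1e-300)
    se1 = np.sqrt(A11 / det)
    return b0, b1, se1, mu


def _nb_ll_rows(y, mu, alpha):
    """Row-wise NB log-likelihood; alpha: (G,)."""
    a = alpha[:, None]
    r = 1.0 / a
    return np.sum(
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(np.maximum(mu, 1e-300) / (r + mu)),
        axis=1,
    )


def _cr_adjustment(mu, alpha, cvec):
    """Cox-Reid term -0.5 log det(X' W X) per pair for the 2-column design."""
    a = alpha[:, None]
    w = mu / (1.0 + a * mu)
    c = np.broadcast_to(cvec, mu.shape)
    A11 = w.sum(axis=1)
    A12 = (w * c).sum(axis=1)
    A22 = (w * c * c).sum(axis=1)
    det = np.maximum(A11 * A22 - A12 * A12, 1e-300)
    return -0.5 * np.log(det)


def _golden_alpha(objective, G, lo=np.log(ALPHA_LO), hi=np.log(ALPHA_HI), iters=50):
    """Vectorized golden-section maximization of objective(log_alpha) per row.

    The objective is cheap and fully vectorized, so both probe points are
    re-evaluated each iteration for simplicity; 50 iterations shrink the
    bracket by ~1e-10.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(G, lo)
    b = np.full(G, hi)
    for _ in range(iters):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        keep_right = objective(x2) > objective(x1)
        a = np.where(keep_right, x1, a)
        b = np.where(keep_right, b, x2)
    return np.exp((a + b) / 2.0)


def _fit_trend(alpha_mle, base_mean, n_iter=10):
    """Parametric dispersion trend a(m) = a0 + a1/m by reweighted gamma-style
    least squares (weights 1/pred^2), as is standard for count-data trends.

    Estimates at the lower search boundary (dispersion indistinguishable
    from zero) are kept, floored at the boundary: dropping them biases the
    trend upward exactly in the low-dispersion regimes where half the
    per-pair MLEs sit at zero.  Only upper-boundary blowups are excluded.
    """
    ok = (alpha_mle < ALPHA_HI * 0.9) & (base_mean > 0)
    if ok.sum() < 10:
        med = float(np.median(alpha_mle))
        return max(med, 1e-6), 0.0, ok
    x = 1.0 / base_mean[ok]
    yv = np.maximum(alpha_mle[ok], ALPHA_LO)
    a0, a1 = float(np.median(yv)), 0.0
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(n_iter):
        pred = np.maximum(a0 + a1 * x, 1e-8)
        w = 1.0 / pred**2
        XtW = X.T * w
        try:
            coef = np.linalg.solve(XtW @ X, XtW @ yv)
        except np.linalg.LinAlgError:
            break
        a0 = max(float(coef[0]), 1e-8)
        a1 = max(float(coef[1]), 0.0)
    return a0, a1, ok


def nb_wald_test(
    atlas: pd.DataFrame,
    counts: np.ndarray,
    samples: list[str],
    conditions: dict[str, str],
    size_factors: pd.DataFrame,
    shrink: bool = True,
) -> pd.DataFrame:
    """Shrinkage NB Wald test of condition on atlas pairs.

    ``conditions`` maps each sample to one of exactly two condition labels;
    the reported log2 fold change is condition2 vs condition1 in sorted label
    order.  Pairs with all-zero counts are excluded (flagged with NaN).
    """
    counts = np.asarray(counts, dtype=float)
    G, S = counts.shape
    labels = sorted(set(conditions.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two conditions, got {labels}")
    cvec = np.array([1.0 if conditions[s] == labels[1] else 0.0 for s in samples])
    for lab in labels:
        if int((cvec == (1.0 if lab == labels[1] else 0.0)).sum()) < 2:
            raise ValueError(f"condition {lab!r} has fewer than 2 replicates")

    col = "rel" if "rel" in size_factors.columns else "s_hat"
    sf_lut = size_factors.set_index(["sample", "distance"])[col]
    d = atlas["distance"].to_numpy()
    sf = np.column_stack([
        sf_lut.loc[list(zip([s] * G, d))].to_numpy(dtype=float) for s in samples])
    norm_counts = counts / sf

    tested = counts.sum(axis=1) > 0
    yt = norm_counts[tested]
    Gt = yt.shape[0]

    # 1) initial fit at a moderate dispersion, then per-pair CR-adjusted MLE
    _, _, _, mu = _irls_2param(yt, cvec, 0.1)

    def cr_obj(loga):
        al = np.exp(loga)
        return _nb_ll_rows(yt, mu, al) + _cr_adjustment(mu, al, cvec)

    alpha_mle = _golden_alpha(cr_obj, Gt)
    b0, b1, _, mu = _irls_2param(yt, cvec, alpha_mle)
    alpha_mle = _golden_alpha(cr_obj, Gt)

    base_mean = yt.mean(axis=1)

    meta = {"conditions": labels, "shrink": shrink}
    if shrink:
        a0, a1, used = _fit_trend(alpha_mle, base_mean)
        trend = np.maximum(a0 + a1 / np.maximum(base_mean, 1e-8), 1e-8)
        interior = used & (alpha_mle > ALPHA_LO * 5)
        if interior.sum() < 10:
            interior = used
        lr = np.log(alpha_mle[interior]) - np.log(trend[interior])
        mad_sq = (1.4826 * float(np.median(np.abs(lr - np.median(lr))))) ** 2
        n_resid = max(S - 2, 1)
        sampling_var = float(special.polygamma(1, n_resid / 2.0))
        prior_var = max(mad_sq - sampling_var, MIN_PRIOR_VAR)
        log_trend = np.log(trend)

        def map_obj(loga):
            al = np.exp(loga)
            pen = (loga - log_trend) ** 2 / (2.0 * prior_var)
            return _nb_ll_rows(yt, mu, al) + _cr_adjustment(mu, al, cvec) - pen

        alpha_final = _golden_alpha(map_obj, Gt)
        meta.update({"trend_a0": a0, "trend_a1": a1, "prior_var": prior_var,
                     "sampling_var": sampling_var})
    else:
        alpha_final = alpha_mle

    b0, b1, se1, mu = _irls_2param(yt, cvec, alpha_final)
    stat = b1 / se1
    pval = 2.0 * norm.sf(np.abs(stat))

    out = atlas.copy()
    for col in ("baseMean", "log2FC", "lfcSE", "stat", "pvalue", "qvalue", "dispersion"):
        out[col] = np.nan
    out["tested"] = tested
    idx = np.where(tested)[0]
    out.loc[out.index[idx], "baseMean"] = base_mean
    out.loc[out.index[idx], "log2FC"] = b1 / np.log(2.0)
    out.loc[out.index[idx], "lfcSE"] = se1 / np.log(2.0)
    out.loc[out.index[idx], "stat"] = stat
    out.loc[out.index[idx], "pvalue"] = pval
    out.loc[out.index[idx], "dispersion"] = alpha_final
    out["qvalue"] = adjust_bh(out["pvalue"].to_numpy())
    for k, s in enumerate(samples):
        out[f"norm_{s}"] = norm_counts[:, k]
    out.attrs["meta"] = meta
    return out


def filter_differential(results: pd.DataFrame, fdr: float = 0.05,
                        min_abs_log2fc: float = 0.0) -> pd.DataFrame:
    """Subset passing both the FDR and the |log2FC| thresholds (idempotent)."""
    keep = (results["qvalue"] < fdr) if fdr < 1.0 else np.isfinite(results["qvalue"])
    keep &= np.abs(results["log2FC"]) >= min_abs_log2fc
    return results[keep.fillna(False)].copy()
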