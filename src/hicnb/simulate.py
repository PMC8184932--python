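"""Synthetic contact data with known ground truth.

Generates bin features, NB-distributed contact tables whose log-mean follows
the background model exactly (distance spline + covariate effects), planted
enriched pairs ("loops"), replicate sets with depth factors and planted
differential folds, and structured dense matrices (block-diagonal domains,
checkerboard compartments).  Every generator is a pure function of its
arguments including the mandatory seed.

The default world emulates a deeply sequenced (merged-replicate) Hi-C
library at 5 kb resolution: one chromosome of 2,000 bins, first-diagonal
mean count ~300 decaying roughly as d^-0.75 to a few counts at 2 Mb,
constant dispersion alpha = 0.15, and modest covariate effects.  Counts use
the same var = mu + alpha mu^2 parameterization as the fitting code
(gamma-Poisson mixture), so generation/fitting round-trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import (
    CovariateScaler,
    SplineSpec,
    build_design,
    choose_knots,
)
from .genome import GenomeBins, make_bins

__all__ = [
    "DEFAULTS",
    "ContactTruth",
    "simulate_features",
    "simulate_contacts",
    "simulate_replicates",
    "simulate_structured_matrix",
    "simulate_glm_dataset",
    "write_hicpro_fixture",
]

# the stated world (module-level so tests and the CLI share one definition)
DEFAULTS = dict(
    n_bins=2000,
    binsize=5000,
    d_min=5000,          # diagonal excluded (self-ligation artifacts)
    d_max=2_000_000,
    peak_mean=300.0,     # mean count at the first off-diagonal
    decay_exponent=0.75, # power-law slope of the distance decay
    alpha=0.15,          # NB dispersion, var = mu + alpha mu^2
    beta_gc=0.30,        # effects per SD of the pair covariate
    beta_map=0.25,
    beta_len=0.20,
    chrom="chrSim",
)


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory for every simulator")
    return np.random.default_rng(seed)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha mu^2 (Poisson at alpha = 0)."""
    mu = np.asarray(mu, dtype=float)
    a = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = a <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / a[nb]
        lam = rng.gamma(shape=r, scale=mu[nb] / r)
        out[nb] = rng.poisson(lam)
    return out


def simulate_features(n_bins: int, seed: int, chrom: str = DEFAULTS["chrom"],
                      binsize: int = DEFAULTS["binsize"],
                      flag_fraction: float = 0.0) -> pd.DataFrame:
    """Per-bin GC / mappability / effective-size draws in [0, 1]."""
    rng = _rng(seed)
    gc = rng.beta(10, 14, n_bins)            # mean ~0.42, realistic GC spread
    mp = np.clip(rng.beta(8, 2, n_bins), 0, 1)
    eff = rng.beta(5, 2, n_bins)
    flagged = rng.random(n_bins) < flag_fraction
    starts = np.arange(n_bins) * binsize
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + binsize,
        "bin_id": np.arange(n_bins), "gc": gc, "mappability": mp,
        "effective_size": eff, "flagged": flagged,
    })


@dataclass
class ContactTruth:
    """Ground truth accompanying a simulated contact table."""

    beta: np.ndarray              # coefficients on the build_design columns
    alpha: float
    spline: SplineSpec
    scaler: CovariateScaler
    features: pd.DataFrame
    mu_baseline: np.ndarray       # per-pair mean before planting
    planted: pd.DataFrame = field(default_factory=pd.DataFrame)

    def design(self, table: pd.DataFrame) -> np.ndarray:
        from .background import pair_covariates
        cov = pair_covariates(table, self.features)
        return build_design(table["distance"].to_numpy(dtype=float), cov,
                            self.spline, self.scaler, "spline")


def _world_design(n_bins, binsize, d_min, d_max, features):
    """All in-range pairs of the world plus their design matrix and spline."""
    from .background import pair_covariates

    k_min = max(int(np.ceil(d_min / binsize)), 1)
    k_max = min(int(d_max // binsize), n_bins - 1)
    ii = np.concatenate([np.arange(0, n_bins - k) for k in range(k_min, k_max + 1)])
    jj = np.concatenate([np.arange(k, n_bins) for k in range(k_min, k_max + 1)])
    order = np.lexsort((jj, ii))
    ii, jj = ii[order], jj[order]
    table = pd.DataFrame({
        "chrom": DEFAULTS["chrom"], "bin_i": ii, "bin_j": jj,
        "distance": (jj - ii) * binsize, "count": 0,
    })
    d = table["distance"].to_numpy(dtype=float)
    spline = choose_knots(d)
    cov = pair_covariates(table, features)
    scaler = CovariateScaler.fit(cov)
    X = build_design(d, cov, spline, scaler, "spline")
    return table, X, spline, scaler


def _decay_beta(X, d, binsize, peak_mean, decay_exponent):
    """Coefficients whose spline decay tracks a target power law.

    The target log-mean log(peak) - e*log(d/binsize) is projected onto the
    design's intercept+spline columns, so the truth lies exactly in the
    fitted model family.
    """
    target = np.log(peak_mean) - decay_exponent * np.log(d / binsize)
    cols = X[:, :7]  # const + 6 spline columns
    coef, *_ = np.linalg.lstsq(cols, target, rcond=None)
    return coef


def simulate_contacts(
    seed: int,
    n_bins: int = DEFAULTS["n_bins"],
    binsize: int = DEFAULTS["binsize"],
    d_min: int = DEFAULTS["d_min"],
    d_max: int = DEFAULTS["d_max"],
    peak_mean: float = DEFAULTS["peak_mean"],
    decay_exponent: float = DEFAULTS["decay_exponent"],
    alpha: float = DEFAULTS["alpha"],
    beta_gc: float = DEFAULTS["beta_gc"],
    beta_map: float = DEFAULTS["beta_map"],
    beta_len: float = DEFAULTS["beta_len"],
    n_loops: int = 0,
    loop_fold: float = 8.0,
    features: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ContactTruth]:
    """Simulate an expanded intra-chromosomal contact table from the model.

    Counts are NB draws around mu = exp(X beta); ``n_loops`` randomly chosen
    pairs get their mean multiplied by ``loop_fold`` and are listed in the
    returned truth record.
    """
    rng = _rng(seed)
    if features is None:
        features = simulate_features(n_bins, rng.integers(2**31), binsize=binsize)
    table, X, spline, scaler = _world_design(n_bins, binsize, d_min, d_max, features)
    d = table["distance"].to_numpy(dtype=float)
    beta = np.zeros(X.shape[1])
    beta[:7] = _decay_beta(X, d, binsize, peak_mean, decay_exponent)
    beta[7:] = [beta_gc, beta_map, beta_len]
    mu = np.exp(np.clip(X @ beta, -30, 30))

    fold = np.ones(len(table))
    planted = pd.DataFrame(columns=["chrom", "bin_i", "bin_j", "fold"])
    if n_loops > 0:
        if any(f <= 0 for f in [loop_fold]):
            raise ValueError("loop folds must be positive")
        pick = rng.choice(len(table), size=n_loops, replace=False)
        fold[pick] = loop_fold
        planted = table.iloc[pick][["chrom", "bin_i", "bin_j"]].copy()
        planted["fold"] = loop_fold
        planted = planted.reset_index(drop=True)

    table = table.copy()
    table["count"] = _nb_draw(rng, mu * fold, alpha)
    truth = ContactTruth(beta=beta, alpha=alpha, spline=spline, scaler=scaler,
                         features=features, mu_baseline=mu, planted=planted)
    return table, truth


REPLICATE_ALPHA = 0.01  # per-replicate dispersion (BCV ~10%): replicate noise
                        # is Poisson-dominated; the background alpha instead
                        # absorbs genomic structure shared across replicates


def simulate_replicates(
    seed: int,
    n_replicates: int = 3,
    depth_factors: dict[str, float] | None = None,
    n_diff: int = 0,
    diff_log2fc: float = 1.0,
    min_diff_mu: float = 0.0,
    conditions: tuple[str, str] = ("cond1", "cond2"),
    rep_alpha: float = REPLICATE_ALPHA,
    **world_kwargs,
) -> tuple[dict[str, pd.DataFrame], dict[str, str], ContactTruth, pd.DataFrame]:
    """Replicate contact tables for two conditions with planted differences.

    Each replicate is an independent NB draw around depth * mu (times the
    planted fold in condition 2), with per-replicate dispersion ``rep_alpha``.
    Returns (tables by sample, condition map, world truth, planted-difference
    table).
    """
    rng = _rng(seed)
    base_table, truth = simulate_contacts(int(rng.integers(2**31)), n_loops=0, **world_kwargs)
    mu = truth.mu_baseline
    eligible = np.arange(len(mu)) if min_diff_mu <= 0 else np.where(mu >= min_diff_mu)[0]
    fold2 = np.ones(len(mu))
    diff = pd.DataFrame(columns=["chrom", "bin_i", "bin_j", "log2fc"])
    if n_diff > 0:
        pick = rng.choice(eligible, size=n_diff, replace=False)
        fold2[pick] = 2.0 ** diff_log2fc
        diff = base_table.iloc[pick][["chrom", "bin_i", "bin_j"]].copy()
        diff["log2fc"] = diff_log2fc
        diff = diff.reset_index(drop=True)

    tables: dict[str, pd.DataFrame] = {}
    cond_of: dict[str, str] = {}
    for c_idx, cond in enumerate(conditions):
        for r in range(1, n_replicates + 1):
            name = f"{cond}_r{r}"
            depth = (depth_factors or {}).get(name, 1.0)
            m = mu * depth * (fold2 if c_idx == 1 else 1.0)
            t = base_table.copy()
            t["count"] = _nb_draw(rng, m, rep_alpha)
            tables[name] = t
            cond_of[name] = cond
    return tables, cond_of, truth, diff


def simulate_structured_matrix(
    kind: str,
    seed: int,
    n_bins: int = 100,
    n_domains: int = 5,
    block_size: int = 10,
    within: float = 10.0,
    cross: float = 1.0,
    oe_same: float = 2.0,
    oe_other: float = 0.5,
    base_mean: float = 50.0,
    decay_exponent: float = 0.5,
    alpha: float = 0.1,
    noise: bool = True,
):
    """Dense structured matrices with recorded truth.

    kind="tads": block-diagonal mean structure (``n_domains`` equal blocks,
    within/cross mean contrast) with multiplicative power-law distance decay;
    returns (matrix, boundary bin indices).  With ``noise=False`` the exact
    mean matrix is returned.

    kind="compartments": checkerboard of interleaved ``block_size``-bin
    groups with within/cross O/E contrast; returns (O/E matrix, labels, gc)
    where counts are NB draws and O/E divides by the known expected decay.
    """
    rng = _rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    decay = (dist + 1.0) ** (-decay_exponent)
    if kind == "tads":
        dom = idx // int(np.ceil(n_bins / n_domains))
        same = dom[:, None] == dom[None, :]
        mean = base_mean * decay * np.where(same, within, cross)
        if noise:
            m = _nb_draw(rng, mean, alpha).astype(float)
            m = (m + m.T) / 2.0
        else:
            m = mean
        boundaries = np.where(np.diff(dom))[0]  # boundary after these bins
        return m, boundaries
    if kind == "compartments":
        labels = (idx // block_size) % 2  # interleaved groups, balanced
        same = labels[:, None] == labels[None, :]
        oe_true = np.where(same, oe_same, oe_other)
        mean = base_mean * decay * oe_true
        counts = _nb_draw(rng, mean, alpha).astype(float) if noise else mean
        counts = (counts + counts.T) / 2.0
        oe = counts / (base_mean * decay)
        gc = 0.40 + 0.06 * (labels == 0) + rng.normal(0, 0.01, n_bins)
        return oe, np.where(labels == 0, "A", "B"), gc
    raise ValueError(f"unknown kind {kind!r}")


def simulate_glm_dataset(n: int, seed: int, alpha: float = DEFAULTS["alpha"],
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(y, X, beta_true, alpha) drawn from the regression model itself.

    Used for parameter-recovery checks at a chosen sample size: distances
    uniform over the world's range, simulated covariates, counts NB around
    exp(X beta).
    """
    rng = _rng(seed)
    n_bins = max(int(np.sqrt(n)), 200)
    feats = simulate_features(n_bins, int(rng.integers(2**31)))
    binsize = DEFAULTS["binsize"]
    d = rng.integers(1, DEFAULTS["d_max"] // binsize + 1, size=n) * binsize
    bi = rng.integers(0, n_bins - 1, size=n)
    bj = np.minimum(bi + d // binsize, n_bins - 1)
    table = pd.DataFrame({"chrom": DEFAULTS["chrom"], "bin_i": bi, "bin_j": bj,
                          "distance": d.astype(float), "count": 0})
    from .background import pair_covariates
    cov = pair_covariates(table, feats)
    spline = choose_knots(d.astype(float))
    scaler = CovariateScaler.fit(cov)
    X = build_design(d.astype(float), cov, spline, scaler, "spline")
    beta = np.zeros(X.shape[1])
    beta[:7] = _decay_beta(X, d.astype(float), binsize, DEFAULTS["peak_mean"],
                           DEFAULTS["decay_exponent"])
    beta[7:] = [DEFAULTS["beta_gc"], DEFAULTS["beta_map"], DEFAULTS["beta_len"]]
    y = _nb_draw(rng, np.exp(np.clip(X @ beta, -30, 30)), alpha)
    return y.astype(float), X, beta, alpha


def write_hicpro_fixture(table: pd.DataFrame, bins: GenomeBins, prefix: str) -> tuple[str, str]:
    """Write a table as HiC-Pro sparse .matrix + _abs.bed (1-based abs ids)."""
    bed_path = f"{prefix}_abs.bed"
    mat_path = f"{prefix}.matrix"
    bed = bins.df.copy()
    bed["abs_id"] = np.arange(1, len(bed) + 1)
    bed[["chrom", "start", "end", "abs_id"]].to_csv(bed_path, sep="\t",
                                                    header=False, index=False)
    lut = bed.set_index(["chrom", "bin_id"])["abs_id"]
    nz = table[table["count"] > 0]
    a = lut.loc[list(zip(nz["chrom"], nz["bin_i"]))].to_numpy()
    b = lut.loc[list(zip(nz["chrom"], nz["bin_j"]))].to_numpy()
    pd.DataFrame({"a": a, "b": b, "count": nz["count"].to_numpy()}).to_csv(
        mat_path, sep="\t", header=False, index=False)
    return mat_path, bed_path


def world_bins(n_bins: int = DEFAULTS["n_bins"], binsize: int = DEFAULTS["binsize"],
               chrom: str = DEFAULTS["chrom"]) -> GenomeBins:
    """GenomeBins matching the simulated world."""
    return make_bins({chrom: n_bins * binsize}, binsize=binsize)
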