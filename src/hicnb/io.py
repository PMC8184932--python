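"""Contact-matrix input/output.

Reads HiC-Pro sparse ``.matrix`` (+ companion ``_abs.bed``), allValidPairs
text and a generic bin-pair TSV into one canonical intra-chromosomal
ContactTable, and writes result tables as TSV / BEDPE / bedGraph.

ContactTable is a pandas DataFrame with columns
``chrom, bin_i, bin_j, distance, count`` where bin ids are 0-based and
consecutive within a chromosome, bin_i <= bin_j, and distance is
``(bin_j - bin_i) * binsize`` for uniform bins (midpoint distance in
fragment mode).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import GenomeBins

__all__ = [
    "read_hicpro",
    "read_validpairs",
    "read_pairs_tsv",
    "expand_zeros",
    "canonicalize",
    "pair_distance",
    "write_bedpe",
    "write_results_tsv",
    "write_bedgraph",
]

log = logging.getLogger("hicnb")

CONTACT_COLS = ["chrom", "bin_i", "bin_j", "distance", "count"]


def pair_distance(bins: GenomeBins, chrom: str, bin_i: np.ndarray, bin_j: np.ndarray) -> np.ndarray:
    """Genomic distance for bin pairs: index distance x binsize for uniform
    bins, midpoint distance in fragment mode."""
    if bins.binsize is not None:
        return (np.asarray(bin_j) - np.asarray(bin_i)) * bins.binsize
    tab = bins.chrom_table(chrom)
    mid = ((tab["start"] + tab["end"]) // 2).to_numpy()
    return np.abs(mid[np.asarray(bin_j)] - mid[np.asarray(bin_i)])


def canonicalize(df: pd.DataFrame, bins: GenomeBins) -> pd.DataFrame:
    """Upper-triangular order, aggregated duplicates forbidden, sorted."""
    i = np.minimum(df["bin_i"], df["bin_j"])
    j = np.maximum(df["bin_i"], df["bin_j"])
    out = pd.DataFrame({"chrom": df["chrom"], "bin_i": i, "bin_j": j, "count": df["count"]})
    dup = out.duplicated(subset=["chrom", "bin_i", "bin_j"], keep=False)
    if dup.any():
        first = out.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate bin pair ({first.chrom}, {first.bin_i}, {first.bin_j}) in input")
    parts = []
    for chrom, sub in out.groupby("chrom", sort=True):
        sub = sub.copy()
        sub["distance"] = pair_distance(bins, chrom, sub["bin_i"].to_numpy(),
                                        sub["bin_j"].to_numpy())
        parts.append(sub)
    res = pd.concat(parts, ignore_index=True)
    res = res.sort_values(["chrom", "bin_i", "bin_j"], kind="stable", ignore_index=True)
    return res[CONTACT_COLS]


def _abs_bed_to_bins(abs_bed: pd.DataFrame, bins: GenomeBins) -> pd.DataFrame:
    """Map the HiC-Pro global bin ids of an _abs.bed onto ``bins``; errors on
    any coordinate mismatch."""
    mapping = []
    for chrom, sub in abs_bed.groupby("chrom", sort=False):
        if chrom not in bins.chroms():
            raise KeyError(f"chromosome {chrom!r} from abs bed absent from bins")
        ref = bins.chrom_table(chrom)
        if len(sub) != len(ref) or not (
            np.array_equal(sub["start"].to_numpy(), ref["start"].to_numpy())
            and np.array_equal(sub["end"].to_numpy(), ref["end"].to_numpy())
        ):
            raise ValueError(f"abs bed bin coordinates do not match bins on {chrom}")
        mapping.append(pd.DataFrame({
            "abs_id": sub["abs_id"].to_numpy(),
            "chrom": chrom,
            "bin_id": ref["bin_id"].to_numpy(),
        }))
    return pd.concat(mapping, ignore_index=True).set_index("abs_id")


def read_hicpro(matrix_path, abs_bed_path, bins: GenomeBins) -> pd.DataFrame:
    """HiC-Pro sparse matrix + _abs.bed -> canonical intra-chromosomal table.

    Inter-chromosomal records are dropped (count logged).
    """
    bed = pd.read_csv(abs_bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "abs_id"])
    lut = _abs_bed_to_bins(bed, bins)
    mat = pd.read_csv(matrix_path, sep=r"\s+", header=None,
                      names=["a", "b", "count"])
    unknown = ~(mat["a"].isin(lut.index) & mat["b"].isin(lut.index))
    if unknown.any():
        bad = mat.loc[unknown].iloc[0]
        raise KeyError(f"matrix references bin id {int(bad.a)}/{int(bad.b)} absent from abs bed")
    ca = lut.loc[mat["a"]].reset_index(drop=True)
    cb = lut.loc[mat["b"]].reset_index(drop=True)
    intra = (ca["chrom"].to_numpy() == cb["chrom"].to_numpy())
    n_inter = int((~intra).sum())
    if n_inter:
        log.info("dropped %d inter-chromosomal records", n_inter)
    df = pd.DataFrame({
        "chrom": ca["chrom"].to_numpy()[intra],
        "bin_i": ca["bin_id"].to_numpy()[intra],
        "bin_j": cb["bin_id"].to_numpy()[intra],
        "count": mat["count"].to_numpy()[intra],
    })
    return canonicalize(df, bins)


def read_validpairs(path, bins: GenomeBins) -> pd.DataFrame:
    """allValidPairs text -> canonical table (pairs binned by 5' position).

    Expected tab-separated fields per line: read id, chrom1, pos1, strand1,
    chrom2, pos2, strand2 [, extra...].  Positions are 1-based and converted
    to 0-based at this boundary; a position on a bin boundary belongs to the
    right-hand (containing) bin by the half-open convention.
    """
    rows = {"chrom": [], "p1": [], "p2": []}
    n_inter = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{ln}: malformed validPairs line ({len(parts)} fields)")
            _, c1, p1, _s1, c2, p2, _s2 = parts[:7]
            try:
                p1, p2 = int(p1) - 1, int(p2) - 1
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer position") from None
            if c1 != c2:
                n_inter += 1
                continue
            rows["chrom"].append(c1)
            rows["p1"].append(p1)
            rows["p2"].append(p2)
    if n_inter:
        log.info("excluded %d inter-chromosomal pairs", n_inter)
    if not rows["chrom"]:
        return pd.DataFrame(columns=CONTACT_COLS)
    df = pd.DataFrame(rows)
    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom not in bins.chroms():
            raise KeyError(f"chromosome {chrom!r} in pairs file absent from bins")
        bi = bins.bin_of(chrom, sub["p1"].to_numpy())
        bj = bins.bin_of(chrom, sub["p2"].to_numpy())
        lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
        agg = (pd.DataFrame({"bin_i": lo, "bin_j": hi})
               .value_counts().rename("count").reset_index())
        agg["chrom"] = chrom
        parts.append(agg)
    out = pd.concat(parts, ignore_index=True)
    return canonicalize(out, bins)


def read_pairs_tsv(path, bins: GenomeBins) -> pd.DataFrame:
    """Generic TSV with columns chrom, start_i, start_j, count (bin starts)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start_i", "start_j", "count"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path} missing columns {sorted(missing)}")
    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        if chrom not in bins.chroms():
            raise KeyError(f"chromosome {chrom!r} absent from bins")
        parts.append(pd.DataFrame({
            "chrom": chrom,
            "bin_i": bins.bin_of(chrom, sub["start_i"].to_numpy()),
            "bin_j": bins.bin_of(chrom, sub["start_j"].to_numpy()),
            "count": sub["count"].to_numpy(),
        }))
    return canonicalize(pd.concat(parts, ignore_index=True), bins)


def expand_zeros(table: pd.DataFrame, bins: GenomeBins, d_min: int, d_max: int) -> pd.DataFrame:
    """Insert explicit zero counts for every absent pair with
    d_min <= distance <= d_max; observed records are preserved unchanged and
    records outside the range are dropped."""
    if d_min > d_max:
        raise ValueError("d_min must be <= d_max")
    parts = []
    for chrom in bins.chroms():
        n = bins.n_bins(chrom)
        if bins.binsize is not None:
            k_min = max(int(np.ceil(d_min / bins.binsize)), 0)
            k_max = min(int(d_max // bins.binsize), n - 1)
            ii, jj = [], []
            for k in range(k_min, k_max + 1):
                i = np.arange(0, n - k)
                ii.append(i)
                jj.append(i + k)
            if not ii:
                continue
            bi = np.concatenate(ii)
            bj = np.concatenate(jj)
        else:
            iu, ju = np.triu_indices(n, k=0)
            d = pair_distance(bins, chrom, iu, ju)
            m = (d >= d_min) & (d <= d_max)
            bi, bj = iu[m], ju[m]
        full = pd.DataFrame({
            "chrom": chrom, "bin_i": bi, "bin_j": bj,
            "distance": pair_distance(bins, chrom, bi, bj),
            "count": 0,
        })
        obs = table[table["chrom"] == chrom]
        if len(obs):
            obs = obs[(obs["distance"] >= d_min) & (obs["distance"] <= d_max)]
            key = full.set_index(["bin_i", "bin_j"])
            key.loc[list(zip(obs["bin_i"], obs["bin_j"])), "count"] = obs["count"].to_numpy()
            full = key.reset_index()
            full["chrom"] = chrom
        parts.append(full[CONTACT_COLS])
    if not parts:
        return pd.DataFrame(columns=CONTACT_COLS)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["chrom", "bin_i", "bin_j"], kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

BEDPE_HEADER = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                "name", "score", "strand1", "strand2"]


def _anchors(records: pd.DataFrame, bins: GenomeBins) -> tuple[pd.DataFrame, pd.DataFrame]:
    lut = bins.df.set_index(["chrom", "bin_id"])
    ai = lut.loc[list(zip(records["chrom"], records["bin_i"]))].reset_index(drop=True)
    aj = lut.loc[list(zip(records["chrom"], records["bin_j"]))].reset_index(drop=True)
    return ai, aj


def write_bedpe(records: pd.DataFrame, bins: GenomeBins, path, score_field: str = "qvalue") -> None:
    """10-column BEDPE with a selectable score column; header-only if empty."""
    if score_field not in records.columns and len(records):
        raise KeyError(f"unknown score field {score_field!r}")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_HEADER) + "\n")
        if not len(records):
            return
        ai, aj = _anchors(records, bins)
        for k in range(len(records)):
            r = records.iloc[k]
            fh.write("\t".join(map(str, [
                r["chrom"], int(ai["start"][k]), int(ai["end"][k]),
                r["chrom"], int(aj["start"][k]), int(aj["end"][k]),
                f"{r['chrom']}:{int(r['bin_i'])}-{int(r['bin_j'])}",
                f"{r[score_field]:.6g}", ".", ".",
            ])) + "\n")


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=None, header=0,
                       names=BEDPE_HEADER).rename(columns=lambda c: c.lstrip("#"))


def write_results_tsv(calls: pd.DataFrame, bins: GenomeBins, path) -> None:
    """Full per-pair results table with genomic anchor starts."""
    out = calls.copy()
    ai, aj = _anchors(calls, bins)
    out.insert(1, "startI", ai["start"].to_numpy())
    out.insert(2, "startJ", aj["start"].to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(values: pd.DataFrame, bins: GenomeBins, path, value_col: str) -> None:
    """Per-bin bedGraph dump (e.g. compartment eigenvector)."""
    lut = bins.df.set_index(["chrom", "bin_id"])
    with open(path, "w") as fh:
        for _, r in values.iterrows():
            b = lut.loc[(r["chrom"], int(r["bin_id"]))]
            v = r[value_col]
            if not np.isfinite(v):
                continue
            fh.write(f"{r['chrom']}\t{int(b.start)}\t{int(b.end)}\t{v:.6g}\n")
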