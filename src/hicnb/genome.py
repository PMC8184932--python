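"""Genomic bins and per-bin model covariates.

Bins the genome into uniform intervals or groups of restriction-enzyme (RE)
fragments and derives the three background-model covariates per bin: GC
content, mappability and effective bin size (the fraction of the bin lying
within a flank of an RE cut site — a proxy for ligatable sequence).

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "REFragmentSet",
    "digest_genome",
    "make_bins",
    "compute_bin_features",
    "read_chrom_sizes",
    "read_feature_tsv",
    "write_feature_tsv",
]

DEFAULT_FLANK_BP = 500      # effective-size / mappability window around cut sites
DEFAULT_GC_EXTRA_BP = 200   # extra symmetric flank for the GC window

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    try:
        pat = "".join(IUPAC[c] for c in motif.upper())
    except KeyError as e:
        raise ValueError(f"unknown IUPAC code {e.args[0]!r} in motif {motif!r}") from None
    # lookahead so overlapping occurrences are all found; N in the genome
    # never matches because the classes only list ACGT
    return re.compile(f"(?=({pat}))")


@dataclass
class REFragmentSet:
    """Restriction-enzyme cut sites and the fragments they imply."""

    chrom: str
    chrom_length: int
    cut_sites: np.ndarray  # sorted, strictly increasing match-start positions

    @property
    def fragments(self) -> pd.DataFrame:
        """Intervals between consecutive cut sites, tiling the chromosome."""
        edges = np.r_[0, self.cut_sites, self.chrom_length]
        edges = np.unique(edges)
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": edges[:-1].astype(int),
            "end": edges[1:].astype(int),
        })


def digest_genome(sequences: dict[str, str], motifs: list[str]) -> dict[str, REFragmentSet]:
    """In-silico digestion: record a cut site at every motif match start.

    Non-palindromic motifs are scanned on both strands (a reverse-strand hit
    is the forward-coordinate match start of the reverse complement).
    Chromosomes with no match yield a single fragment covering them.
    """
    if not motifs:
        raise ValueError("at least one restriction motif is required")
    patterns = []
    for m in motifs:
        patterns.append(_iupac_regex(m))
        rc = _revcomp(m)
        if rc.upper() != m.upper():
            patterns.append(_iupac_regex(rc))
    out = {}
    for chrom, seq in sequences.items():
        s = str(seq).upper()
        sites: set[int] = set()
        for pat in patterns:
            sites.update(m.start() for m in pat.finditer(s))
        out[chrom] = REFragmentSet(
            chrom=chrom, chrom_length=len(s),
            cut_sites=np.asarray(sorted(sites), dtype=int),
        )
    return out


@dataclass
class GenomeBins:
    """Genome tiling used to index contact matrices.

    ``df`` holds chrom, start, end, bin_id with bin_id consecutive within
    each chromosome starting at 0.  ``binsize`` is the uniform bin width in
    bp, or None in RE-fragment mode.
    """

    df: pd.DataFrame
    binsize: int | None = None
    fragments_per_bin: int | None = None
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self._starts[chrom] = sub["start"].to_numpy()

    def chroms(self) -> list[str]:
        return list(self._starts)

    def n_bins(self, chrom: str) -> int:
        return len(self._starts[chrom])

    def bin_of(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Bin id containing each position (half-open intervals)."""
        starts = self._starts[chrom]
        return np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(starts) - 1)

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom sizes TSV -> {chrom: length}."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    if not sizes:
        raise ValueError(f"no chromosomes found in {path}")
    return sizes


def make_bins(
    chrom_sizes: dict[str, int],
    binsize: int | None = None,
    fragments_per_bin: int | None = None,
    fragment_sets: dict[str, REFragmentSet] | None = None,
) -> GenomeBins:
    """Tile chromosomes into uniform bins or groups of RE fragments."""
    rows = []
    if binsize is not None:
        if binsize <= 0:
            raise ValueError("binsize must be positive")
        for chrom, length in chrom_sizes.items():
            starts = np.arange(0, length, binsize)
            ends = np.minimum(starts + binsize, length)
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends,
                "bin_id": np.arange(len(starts)),
            }))
        return GenomeBins(pd.concat(rows, ignore_index=True), binsize=binsize)
    if fragments_per_bin is None or fragment_sets is None:
        raise ValueError("fragment mode needs fragments_per_bin and fragment_sets")
    if fragments_per_bin <= 0:
        raise ValueError("fragments_per_bin must be positive")
    for chrom, length in chrom_sizes.items():
        if chrom not in fragment_sets:
            raise KeyError(f"chromosome {chrom!r} missing from fragment sets")
        frags = fragment_sets[chrom].fragments
        n = len(frags)
        group = np.arange(n) // fragments_per_bin
        g = frags.groupby(group)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": g["start"].first().to_numpy(),
            "end": g["end"].last().to_numpy(),
            "bin_id": np.arange(g.ngroups),
        }))
    return GenomeBins(pd.concat(rows, ignore_index=True),
                      fragments_per_bin=fragments_per_bin)


def _union_windows(centers: np.ndarray, flank: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """Union of [c-flank, c+flank) windows clipped to [lo, hi)."""
    if len(centers) == 0:
        return []
    iv = np.column_stack([np.maximum(centers - flank, lo), np.minimum(centers + flank, hi)])
    iv = iv[iv[:, 1] > iv[:, 0]]
    if len(iv) == 0:
        return []
    merged = [tuple(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(int(s), int(e)) for s, e in merged]


class IntervalTrack:
    """Piecewise-constant per-base track from bedGraph-like intervals.

    Used for mappability when no bigWig reader is available; values default
    to NaN outside the given intervals.
    """

    def __init__(self, df: pd.DataFrame):
        self.by_chrom = {
            c: (sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["value"].to_numpy(dtype=float))
            for c, sub in df.groupby("chrom", sort=False)
        }

    @classmethod
    def from_tsv(cls, path) -> "IntervalTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        return cls(df)

    @classmethod
    def constant(cls, chrom_sizes: dict[str, int], value: float) -> "IntervalTrack":
        df = pd.DataFrame({
            "chrom": list(chrom_sizes), "start": 0,
            "end": list(chrom_sizes.values()), "value": value,
        })
        return cls(df)

    def mean_over(self, chrom: str, windows: list[tuple[int, int]]) -> float:
        if chrom not in self.by_chrom or not windows:
            return float("nan")
        starts, ends, vals = self.by_chrom[chrom]
        total = 0.0
        weight = 0
        for ws, we in windows:
            i0 = np.searchsorted(ends, ws, side="right")
            i1 = np.searchsorted(starts, we, side="left")
            for k in range(i0, i1):
                ov = min(we, ends[k]) - max(ws, starts[k])
                if ov > 0:
                    total += vals[k] * ov
                    weight += ov
        return total / weight if weight else float("nan")


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def compute_bin_features(
    bins: GenomeBins,
    fragment_sets: dict[str, REFragmentSet],
    sequences: dict[str, str],
    mappability: IntervalTrack | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
    gc_extra_bp: int = DEFAULT_GC_EXTRA_BP,
) -> pd.DataFrame:
    """Per-bin GC, mappability and effective size from RE cut-site windows.

    effective_size = |union of +-flank_bp windows around cut sites ∩ bin| /
    bin length; GC is computed over the same union widened by ``gc_extra_bp``
    on each side, mappability as the mean track value over the union.  Bins
    without a cut site get effective_size 0 and flagged (NaN) GC/mappability.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    rows = []
    for chrom in bins.chroms():
        if chrom not in fragment_sets:
            raise KeyError(f"chromosome {chrom!r} has no digestion result")
        seq = str(sequences[chrom]).upper()
        sites = fragment_sets[chrom].cut_sites
        for _, b in bins.chrom_table(chrom).iterrows():
            s, e = int(b.start), int(b.end)
            local = sites[(sites >= s - flank_bp) & (sites < e + flank_bp)]
            wins = _union_windows(local, flank_bp, s, e)
            covered = sum(we - ws for ws, we in wins)
            eff = covered / (e - s)
            if covered == 0:
                rows.append((chrom, s, e, int(b.bin_id), np.nan, np.nan, 0.0, True))
                continue
            gc_wins = _union_windows(local, flank_bp + gc_extra_bp, max(s - gc_extra_bp, 0),
                                     min(e + gc_extra_bp, len(seq)))
            gc = _gc_fraction("".join(seq[ws:we] for ws, we in gc_wins))
            mp = (mappability.mean_over(chrom, wins)
                  if mappability is not None else np.nan)
            flagged = not (np.isfinite(gc) and (mappability is None or np.isfinite(mp)))
            rows.append((chrom, s, e, int(b.bin_id), gc, mp, eff, flagged))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "bin_id", "gc",
                       "mappability", "effective_size", "flagged"])


def write_feature_tsv(features: pd.DataFrame, path) -> None:
    """Write the "bintolen" per-bin feature table consumed by the model."""
    features.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path) -> pd.DataFrame:
    """Read a precomputed per-bin feature table (bypasses FASTA/track input)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "bin_id", "gc", "mappability", "effective_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns: {sorted(missing)}")
    if "flagged" not in df.columns:
        df["flagged"] = ~np.isfinite(df[["gc", "mappability", "effective_size"]]).all(axis=1)
    return df


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA into {name: sequence} via pyfaidx."""
    from pyfaidx import Fasta
    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
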