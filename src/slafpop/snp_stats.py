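"""Marker filtering and SNP landscape statistics.

Implements the marker-quality filter (minor allele frequency and call-rate
"integrity", both strict inequalities), mutation-frequency hotspots
(positions where the fraction of accessions carrying any non-reference
genotype exceeds a threshold), fixed-width window SNP counts, top-fraction
SNP-rich regions, and the per-ecotype presence/absence contrast of rich
regions.

Windows are anchored at coordinate 0, 0-based half-open, with the last
window per chromosome truncated — so a 100-kb window grid yields region
coordinates that are multiples of 1e5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_away
from .genotypes import GenotypeMatrix

__all__ = [
    "minor_allele_frequency",
    "integrity",
    "filter_markers",
    "mutation_frequency",
    "call_hotspots",
    "windowed_snp_counts",
    "snp_rich_regions",
    "compare_rich_regions_by_ecotype",
    "WindowCounts",
    "RichRegionSet",
    "density_per_100kb",
]


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF of a dosage column: min(p, 1-p), p = sum(dosage)/(2 * n called).

    Returns NaN for an all-missing column.
    """
    col = np.asarray(column, dtype=float)
    called = col[~np.isnan(col)]
    if called.size == 0:
        return float("nan")
    p = called.sum() / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def integrity(column: np.ndarray) -> float:
    """Call rate: fraction of accessions with a non-missing genotype."""
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("empty column")
    return float(1.0 - np.isnan(col).mean())


def mutation_frequency(column: np.ndarray) -> float:
    """Fraction of called accessions with any non-reference allele (dosage >= 1)."""
    col = np.asarray(column, dtype=float)
    called = col[~np.isnan(col)]
    if called.size == 0:
        return float("nan")
    return float((called >= 1).mean())


def _column_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(maf, integrity, mutation frequency) per marker, vectorized."""
    d = gm.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(d, axis=0) / (2.0 * n_called)
        mut = np.nansum(d >= 1, axis=0) / n_called
    maf = np.minimum(p, 1.0 - p)
    integ = n_called / d.shape[0]
    maf[n_called == 0] = np.nan
    mut = np.where(n_called == 0, np.nan, mut)
    return maf, integ, mut


def filter_markers(
    gm: GenotypeMatrix, maf_min: float = 0.05, integrity_min: float = 0.8
) -> GenotypeMatrix:
    """Retain markers with MAF > maf_min AND integrity > integrity_min.

    Both inequalities are strict: boundary markers are removed. Marker
    order is preserved; an empty result is allowed.
    """
    maf, integ, _ = _column_stats(gm)
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_min) & (integ > integrity_min)
    return gm.take_markers(np.flatnonzero(keep))


def call_hotspots(gm: GenotypeMatrix, threshold: float = 0.8) -> np.ndarray:
    """Indices of hotspot markers: mutation frequency strictly > threshold."""
    _, _, mut = _column_stats(gm)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(mut > threshold)


def hotspot_counts_per_chrom(gm: GenotypeMatrix, threshold: float = 0.8) -> dict[str, int]:
    idx = call_hotspots(gm, threshold)
    chrom = gm.markers["chrom"].to_numpy()
    out = {c: 0 for c in gm.chroms}
    for i in idx:
        out[chrom[i]] += 1
    return out


@dataclass
class WindowCounts:
    """SNP counts in fixed windows tiling each chromosome."""

    windows: pd.DataFrame  # chrom, start, end (0-based half-open), count
    window_bp: int

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "count"}
        if not need <= set(self.windows.columns):
            raise ValueError(f"window table must have columns {sorted(need)}")

    @property
    def density_per_100kb(self) -> np.ndarray:
        w = self.windows
        return np.array(
            [round_half_away(c / (e - s) * 100_000)
             for c, s, e in zip(w["count"], w["start"], w["end"])]
        )

    def total(self) -> int:
        return int(self.windows["count"].sum())


def density_per_100kb(n_snps: float, length_bp: float) -> int:
    """SNPs per 100 kb, rounded to the nearest integer (ties away from zero)."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    return round_half_away(n_snps / length_bp * 100_000)


def windowed_snp_counts(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window_bp: int = 100_000,
) -> WindowCounts:
    """Count markers in fixed windows anchored at 0 along each chromosome.

    Each marker falls in exactly one window by (pos - 1) // window_bp; the
    last window per chromosome is truncated at the chromosome end.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows: list[tuple[str, int, int, int]] = []
    chrom_arr = gm.markers["chrom"].to_numpy()
    pos_arr = gm.markers["pos"].to_numpy()
    for chrom, length in chrom_lengths.items():
        on = chrom_arr == chrom
        pos = pos_arr[on]
        if pos.size and pos.max() > length:
            raise ValueError(f"marker beyond end of {chrom} (length {length})")
        n_win = max(1, math.ceil(length / window_bp))
        counts = np.bincount((pos - 1) // window_bp, minlength=n_win) if pos.size else np.zeros(n_win, int)
        for w in range(n_win):
            start = w * window_bp
            end = min(length, start + window_bp)
            rows.append((chrom, start, end, int(counts[w])))
    extra = set(chrom_arr) - set(chrom_lengths)
    if extra:
        raise ValueError(f"markers on chromosomes without lengths: {sorted(extra)}")
    return WindowCounts(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]), window_bp
    )


@dataclass
class RichRegionSet:
    """Merged runs of top-fraction windows: the SNP-rich regions."""

    regions: pd.DataFrame  # chrom, start, end, snp_count
    top_fraction: float

    def __len__(self) -> int:
        return len(self.regions)


def snp_rich_regions(wc: WindowCounts, top_fraction: float = 0.01) -> RichRegionSet:
    """Top-fraction windows by count, merged into regions when adjacent.

    ceil(top_fraction * #windows) windows are selected; ties are broken by
    genomic order (earlier wins). Adjacent selected windows on the same
    chromosome merge into one region.
    """
    w = wc.windows
    if len(w) == 0:
        raise ValueError("no windows")
    n_take = math.ceil(top_fraction * len(w))
    order = np.lexsort((np.arange(len(w)), -w["count"].to_numpy()))
    chosen = np.sort(order[:n_take])
    rows: list[list] = []
    for i in chosen:
        chrom, start, end, count = w.iloc[i][["chrom", "start", "end", "count"]]
        if rows and rows[-1][0] == chrom and rows[-1][2] == start:
            rows[-1][2] = end
            rows[-1][3] += count
        else:
            rows.append([chrom, start, end, count])
    return RichRegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_count"]),
        top_fraction,
    )


def _overlaps(chrom: str, start: int, end: int, table: pd.DataFrame) -> bool:
    sel = table[table["chrom"] == chrom]
    return bool(((sel["start"] < end) & (sel["end"] > start)).any())


def compare_rich_regions_by_ecotype(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window_bp: int = 100_000,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Presence/absence of SNP-rich regions across ecotypes.

    The window/top-fraction pipeline is recomputed within each ecotype
    subset, keeping only markers polymorphic within that subset. The region
    universe is the union of all per-ecotype regions (merged); a region is
    present in an ecotype iff it overlaps one of that ecotype's selected
    regions. Ecotypes with fewer than two accessions are excluded.
    """
    if gm.ecotype is None:
        raise ValueError("genotype matrix carries no ecotype labels")
    eco_arr = np.asarray(gm.ecotype)
    per_eco: dict[str, pd.DataFrame] = {}
    for eco in dict.fromkeys(gm.ecotype):
        idx = np.flatnonzero(eco_arr == eco)
        if idx.size < 2:
            warnings.warn(f"ecotype {eco!r} has <2 accessions; excluded")
            continue
        sub = gm.take_accessions(idx)
        maf, _, _ = _column_stats(sub)
        with np.errstate(invalid="ignore"):
            poly = np.flatnonzero(maf > 0)
        sub = sub.take_markers(poly)
        wc = windowed_snp_counts(sub, chrom_lengths, window_bp)
        per_eco[eco] = snp_rich_regions(wc, top_fraction).regions
    if len(per_eco) < 2:
        raise ValueError("need at least two ecotypes with >=2 accessions")

    pooled = pd.concat(per_eco.values(), ignore_index=True)
    universe: list[list] = []
    for chrom in dict.fromkeys(pooled["chrom"]):
        sel = pooled[pooled["chrom"] == chrom].sort_values("start")
        for _, r in sel.iterrows():
            # merge only strict overlaps: regions that merely touch stay
            # distinct so different ecotypes' regions remain separable
            if universe and universe[-1][0] == chrom and universe[-1][2] > r["start"]:
                universe[-1][2] = max(universe[-1][2], r["end"])
            else:
                universe.append([chrom, r["start"], r["end"]])
    rows = []
    for chrom, start, end in universe:
        row: dict[str, object] = {"chrom": chrom, "start": start, "end": end}
        for eco, table in per_eco.items():
            row[eco] = _overlaps(chrom, start, end, table)
        rows.append(row)
    return pd.DataFrame(rows)
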