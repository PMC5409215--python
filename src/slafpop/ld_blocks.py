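"""Linkage disequilibrium: pairwise r², decay curves, D' confidence
intervals and Gabriel-style haplotype blocks.

r² is the squared Pearson correlation of dosage vectors (composite LD),
the appropriate statistic for unphased diploid genotypes; missing entries
are handled by pairwise deletion. Decay curves are distance-binned mean r²
anchored at (0 bp, r² = 1), with the decay distance taken as the first
linear-interpolated crossing of the threshold (default r² = 0.1).

D' confidence intervals follow the Gabriel et al. (2002) likelihood
procedure: two-locus haplotype frequencies are resolved by EM (double
heterozygotes split by phase probability), the likelihood is profiled over
|D'| on a fine grid with allele frequencies held at their estimates, and
the 90% interval is read off the normalized likelihood mass. Blocks use
the Gabriel defaults: a pair is in "strong LD" when CI low >= 0.70 and CI
high >= 0.98, shows "strong recombination" when CI high < 0.90; a marker
interval is a block when its outermost pair is in strong LD and >= 95% of
its informative pairs are; non-overlapping blocks are kept greedily by
descending bp span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "pairwise_r2",
    "DecayCurve",
    "ld_decay",
    "ld_decay_scopes",
    "dprime_ci",
    "HaplotypeBlockSet",
    "gabriel_blocks",
    "block_summary",
    "summarize_blocks",
    "SIZE_CLASSES",
]

LD_COLUMNS = ["chrom", "pos_i", "pos_j", "distance", "r2"]

# size-class bin edges in bp, right-open: [0,1k), [1k,10k), [10k,100k), >=100k
SIZE_CLASSES = ("0-1 kb", "1-10 kb", "10-100 kb", ">100 kb")
_SIZE_EDGES = (0, 1_000, 10_000, 100_000)


def pairwise_r2(
    gm: GenotypeMatrix,
    chrom: str,
    max_distance_bp: int | None = None,
    maf_min: float = 0.05,
    min_shared: int = 4,
) -> pd.DataFrame:
    """All intra-chromosome marker pairs with squared dosage correlation.

    Markers are pre-filtered to MAF > maf_min. Pairs with fewer than
    ``min_shared`` jointly called accessions, or monomorphic within the
    shared accessions, are skipped. Returns a DataFrame with columns
    chrom, pos_i, pos_j, distance, r2.
    """
    idx = gm.markers_on(chrom)
    if idx.size < 2:
        return pd.DataFrame(columns=LD_COLUMNS)
    sub = gm.take_markers(idx)
    d = sub.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * np.maximum(n_called, 1))
        maf = np.minimum(p, 1 - p)
        keep = np.flatnonzero((n_called > 0) & (maf > maf_min))
    if keep.size < 2:
        return pd.DataFrame(columns=LD_COLUMNS)
    d = d[:, keep]
    pos = sub.markers["pos"].to_numpy()[keep]

    w = (~np.isnan(d)).astype(float)
    x = np.where(np.isnan(d), 0.0, d)
    n = w.T @ w
    sx = x.T @ w  # sum of x over jointly-called accessions
    sxx = (x * x).T @ w
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_i = n * sxx - sx**2
        var_j = var_i.T
        r2 = cov**2 / (var_i * var_j)

    m = d.shape[1]
    iu, ju = np.triu_indices(m, k=1)
    dist = np.abs(pos[ju] - pos[iu])
    ok = (n[iu, ju] >= min_shared) & (var_i[iu, ju] > 0) & (var_j[iu, ju] > 0)
    if max_distance_bp is not None:
        ok &= dist <= max_distance_bp
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_i": pos[iu][ok],
            "pos_j": pos[ju][ok],
            "distance": dist[ok],
            "r2": r2[iu, ju][ok],
        }
    )


@dataclass
class DecayCurve:
    """Distance-binned mean r² with the (0, 1) anchor."""

    bin_centers: np.ndarray  # bp, ascending, excludes the anchor
    bin_mean_r2: np.ndarray
    threshold: float
    decay_distance: float | None  # bp, None when the curve never crosses

    @property
    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """Curve points including the anchor (0 bp, r² = 1)."""
        return (
            np.concatenate([[0.0], self.bin_centers]),
            np.concatenate([[1.0], self.bin_mean_r2]),
        )


def _first_crossing(xs: np.ndarray, ys: np.ndarray, threshold: float) -> float | None:
    for (x0, y0), (x1, y1) in zip(zip(xs[:-1], ys[:-1]), zip(xs[1:], ys[1:])):
        if y0 > threshold >= y1:
            return float(x0 + (x1 - x0) * (y0 - threshold) / (y0 - y1))
    if ys[0] <= threshold:
        return float(xs[0])
    return None


def ld_decay(
    pairs: pd.DataFrame, threshold: float = 0.1, bin_width_bp: int = 1000
) -> DecayCurve:
    """Distance-binned decay curve and threshold-crossing distance.

    Pairs are binned by distance (bin centers at (k + 1/2) * width); the
    piecewise-linear curve through the anchor (0, 1) and the bin means, in
    distance order, is interpolated for its first crossing of the
    threshold. A curve that never reaches the threshold has
    ``decay_distance = None``.
    """
    if len(pairs) == 0:
        raise ValueError("no LD pairs")
    if bin_width_bp <= 0:
        raise ValueError("bin width must be positive")
    dist = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    bins = (dist // bin_width_bp).astype(int)
    uniq = np.unique(bins)
    centers = (uniq + 0.5) * bin_width_bp
    means = np.array([r2[bins == b].mean() for b in uniq])
    xs = np.concatenate([[0.0], centers])
    ys = np.concatenate([[1.0], means])
    return DecayCurve(centers, means, threshold, _first_crossing(xs, ys, threshold))


def ld_decay_scopes(
    gm: GenotypeMatrix,
    subgenomes: dict[str, str],
    threshold: float = 0.1,
    bin_width_bp: int = 1000,
    max_distance_bp: int | None = None,
    maf_min: float = 0.05,
) -> dict[str, DecayCurve]:
    """Decay curves per chromosome, per subgenome and genome-wide.

    Subgenome and genome scopes pool the pairwise records of their
    chromosomes before binning. Keys are chromosome names, subgenome
    labels, and "genome".
    """
    per_chrom = {
        c: pairwise_r2(gm, c, max_distance_bp, maf_min) for c in gm.chroms
    }
    out: dict[str, DecayCurve] = {}
    for c, tab in per_chrom.items():
        if len(tab):
            out[c] = ld_decay(tab, threshold, bin_width_bp)
    for sub in sorted({s for s in subgenomes.values() if s}):
        tabs = [t for c, t in per_chrom.items() if subgenomes.get(c) == sub and len(t)]
        if tabs:
            out[sub] = ld_decay(pd.concat(tabs, ignore_index=True), threshold, bin_width_bp)
    all_tabs = [t for t in per_chrom.values() if len(t)]
    if all_tabs:
        out["genome"] = ld_decay(pd.concat(all_tabs, ignore_index=True), threshold, bin_width_bp)
    return out


# ---------------------------------------------------------------------------
# D' confidence intervals (Gabriel likelihood procedure)


def _genotype_table(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray | None:
    both = ~(np.isnan(col_i) | np.isnan(col_j))
    if both.sum() < 4:
        return None
    gi = col_i[both].astype(int)
    gj = col_j[both].astype(int)
    table = np.zeros((3, 3))
    np.add.at(table, (gi, gj), 1)
    return table


def _hap_freqs_em(table: np.ndarray, n_iter: int = 64) -> tuple[float, float, float]:
    """(h11, p, q): EM haplotype frequency of the alt-alt haplotype.

    Allele frequencies p (locus 1) and q (locus 2) are fixed by the data;
    only the double-heterozygote phase split is iterated.
    """
    n = table.sum()
    p = (table * np.arange(3)[:, None]).sum() / (2 * n)
    q = (table * np.arange(3)[None, :]).sum() / (2 * n)
    # haplotype counts certain from all cells except the double het
    base11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    ndh = table[1, 1]
    h11 = p * q  # start at linkage equilibrium
    for _ in range(n_iter):
        h10, h01 = p - h11, q - h11
        h00 = 1 - p - q + h11
        cis = h11 * h00
        trans = h10 * h01
        frac = 0.5 if cis + trans <= 0 else cis / (cis + trans)
        h11_new = (base11 + ndh * frac) / (2 * n)
        lo = max(0.0, p + q - 1.0)
        h11_new = min(max(h11_new, lo), min(p, q))
        if abs(h11_new - h11) < 1e-12:
            h11 = h11_new
            break
        h11 = h11_new
    return float(h11), float(p), float(q)


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities from hap freqs [h00, h01, h10, h11]."""
    alleles = [(0, 0), (0, 1), (1, 0), (1, 1)]
    probs = np.zeros((3, 3))
    for a, (a1, a2) in enumerate(alleles):
        for b, (b1, b2) in enumerate(alleles):
            probs[a1 + b1, a2 + b2] += h[a] * h[b]
    return probs


def _loglik_at_dprime(table: np.ndarray, p: float, q: float, d: float) -> float:
    """Multinomial log-likelihood of the genotype table at covariance D = d."""
    h = np.array(
        [1 - p - q + p * q + d, q - p * q - d, p - p * q - d, p * q + d]
    )
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    probs = np.clip(_genotype_probs(h), 1e-300, None)
    return float((table * np.log(probs)).sum())


def dprime_ci(
    col_i: np.ndarray,
    col_j: np.ndarray,
    resolution: float = 0.001,
    ci_alpha: float = 0.05,
) -> tuple[float, float, float] | None:
    """Point estimate and 90% CI for |D'| between two dosage columns.

    Returns (point, ci_low, ci_high) or None when fewer than four jointly
    called accessions or either marker is monomorphic in the shared set.
    The likelihood is profiled over the |D'| grid (sign fixed to the EM
    estimate's sign); the interval bounds hold 5% of the normalized
    likelihood mass in each tail, and the point estimate is the grid
    maximum.
    """
    table = _genotype_table(np.asarray(col_i, float), np.asarray(col_j, float))
    if table is None:
        return None
    h11, p, q = _hap_freqs_em(table)
    if not (0 < p < 1) or not (0 < q < 1):
        return None
    d_mle = h11 - p * q
    sign = 1.0 if d_mle >= 0 else -1.0
    dmax = min(p * (1 - q), q * (1 - p)) if sign > 0 else min(p * q, (1 - p) * (1 - q))
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    ll = np.array([_loglik_at_dprime(table, p, q, sign * g * dmax) for g in grid])
    like = np.exp(ll - ll.max())
    total = like.sum()
    cum = np.cumsum(like)
    low = float(grid[int(np.searchsorted(cum, ci_alpha * total))])
    high = float(grid[int(np.searchsorted(cum, (1 - ci_alpha) * total))])
    point = float(grid[int(np.argmax(like))])
    return point, low, high


# ---------------------------------------------------------------------------
# Gabriel blocks


@dataclass
class HaplotypeBlockSet:
    """Non-overlapping marker-interval blocks on one or more chromosomes."""

    blocks: pd.DataFrame  # chrom, first, last (marker idx), start_bp, end_bp, length_bp

    def __len__(self) -> int:
        return len(self.blocks)

    def size_class_histogram(self) -> dict[str, int]:
        lengths = self.blocks["length_bp"].to_numpy() if len(self.blocks) else np.array([])
        hist = {}
        edges = [*_SIZE_EDGES, math.inf]
        for name, lo, hi in zip(SIZE_CLASSES, edges[:-1], edges[1:]):
            hist[name] = int(((lengths >= lo) & (lengths < hi)).sum())
        return hist


def classify_pair(
    ci: tuple[float, float, float] | None,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
) -> str:
    """Gabriel pair class: "strong_ld", "recombination" or "uninformative"."""
    if ci is None:
        return "uninformative"
    _, low, high = ci
    if low >= strong_low and high >= strong_high:
        return "strong_ld"
    if high < recomb_high:
        return "recombination"
    return "uninformative"


def gabriel_blocks(
    gm: GenotypeMatrix,
    chrom: str,
    informative_fraction: float = 0.95,
    resolution: float = 0.001,
    max_distance_bp: int | None = None,
) -> HaplotypeBlockSet:
    """Gabriel-rule haplotype blocks on one chromosome.

    A candidate interval's outermost marker pair must be in strong LD and
    >= ``informative_fraction`` of its informative pairs (strong LD or
    strong recombination) must be strong LD; candidates are kept greedily
    by descending bp span. Pairs farther apart than ``max_distance_bp``
    (when set) are treated as uninformative.
    """
    idx = gm.markers_on(chrom)
    cols = ["chrom", "first", "last", "start_bp", "end_bp", "length_bp", "n_markers"]
    if idx.size < 2:
        return HaplotypeBlockSet(pd.DataFrame(columns=cols))
    sub = gm.take_markers(idx)
    pos = sub.markers["pos"].to_numpy()
    m = len(pos)
    cls = np.full((m, m), "", dtype=object)
    for a in range(m):
        for b in range(a + 1, m):
            if max_distance_bp is not None and pos[b] - pos[a] > max_distance_bp:
                cls[a, b] = "uninformative"
                continue
            ci = dprime_ci(sub.dosages[:, a], sub.dosages[:, b], resolution)
            cls[a, b] = classify_pair(ci)

    candidates: list[tuple[int, int, int]] = []  # (span, first, last)
    for a in range(m):
        for b in range(a + 1, m):
            if cls[a, b] != "strong_ld":
                continue
            strong = recomb = 0
            for u in range(a, b + 1):
                for v in range(u + 1, b + 1):
                    if cls[u, v] == "strong_ld":
                        strong += 1
                    elif cls[u, v] == "recombination":
                        recomb += 1
            informative = strong + recomb
            if informative and strong / informative >= informative_fraction:
                candidates.append((int(pos[b] - pos[a]), a, b))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    rows = []
    for span, a, b in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        rows.append((chrom, a, b, int(pos[a]), int(pos[b]), span, b - a + 1))
    rows.sort(key=lambda r: r[3])
    return HaplotypeBlockSet(pd.DataFrame(rows, columns=cols))


# ---------------------------------------------------------------------------
# summaries


def summarize_blocks(
    per_chrom: pd.DataFrame,
    chrom_lengths: dict[str, int],
    subgenomes: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """Per-chromosome, per-subgenome and genome block summaries.

    ``per_chrom`` needs columns chrom, n_blocks, total_length_bp. The
    per-chromosome frequency is total block length over chromosome length
    as a percentage (2 decimals); the subgenome frequency is the mean of
    its chromosomes' percentages (not the pooled ratio), and the genome row
    uses the pooled ratio.
    """
    rows = []
    for _, r in per_chrom.iterrows():
        chrom = r["chrom"]
        length = chrom_lengths[chrom]
        freq = round(float(r["total_length_bp"]) / length * 100, 2)
        rows.append((chrom, subgenomes.get(chrom, ""), length,
                     int(r["n_blocks"]), int(r["total_length_bp"]), freq))
    chrom_tab = pd.DataFrame(
        rows, columns=["chrom", "subgenome", "chrom_length", "n_blocks",
                       "total_length_bp", "frequency_pct"],
    )
    sub_rows = []
    for sub in sorted({s for s in chrom_tab["subgenome"] if s}):
        sel = chrom_tab[chrom_tab["subgenome"] == sub]
        sub_rows.append(
            (
                sub,
                float(sel["n_blocks"].mean()),
                float(sel["total_length_bp"].mean()),
                round(float(sel["frequency_pct"].mean()), 2),
            )
        )
    sub_tab = pd.DataFrame(
        sub_rows, columns=["subgenome", "mean_n_blocks", "mean_total_length_bp",
                           "mean_frequency_pct"],
    )
    total_len = sum(chrom_lengths[c] for c in chrom_tab["chrom"])
    genome = pd.DataFrame(
        {
            "n_blocks": [int(chrom_tab["n_blocks"].sum())],
            "total_length_bp": [int(chrom_tab["total_length_bp"].sum())],
            "frequency_pct": [round(chrom_tab["total_length_bp"].sum() / total_len * 100, 2)],
        }
    )
    return {"per_chrom": chrom_tab, "per_subgenome": sub_tab, "genome": genome}


def block_summary(
    blocksets: dict[str, HaplotypeBlockSet],
    chrom_lengths: dict[str, int],
    subgenomes: dict[str, str],
) -> dict[str, pd.DataFrame]:
    """Summaries from computed block sets (one per chromosome)."""
    rows = []
    for chrom, bs in blocksets.items():
        total = int(bs.blocks["length_bp"].sum()) if len(bs) else 0
        rows.append((chrom, len(bs), total))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_blocks", "total_length_bp"])
    return summarize_blocks(per_chrom, chrom_lengths, subgenomes)
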