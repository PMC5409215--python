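"""Kinship, p-distance, neighbor-joining trees and PCA on dosage matrices.

Kinship uses the Loiselle et al. (1995) marker-based coancestry estimator;
for a biallelic marker with within-individual allele frequency x = dosage/2
and panel frequency p it reduces to

    f_ij = sum_l (x_il - p_l)(x_jl - p_l) / sum_l p_l (1 - p_l)

with pairwise deletion of markers missing in either accession, and negative
estimates truncated to zero afterwards (less-related-than-random pairs are
reported as unrelated).

p-distance is the proportion of pairwise-complete markers whose genotype
calls differ — the sequence-space mismatch proportion carried over to
dosage space. Neighbor joining follows Saitou-Nei with the Studier-Keppler
Q criterion; PCA is an eigendecomposition of the accession covariance of
the mean-imputed, marker-centered dosage matrix (no variance scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "DistanceMatrix",
    "PcaResult",
    "kinship_matrix",
    "p_distance",
    "neighbor_joining",
    "pca",
    "fraction_below",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    accessions: list[str]
    estimator_name: str = "Loiselle"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    accessions: list[str]
    method: str = "p-distance"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass
class PcaResult:
    scores: np.ndarray  # accessions x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


def kinship_matrix(gm: GenotypeMatrix) -> KinshipMatrix:
    """Loiselle kinship with pairwise deletion and negative truncation.

    Pairs sharing no called marker get NaN (with a warning). The diagonal
    is the self-coancestry under the same formula.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least two accessions")
    d = gm.dosages
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_called)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic marker")
    x = d[:, poly] / 2.0
    pl = p[poly]
    w = called[:, poly].astype(float)
    z = np.where(np.isnan(x), 0.0, x - pl)  # zeros drop missing terms
    num = z @ z.T
    den = w @ (w * (pl * (1 - pl))[None, :]).T
    with np.errstate(invalid="ignore", divide="ignore"):
        f = num / den
    if np.isnan(f).any():
        warnings.warn("some accession pairs share no called marker")
    f = np.where(f < 0, 0.0, f)
    f = (f + f.T) / 2.0
    return KinshipMatrix(f, list(gm.accessions))


def fraction_below(km: KinshipMatrix, cutoff: float = 0.05) -> float:
    """Fraction of distinct accession pairs with kinship below the cutoff."""
    n = km.values.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = km.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairs")
    return float((vals < cutoff).mean())


def p_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise genotype-call mismatch proportion with pairwise deletion."""
    if gm.n_accessions < 2:
        raise ValueError("need at least two accessions")
    d = gm.dosages
    called = (~np.isnan(d)).astype(float)
    shared = called @ called.T
    matches = np.zeros_like(shared)
    for val in (0.0, 1.0, 2.0):
        ind = np.where(np.isnan(d), 0.0, (d == val).astype(float))
        matches += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (shared - matches) / shared
    dist[shared == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        warnings.warn("some accession pairs share no called marker")
    return DistanceMatrix((dist + dist.T) / 2.0, list(gm.accessions))


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children=None):
        self.label = label
        self.children: list[tuple["_Node", float]] = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in Newick.

    Negative branch lengths from the standard update are clamped to zero
    and the deficit transferred to the sister branch, preserving the pair's
    summed length.
    """
    D = np.array(dm.values, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least three taxa")
    nodes: list[_Node] = [_Node(lbl) for lbl in dm.accessions]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (r - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        parent = _Node(None, [(nodes[ia], la), (nodes[ib], lb)])
        new_d = 0.5 * (D[ia, :] + D[ib, :] - dab)
        D = np.vstack([D, new_d[None, :]])
        new_col = np.append(new_d, 0.0)
        D = np.hstack([D, new_col[:, None]])
        nodes.append(parent)
        active = [i for i in active if i not in (ia, ib)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    branches = []
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        branches.append((nodes[idx], max(ln, 0.0)))
    root = _Node(None, branches)
    return root.newick() + ";"


def pca(gm: GenotypeMatrix, n_components: int = 3) -> PcaResult:
    """PCA of the mean-imputed, marker-centered dosage matrix.

    Missing entries are imputed to the marker mean dosage before centering,
    so they contribute nothing after centering. variance_explained is each
    eigenvalue over the eigenvalue total.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least two accessions")
    d = gm.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    x = d - d.mean(axis=0)
    # eigen-decomposition via SVD of the centered matrix
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2
    total = eig.sum()
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    if total <= 0:
        ve = np.zeros(k)
    else:
        ve = eig[:k] / total
    return PcaResult(scores=scores, variance_explained=ve)
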