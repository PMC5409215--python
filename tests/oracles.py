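"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops, independent of the library's
vectorized implementations, so the two can be compared on small inputs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# digestion


def naive_digest(sequence: str, enzymes) -> list[tuple[int, int]]:
    """Fragment intervals by scanning every position for each word."""
    seq = sequence.upper()
    cuts = set()
    for enz in enzymes:
        w = enz.recognition
        for i in range(len(seq) - len(w) + 1):
            if seq[i : i + len(w)] == w:
                c = i + enz.cut_offset
                if 0 < c < len(seq):
                    cuts.add(c)
    bounds = [0, *sorted(cuts), len(seq)]
    return list(zip(bounds[:-1], bounds[1:]))


# ---------------------------------------------------------------------------
# per-marker statistics by explicit enumeration


def col_maf(column) -> float:
    alt = tot = 0
    for g in column:
        if not math.isnan(g):
            alt += g
            tot += 2
    if tot == 0:
        return float("nan")
    p = alt / tot
    return min(p, 1 - p)


def col_integrity(column) -> float:
    n_called = sum(0 if math.isnan(g) else 1 for g in column)
    return n_called / len(column)


def col_mutation_frequency(column) -> float:
    called = [g for g in column if not math.isnan(g)]
    if not called:
        return float("nan")
    return sum(1 for g in called if g >= 1) / len(called)


def hudson_fst(f1, f2) -> float:
    """Ratio-of-averages F_ST from two groups' true allele frequencies."""
    num = den = 0.0
    for a, b in zip(f1, f2):
        num += (a - b) ** 2
        den += a * (1 - b) + b * (1 - a)
    return num / den


# ---------------------------------------------------------------------------
# pairwise r^2 by explicit loops


def pair_r2(col_i, col_j) -> float | None:
    xs, ys = [], []
    for a, b in zip(col_i, col_j):
        if not (math.isnan(a) or math.isnan(b)):
            xs.append(a)
            ys.append(b)
    n = len(xs)
    if n < 4:
        return None
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return None
    return sxy**2 / (sxx * syy)


# ---------------------------------------------------------------------------
# D' confidence interval by exhaustive grid search (independent coding path)


def dprime_ci_oracle(col_i, col_j, resolution: float = 0.001):
    table = [[0] * 3 for _ in range(3)]
    n = 0
    for a, b in zip(col_i, col_j):
        if not (math.isnan(a) or math.isnan(b)):
            table[int(a)][int(b)] += 1
            n += 1
    if n < 4:
        return None
    p = sum(i * table[i][j] for i in range(3) for j in range(3)) / (2 * n)
    q = sum(j * table[i][j] for i in range(3) for j in range(3)) / (2 * n)
    if p <= 0 or p >= 1 or q <= 0 or q >= 1:
        return None

    # EM for the double-het phase split, to fix the sign of D
    h11 = p * q
    for _ in range(64):
        h10, h01, h00 = p - h11, q - h11, 1 - p - q + h11
        cis, trans = h11 * h00, h10 * h01
        frac = 0.5 if cis + trans <= 0 else cis / (cis + trans)
        base = 2 * table[2][2] + table[2][1] + table[1][2]
        new = (base + table[1][1] * frac) / (2 * n)
        new = min(max(new, max(0.0, p + q - 1)), min(p, q))
        if abs(new - h11) < 1e-12:
            h11 = new
            break
        h11 = new
    sign = 1.0 if h11 - p * q >= 0 else -1.0
    dmax = min(p * (1 - q), q * (1 - p)) if sign > 0 else min(p * q, (1 - p) * (1 - q))

    def loglik(dp: float) -> float:
        d = sign * dp * dmax
        h = [1 - p - q + p * q + d, q - p * q - d, p - p * q - d, p * q + d]
        h = [max(x, 1e-12) for x in h]
        s = sum(h)
        h = [x / s for x in h]
        alleles = [(0, 0), (0, 1), (1, 0), (1, 1)]
        probs = [[0.0] * 3 for _ in range(3)]
        for a in range(4):
            for b in range(4):
                a1, a2 = alleles[a]
                b1, b2 = alleles[b]
                probs[a1 + b1][a2 + b2] += h[a] * h[b]
        ll = 0.0
        for i in range(3):
            for j in range(3):
                if table[i][j]:
                    ll += table[i][j] * math.log(max(probs[i][j], 1e-300))
        return ll

    grid = [round(k * resolution, 10) for k in range(int(round(1 / resolution)) + 1)]
    lls = [loglik(g) for g in grid]
    top = max(lls)
    likes = [math.exp(v - top) for v in lls]
    total = sum(likes)
    cum = 0.0
    low = high = None
    for g, l in zip(grid, likes):
        cum += l
        if low is None and cum >= 0.05 * total:
            low = g
        if high is None and cum >= 0.95 * total:
            high = g
    point = grid[likes.index(max(likes))]
    return point, low, high


# ---------------------------------------------------------------------------
# Gabriel blocks by exhaustive interval enumeration


def gabriel_blocks_oracle(dosages, positions, frac: float = 0.95):
    m = len(positions)
    cls = {}
    for a in range(m):
        for b in range(a + 1, m):
            ci = dprime_ci_oracle(dosages[:, a], dosages[:, b])
            if ci is None:
                cls[a, b] = "uninformative"
            else:
                _, low, high = ci
                if low >= 0.70 and high >= 0.98:
                    cls[a, b] = "strong_ld"
                elif high < 0.90:
                    cls[a, b] = "recombination"
                else:
                    cls[a, b] = "uninformative"
    candidates = []
    for a in range(m):
        for b in range(a + 1, m):
            if cls[a, b] != "strong_ld":
                continue
            strong = sum(
                1
                for u in range(a, b + 1)
                for v in range(u + 1, b + 1)
                if cls[u, v] == "strong_ld"
            )
            recomb = sum(
                1
                for u in range(a, b + 1)
                for v in range(u + 1, b + 1)
                if cls[u, v] == "recombination"
            )
            if strong + recomb and strong / (strong + recomb) >= frac:
                candidates.append((positions[b] - positions[a], a, b))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    used = set()
    blocks = []
    for span, a, b in candidates:
        if any(i in used for i in range(a, b + 1)):
            continue
        used.update(range(a, b + 1))
        blocks.append((a, b))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# least-squares tree search


def _unrooted_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists.

    Edges are (node, node); internal nodes get ids >= n. Built by
    iterative leaf insertion into every edge.
    """
    hub = n  # first internal node id
    trees = [([(0, hub), (1, hub), (2, hub)], hub + 1)]
    for leaf in range(3, n):
        new_trees = []
        for edges, next_id in trees:
            for i, (u, v) in enumerate(edges):
                ne = [e for j, e in enumerate(edges) if j != i]
                mid = next_id
                ne += [(u, mid), (v, mid), (leaf, mid)]
                new_trees.append((ne, next_id + 1))
        trees = new_trees
    return [edges for edges, _ in trees]


def _tree_bipartitions(edges, n: int) -> frozenset:
    bips = set()
    for removed in range(len(edges)):
        adj = {}
        for j, (u, v) in enumerate(edges):
            if j == removed:
                continue
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        u0 = edges[removed][0]
        seen = {u0}
        stack = [u0]
        while stack:
            x = stack.pop()
            for y in adj.get(x, []):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(t for t in seen if t < n)
        if 2 <= len(side) <= n - 2:
            other = frozenset(range(n)) - side
            bips.add(side if sorted(side) < sorted(other) else other)
    return frozenset(bips)


def _path_matrix(edges, n: int) -> np.ndarray:
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        # BFS path from a to b
        prev = {a: None}
        stack = [a]
        while stack:
            x = stack.pop(0)
            if x == b:
                break
            for y, idx in adj[x]:
                if y not in prev:
                    prev[y] = (x, idx)
                    stack.append(y)
        x = b
        while prev[x] is not None:
            x, idx = prev[x]
            A[row, idx] = 1
    return A


def least_squares_topology(D: np.ndarray) -> frozenset:
    """Bipartition set of the OLS-best unrooted topology for distances D."""
    n = D.shape[0]
    pairs = list(combinations(range(n), 2))
    d = np.array([D[a, b] for a, b in pairs])
    best = None
    best_sse = np.inf
    for edges in _unrooted_topologies(n):
        A = _path_matrix(edges, n)
        coef, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ coef - d) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = _tree_bipartitions(edges, n)
    return best


def newick_bipartitions(newick: str, taxa: list[str]) -> frozenset:
    """Non-trivial bipartitions of a Newick tree, as frozensets of indices."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    bips = set()
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        leaves = frozenset(
            index[lf.taxon.label] for lf in edge.head_node.leaf_iter()
        )
        if 2 <= len(leaves) <= n - 2:
            other = frozenset(range(n)) - leaves
            bips.add(leaves if sorted(leaves) < sorted(other) else other)
    return frozenset(bips)
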