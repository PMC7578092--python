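"""Unsupervised grouping of variants from similarity/distance matrices.

Dominant Set clustering treats a symmetric non-negative similarity matrix A
as an edge-weighted graph and extracts clusters as local maximizers of the
quadratic form x'Ax on the standard simplex.  Maximizers are found with
discrete replicator dynamics x_i <- x_i (Ax)_i / (x'Ax) started from the
uniform barycenter; the support of the converged vector is the dominant set,
which is peeled off and the process repeated on the remainder.  The number
of clusters is not specified in advance.

Average linkage (UPGMA-style) agglomeration is implemented with explicit
smallest-id tie-breaking so dendrograms are reproducible; cluster-cluster
distance is the mean of all cross-pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DSParams",
    "DSResult",
    "Dendrogram",
    "dominant_set_peel",
    "ds_reiterate",
    "replicator_dynamics",
    "average_linkage",
    "cut_dendrogram",
    "to_newick",
]


@dataclass(frozen=True)
class DSParams:
    tol: float = 1e-8
    max_iter: int = 10000
    support_threshold: float = 1e-4
    max_clusters: int | None = None
    pool_remainder: bool = True


@dataclass
class DSResult:
    """Ordered extracted clusters with characteristic weights at extraction."""

    clusters: list[set]
    weights: list[dict]
    unassigned: set = field(default_factory=set)

    def assignment(self, ids: list | None = None, pool_remainder: bool = True) -> dict:
        """Map each id to its cluster index; remainder pooled into the last
        cluster index + 1 (or left out when pooling is disabled)."""
        out = {}
        for ci, cluster in enumerate(self.clusters):
            for i in cluster:
                out[i] = ci
        if pool_remainder and self.unassigned:
            for i in self.unassigned:
                out[i] = len(self.clusters)
        return out


def _validate_similarity(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    off = A - np.diag(np.diag(A))
    if np.min(off) < 0:
        raise ValueError("similarity matrix must have non-negative off-diagonal")
    return A


def replicator_dynamics(
    A: np.ndarray, tol: float = 1e-8, max_iter: int = 10000
) -> np.ndarray:
    """Run x_i <- x_i (Ax)_i / (x'Ax) from the barycenter to convergence.

    The iteration preserves the simplex and monotonically increases x'Ax
    (A symmetric, non-negative).  Returns the converged weight vector.

    The start point is the barycenter plus a tiny deterministic index-graded
    perturbation (relative size 1e-3): on matrices with an exact block
    symmetry the barycenter is a saddle point the dynamics would never
    leave, and the perturbation lets the iteration commit to one block.
    """
    n = A.shape[0]
    x = 1.0 + 1e-3 * np.arange(n) / max(n - 1, 1)
    x /= x.sum()
    for _ in range(max_iter):
        Ax = A @ x
        denom = float(x @ Ax)
        if denom <= 0:
            return x  # zero payoff: barycenter is already stationary
        x_new = x * Ax / denom
        if np.abs(x_new - x).sum() < tol:
            return x_new
        x = x_new
    return x


def dominant_set_peel(A: np.ndarray, params: DSParams | None = None) -> DSResult:
    """Peel dominant sets off a similarity matrix until < 2 elements remain.

    The diagonal is zeroed before processing.  A zero payoff at the start of
    a round (e.g. an all-zero remainder) stops the peeling and reports the
    remaining ids as unassigned.
    """
    params = params or DSParams()
    A = _validate_similarity(A).copy()
    np.fill_diagonal(A, 0.0)
    remaining = list(range(A.shape[0]))
    clusters: list[set] = []
    weights: list[dict] = []
    while len(remaining) >= 2:
        if params.max_clusters is not None and len(clusters) >= params.max_clusters:
            break
        sub = A[np.ix_(remaining, remaining)]
        if float(np.sum(sub)) <= 0:
            break
        x = replicator_dynamics(sub, tol=params.tol, max_iter=params.max_iter)
        support = [remaining[i] for i in range(len(remaining)) if x[i] > params.support_threshold]
        if not support:
            break
        clusters.append(set(support))
        weights.append(
            {remaining[i]: float(x[i]) for i in range(len(remaining)) if x[i] > params.support_threshold}
        )
        remaining = [i for i in remaining if i not in clusters[-1]]
    return DSResult(clusters=clusters, weights=weights, unassigned=set(remaining))


def ds_reiterate(A: np.ndarray, cluster: set, params: DSParams | None = None) -> DSResult:
    """Re-run dominant-set peeling inside one previously extracted cluster."""
    ids = sorted(cluster)
    if len(ids) < 2:
        raise ValueError("cluster must contain at least 2 elements")
    A = _validate_similarity(A)
    sub = A[np.ix_(ids, ids)]
    res = dominant_set_peel(sub, params)
    remap = {local: ids[local] for local in range(len(ids))}
    return DSResult(
        clusters=[{remap[i] for i in c} for c in res.clusters],
        weights=[{remap[i]: w for i, w in ws.items()} for ws in res.weights],
        unassigned={remap[i] for i in res.unassigned},
    )


@dataclass
class Dendrogram:
    """Binary agglomeration tree in linkage-matrix form.

    ``merges`` has one row (left, right, height, size) per merge; cluster
    indices 0..n-1 are leaves, n+i is the cluster created by merge i.
    """

    merges: np.ndarray
    n_leaves: int
    ids: list

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        heights = self.merges[:, 2] if len(self.merges) else np.array([])
        if len(heights) > 1 and np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")

    def leaves_of(self, node: int) -> set[int]:
        if node < self.n_leaves:
            return {node}
        left, right = int(self.merges[node - self.n_leaves, 0]), int(
            self.merges[node - self.n_leaves, 1]
        )
        return self.leaves_of(left) | self.leaves_of(right)


def average_linkage(D: np.ndarray, ids: list | None = None) -> Dendrogram:
    """Agglomerative clustering with mean cross-pair cluster distance.

    Ties on the minimum distance are broken by the lexicographically
    smallest pair of cluster member-id sets, so output is deterministic.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.diag(D) != 0) or np.min(D) < 0:
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    n = D.shape[0]
    if ids is None:
        ids = list(range(n))
    if n == 1:
        return Dendrogram(merges=np.zeros((0, 4)), n_leaves=1, ids=list(ids))

    # active clusters: node index -> (member leaf set, min member id)
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_node = n
    while len(active) > 1:
        # pick minimal distance; break ties by smallest (min id of a, min id of b)
        best = None
        for (a, b), d in dist.items():
            key = (d, min(min(active[a]), min(active[b])), max(min(active[a]), min(active[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        d_ab = dist[(min(a, b), max(a, b))]
        size_a, size_b = len(active[a]), len(active[b])
        new = next_node
        next_node += 1
        merged = active[a] | active[b]
        # average-linkage update: weighted mean of distances to a and b
        for c in active:
            if c in (a, b):
                continue
            d_ac = dist[(min(a, c), max(a, c))]
            d_bc = dist[(min(b, c), max(b, c))]
            dist[(c, new)] = (size_a * d_ac + size_b * d_bc) / (size_a + size_b)
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del active[a], active[b]
        active[new] = merged
        merges.append((min(a, b), max(a, b), d_ab, len(merged)))
    return Dendrogram(merges=np.array(merges, dtype=float), n_leaves=n, ids=list(ids))


def cut_dendrogram(tree: Dendrogram, k: int) -> dict:
    """Cut into k clusters by undoing the k-1 highest merges.

    Returns {id: cluster index}; cluster indices are assigned in order of
    the smallest leaf index they contain.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in range(n - k):  # apply the n-k lowest merges
        left, right, _, _ = tree.merges[m]
        node = n + m
        parent[find(int(left))] = node
        parent[find(int(right))] = node

    roots: dict[int, int] = {}
    labels = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[tree.ids[leaf]] = roots[r]
    return labels


def to_newick(tree: Dendrogram) -> str:
    """Newick export; branch lengths are merge-height differences."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    for m, (_, _, h, _) in enumerate(tree.merges):
        height[n + m] = float(h)

    def render(node: int, parent_height: float) -> str:
        bl = parent_height - height[node]
        if node < n:
            return f"{tree.ids[node]}:{bl:.6g}"
        left, right, h, _ = tree.merges[node - n]
        inner = f"({render(int(left), h)},{render(int(right), h)})"
        return f"{inner}:{bl:.6g}"

    if len(tree.merges) == 0:
        return f"({tree.ids[0]}:0);"
    root = n + len(tree.merges) - 1
    left, right, h, _ = tree.merges[-1]
    return f"({render(int(left), h)},{render(int(right), h)});"
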