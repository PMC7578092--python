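"""Vertex Histogram and Weisfeiler-Lehman subtree kernels on labelled graphs.

Both kernels compare graphs through node-label count vectors.  The VH kernel
is the dot product of the label histograms; the WL subtree kernel iteratively
replaces each node label with a compressed (label, sorted neighbour labels)
multiset for h rounds and sums the histogram dot products over rounds
0..h, so WL at h = 0 equals VH.  Label compression uses a single dictionary
shared across the whole ensemble, built in sorted multiset order, which makes
the per-iteration histograms reproducible across runs and node orderings.

For residue interaction networks the node label is the residue position in
the wild-type sequence, so the VH kernel reduces to a comparison of which
residues form any non-covalent contact at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "LabeledGraph",
    "KernelMatrix",
    "from_networkx",
    "vertex_histogram_kernel",
    "wl_relabel",
    "wl_subtree_kernel",
    "similarity_matrix",
    "distance_from_kernel",
]


@dataclass(frozen=True)
class LabeledGraph:
    """Undirected graph with hashable node labels, in adjacency form.

    ``labels[i]`` is the label of node i; ``adj[i]`` lists the neighbour
    indices of node i.  Multi-edges and self-loops are not represented.
    """

    labels: tuple
    adj: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def from_networkx(g: nx.Graph, label_attr: str = "label") -> LabeledGraph:
    """Convert a networkx graph; nodes without ``label_attr`` use the node id."""
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    labels = tuple(g.nodes[v].get(label_attr, v) for v in nodes)
    adj = tuple(
        tuple(sorted(index[u] for u in g.neighbors(v) if u != v)) for v in nodes
    )
    return LabeledGraph(labels=labels, adj=adj)


def _coerce(g) -> LabeledGraph:
    if isinstance(g, LabeledGraph):
        return g
    if isinstance(g, nx.Graph):
        return from_networkx(g)
    raise TypeError(f"expected LabeledGraph or networkx.Graph, got {type(g)!r}")


def _histogram(g: LabeledGraph) -> Counter:
    return Counter(g.labels)


def vertex_histogram_kernel(g1, g2) -> float:
    """Dot product of node-label count vectors: sum_l n1(l) * n2(l)."""
    h1, h2 = _histogram(_coerce(g1)), _histogram(_coerce(g2))
    if len(h2) < len(h1):
        h1, h2 = h2, h1
    return float(sum(c * h2.get(label, 0) for label, c in h1.items()))


def wl_relabel(graphs: list, h: int) -> list[list[Counter]]:
    """Run h rounds of WL relabelling jointly over an ensemble.

    Returns, per graph, the list of compressed-label histograms for
    iterations 0..h.  Iteration 0 histograms count the original labels.
    The compression dictionary is shared across the ensemble and assigned in
    sorted multiset order, so it is injective and deterministic.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    gs = [_coerce(g) for g in graphs]
    current: list[list] = [list(g.labels) for g in gs]
    histories: list[list[Counter]] = [[Counter(lbls)] for lbls in current]

    for _ in range(h):
        multisets: list[list[tuple]] = []
        seen = set()
        for g, lbls in zip(gs, current):
            ms = [
                (lbls[i], tuple(sorted(lbls[j] for j in g.adj[i])))
                for i in range(g.n_nodes)
            ]
            multisets.append(ms)
            seen.update(ms)
        compress = {m: k for k, m in enumerate(sorted(seen))}
        current = [[compress[m] for m in ms] for ms in multisets]
        for hist, lbls in zip(histories, current):
            hist.append(Counter(lbls))
    return histories


def wl_subtree_kernel(g1, g2, h: int = 5) -> float:
    """WL subtree kernel: histogram dot products summed over rounds 0..h."""
    hist1, hist2 = wl_relabel([g1, g2], h)
    total = 0.0
    for c1, c2 in zip(hist1, hist2):
        if len(c2) < len(c1):
            c1, c2 = c2, c1
        total += sum(v * c2.get(label, 0) for label, v in c1.items())
    return float(total)


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over an ordered graph ensemble."""

    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_psd(self, rel_tol: float = 1e-8) -> bool:
        return self.min_eigenvalue() >= -rel_tol * max(np.trace(self.values), 1.0)

    def plot_heatmap(self, path, title: str = "") -> None:
        """Render the similarity matrix as a heatmap (ids on both axes)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.values, cmap="viridis")
        ax.set_xlabel("variant id")
        ax.set_ylabel("variant id")
        if title:
            ax.set_title(title)
        fig.colorbar(im, ax=ax, label="kernel value")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def write_tsv(self, path) -> None:
        header = "id\t" + "\t".join(str(i) for i in self.ids)
        rows = [
            str(gid) + "\t" + "\t".join(f"{v:.10g}" for v in row)
            for gid, row in zip(self.ids, self.values)
        ]
        from pathlib import Path

        Path(path).write_text("\n".join([header] + rows) + "\n")


def similarity_matrix(
    graphs: list,
    kernel: str = "wl",
    h: int = 5,
    normalize: bool = False,
    ids: list | None = None,
) -> KernelMatrix:
    """Pairwise kernel matrix over an ensemble.

    ``kernel`` is ``"vh"`` or ``"wl"``; normalization (off by default)
    rescales to cosine similarity k_ij / sqrt(k_ii k_jj).
    """
    if not graphs:
        raise ValueError("need at least one graph")
    if kernel not in ("vh", "wl"):
        raise ValueError(f"unknown kernel {kernel!r}")
    n = len(graphs)
    histories = wl_relabel(graphs, 0 if kernel == "vh" else h)
    # Stack per-iteration histograms into one sparse feature map per graph.
    features: list[Counter] = []
    for hist in histories:
        feat: Counter = Counter()
        for it, counter in enumerate(hist):
            for label, count in counter.items():
                feat[(it, label)] = count
        features.append(feat)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            fi, fj = features[i], features[j]
            if len(fj) < len(fi):
                fi, fj = fj, fi
            K[i, j] = K[j, i] = sum(v * fj.get(k, 0) for k, v in fi.items())
    if normalize:
        diag = np.sqrt(np.diag(K))
        diag[diag == 0] = 1.0
        K = K / np.outer(diag, diag)
    if ids is None:
        ids = [getattr(g, "id", i) for i, g in enumerate(graphs)]
    return KernelMatrix(values=K, ids=list(ids))


def distance_from_kernel(K: KernelMatrix | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Feature-space Euclidean distances d_ij = sqrt(k_ii + k_jj - 2 k_ij)."""
    values = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    diag = np.diag(values)
    sq = diag[:, None] + diag[None, :] - 2.0 * values
    scale = max(float(np.max(np.abs(values))), 1.0)
    if np.min(sq) < -tol * scale:
        raise ValueError("negative squared distance: kernel matrix is not PSD")
    np.fill_diagonal(sq, 0.0)
    return np.sqrt(np.clip(sq, 0.0, None))
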