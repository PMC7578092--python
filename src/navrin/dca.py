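"""Direct coupling analysis by pseudolikelihood maximization.

Fits a Potts model — per-site fields h_i(a) and pairwise couplings
J_ij(a, b) — to a multiple sequence alignment by minimizing the weighted
negative log-pseudolikelihood (the sum over sites of the conditional
likelihood of each column given the rest) with L2 penalties, the standard
tractable alternative to full maximum likelihood for these models.  Coupling
strength is summarized per pair by the Frobenius norm of J_ij in the
zero-sum gauge, followed by the average product correction (APC), and ranked
scores are compared against a structure-derived contact map.

Sequences are reweighted by 1/(number of neighbours at >= 80% identity) so
densely sampled subfamilies do not dominate the fit.  By default the gap
state is excluded from Frobenius norms, since gaps are alignment artifacts
rather than physical states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .msa_stats import GAP, MSA
from .structure_io import AMINO_ACIDS, Structure

__all__ = [
    "PottsModel",
    "PairScores",
    "ContactMap",
    "encode_msa",
    "sequence_weights",
    "fit_plm",
    "plm_objective",
    "frobenius_apc",
    "contact_map",
    "evaluate_predictions",
]

DEFAULT_ALPHABET = AMINO_ACIDS + GAP  # q = 21, gap last


def encode_msa(msa: MSA, alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Integer-encode an alignment; symbols outside the alphabet -> gap index."""
    lut = {c: i for i, c in enumerate(alphabet)}
    gap_idx = lut.get(GAP, len(alphabet) - 1)
    out = np.empty(msa.matrix.shape, dtype=np.int64)
    for sym, idx in lut.items():
        out[msa.matrix == sym] = idx
    out[~np.isin(msa.matrix, list(alphabet))] = gap_idx
    return out


def sequence_weights(X: np.ndarray | MSA, identity_threshold: float = 0.8) -> np.ndarray:
    """1 / (number of sequences within ``identity_threshold``, self included)."""
    if isinstance(X, MSA):
        X = encode_msa(X)
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    X = np.asarray(X)
    n, L = X.shape
    counts = np.zeros(n, dtype=np.int64)
    # pairwise identity in blocks to bound memory
    block = max(1, 2_000_000 // max(n * L, 1))
    for start in range(0, n, block):
        chunk = X[start : start + block]
        ident = (chunk[:, None, :] == X[None, :, :]).mean(axis=2)
        counts[start : start + block] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


@dataclass
class PottsModel:
    """Fields (L, q) and symmetric couplings (L, L, q, q) with zero diagonal."""

    h: np.ndarray
    J: np.ndarray
    lambda_h: float
    lambda_J: float
    gap_index: int | None = None
    columns: list[int] | None = None

    def __post_init__(self) -> None:
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("coupling tensor shape must be (L, L, q, q)")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]


def _unpack(theta: np.ndarray, L: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    h = theta[: L * q].reshape(L, q)
    Jup = theta[L * q :].reshape(L * (L - 1) // 2, q, q)
    return h, Jup


def _full_J(Jup: np.ndarray, L: int, q: int) -> np.ndarray:
    J = np.zeros((L, L, q, q))
    idx = 0
    for i in range(L):
        for j in range(i + 1, L):
            J[i, j] = Jup[idx]
            J[j, i] = Jup[idx].T
            idx += 1
    return J


def plm_objective(
    theta: np.ndarray,
    X: np.ndarray,
    q: int,
    weights: np.ndarray,
    lambda_h: float,
    lambda_J: float,
) -> tuple[float, np.ndarray]:
    """Weighted negative log-pseudolikelihood and its gradient.

    The model is symmetric: one coupling matrix per unordered pair enters
    the conditionals of both sites.
    """
    n, L = X.shape
    h, Jup = _unpack(theta, L, q)
    J = _full_J(Jup, L, q)
    O = np.zeros((n, L, q))
    O[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0

    nll = 0.0
    grad_h = np.zeros_like(h)
    grad_J = np.zeros_like(J)
    W = weights[:, None]
    for r in range(L):
        # logits: h_r + sum_{j != r} J[r, j][:, x_j]
        Z = h[r][None, :] + np.einsum("njb,jab->na", O, J[r], optimize=True)
        Z -= Z.max(axis=1, keepdims=True)
        expZ = np.exp(Z)
        logsum = np.log(expZ.sum(axis=1))
        P = expZ / expZ.sum(axis=1, keepdims=True)
        nll -= float(np.sum(weights * (Z[np.arange(n), X[:, r]] - logsum)))
        R = W * (P - O[:, r, :])  # (n, q) residual
        grad_h[r] = R.sum(axis=0)
        # d/dJ[r, j, a, b] = sum_n R[n, a] O[n, j, b]
        grad_J[r] += np.einsum("na,njb->jab", R, O, optimize=True)
        grad_J[r, r] = 0.0

    # fold site-wise coupling gradients back onto the upper-triangle parameters
    grad_Jup = np.empty_like(Jup)
    idx = 0
    for i in range(L):
        for j in range(i + 1, L):
            grad_Jup[idx] = grad_J[i, j] + grad_J[j, i].T
            idx += 1

    nll += lambda_h * float(np.sum(h**2)) + lambda_J * float(np.sum(Jup**2))
    grad_h += 2.0 * lambda_h * h
    grad_Jup += 2.0 * lambda_J * Jup
    return nll, np.concatenate([grad_h.ravel(), grad_Jup.ravel()])


def fit_plm(
    msa: MSA | np.ndarray,
    q: int | None = None,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    weights: np.ndarray | None = None,
    identity_threshold: float = 0.8,
    max_iter: int = 500,
    gtol: float = 1e-5,
    columns: list[int] | None = None,
) -> PottsModel:
    """Fit fields and couplings by L-BFGS from zero initialization.

    Accepts an :class:`~navrin.msa_stats.MSA` (encoded over the 21-letter
    alphabet, gap last) or an already integer-encoded (N, L) array with
    states 0..q-1.  ``lambda_J`` defaults to ``0.01 * (q - 1)``.
    """
    gap_index: int | None = None
    if isinstance(msa, MSA):
        X = encode_msa(msa)
        q = len(DEFAULT_ALPHABET)
        gap_index = q - 1
        columns = columns if columns is not None else list(msa.columns)
    else:
        X = np.asarray(msa, dtype=np.int64)
        if q is None:
            q = int(X.max()) + 1
    n, L = X.shape
    if L < 1 or n < 1:
        raise ValueError("alignment must be non-empty")
    if lambda_J is None:
        lambda_J = 0.01 * (q - 1)
    if weights is None:
        weights = sequence_weights(X, identity_threshold)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum() * len(weights)  # keep scale ~ n_eff

    n_params = L * q + (L * (L - 1) // 2) * q * q
    theta0 = np.zeros(n_params)
    res = minimize(
        plm_objective,
        theta0,
        args=(X, q, weights, lambda_h, lambda_J),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "maxfun": 10 * max_iter},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RuntimeError(f"pseudolikelihood fit failed to converge: {res.message}")
    h, Jup = _unpack(res.x, L, q)
    return PottsModel(
        h=h,
        J=_full_J(Jup, L, q),
        lambda_h=lambda_h,
        lambda_J=lambda_J,
        gap_index=gap_index,
        columns=columns,
    )


@dataclass
class PairScores:
    """Raw Frobenius and APC-corrected coupling scores; symmetric, zero diagonal."""

    raw: np.ndarray
    apc: np.ndarray
    positions: list[int]

    def ranking(self, min_separation: int = 1) -> list[tuple[int, int, float]]:
        """Pairs (pos_i, pos_j, apc) sorted by decreasing corrected score."""
        L = self.raw.shape[0]
        pairs = []
        for i in range(L):
            for j in range(i + 1, L):
                if abs(self.positions[j] - self.positions[i]) >= min_separation:
                    pairs.append((self.positions[i], self.positions[j], float(self.apc[i, j])))
        pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
        return pairs

    def write_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["i\tj\traw\tapc\trank"]
        for rank, (i, j, score) in enumerate(self.ranking(), start=1):
            li, lj = self.positions.index(i), self.positions.index(j)
            lines.append(f"{i}\t{j}\t{self.raw[li, lj]:.6g}\t{score:.6g}\t{rank}")
        Path(path).write_text("\n".join(lines) + "\n")


def frobenius_apc(model: PottsModel, exclude_gap: bool = True) -> PairScores:
    """Zero-sum-gauge Frobenius norms with average product correction.

    The gauge shift J'(a,b) = J - rowmean - colmean + grandmean is applied
    over the scored states; the gap state is excluded when the model was fit
    with one (and ``exclude_gap`` is set).
    """
    L, q = model.L, model.q
    states = np.arange(q)
    if exclude_gap and model.gap_index is not None:
        states = states[states != model.gap_index]
    F = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            Jij = model.J[i, j][np.ix_(states, states)]
            Jij = Jij - Jij.mean(axis=0, keepdims=True) - Jij.mean(axis=1, keepdims=True) + Jij.mean()
            F[i, j] = F[j, i] = float(np.sqrt(np.sum(Jij**2)))
    if L > 1 and F.sum() > 0:
        row_mean = F.sum(axis=1) / (L - 1)
        grand = F.sum() / (L * (L - 1))
        apc = F - np.outer(row_mean, row_mean) / grand
    else:
        apc = F.copy()
    np.fill_diagonal(apc, 0.0)
    positions = model.columns if model.columns is not None else list(range(1, L + 1))
    return PairScores(raw=F, apc=apc, positions=list(positions))


@dataclass
class ContactMap:
    """Residue pairs in contact at a heavy-atom distance cutoff."""

    pairs: set[tuple[int, int]]
    cutoff: float
    min_separation: int

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


def contact_map(structure: Structure, cutoff: float = 8.0, min_separation: int = 5) -> ContactMap:
    """Residue pairs whose closest heavy atoms are within ``cutoff`` Angstrom."""
    residues = structure.residues
    coords, owner = [], []
    for idx, res in enumerate(residues):
        for atom in res.atoms:
            if atom.element.upper() not in ("H", "D"):
                coords.append(atom.coord)
                owner.append(idx)
    pairs: set[tuple[int, int]] = set()
    if coords and cutoff > 0:
        coords = np.asarray(coords)
        owner = np.asarray(owner)
        tree = cKDTree(coords)
        for ai, bi in tree.query_pairs(cutoff):
            i, j = owner[ai], owner[bi]
            if i == j:
                continue
            pi, pj = residues[i].position, residues[j].position
            if abs(pi - pj) >= min_separation:
                pairs.add((min(pi, pj), max(pi, pj)))
    return ContactMap(pairs=pairs, cutoff=cutoff, min_separation=min_separation)


def plot_contact_overlay(scores: PairScores, cmap: ContactMap, top_n: int, path) -> None:
    """Overlay of the structure contact map (green) and top predictions (red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    if cmap.pairs:
        xs, ys = zip(*cmap.pairs)
        ax.scatter(xs, ys, s=6, c="green", label="structure contacts")
        ax.scatter(ys, xs, s=6, c="green")
    top = scores.ranking(min_separation=cmap.min_separation)[:top_n]
    if top:
        xs, ys = zip(*[(i, j) for i, j, _ in top])
        ax.scatter(xs, ys, s=10, c="red", label=f"top {top_n} predictions")
        ax.scatter(ys, xs, s=10, c="red")
    ax.set_xlabel("residue position")
    ax.set_ylabel("residue position")
    ax.set_aspect("equal")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate_predictions(scores: PairScores, cmap: ContactMap, top_n: int) -> float:
    """Positive predictive value of the top-n APC-ranked pairs."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = scores.ranking(min_separation=cmap.min_separation)[:top_n]
    if not ranked:
        return 0.0
    hits = sum(1 for i, j, _ in ranked if (i, j) in cmap)
    return hits / len(ranked)
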