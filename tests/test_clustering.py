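"""Dominant-set peeling, replicator dynamics, and average-linkage trees."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from navrin.clustering import (
    DSParams,
    average_linkage,
    cut_dendrogram,
    dominant_set_peel,
    ds_reiterate,
    replicator_dynamics,
    to_newick,
)


def planted_matrix(sizes, within, between, rng=None, noise=0.0):
    n = sum(sizes)
    A = np.full((n, n), between)
    start = 0
    for s in sizes:
        A[start : start + s, start : start + s] = within
        start += s
    if rng is not None and noise > 0:
        A = A + rng.uniform(-noise, noise, (n, n))
        A = (A + A.T) / 2
        A = np.clip(A, 0.0, None)
    np.fill_diagonal(A, 0.0)
    return A


class TestReplicatorDynamics:
    def test_simplex_preserved_and_payoff_nondecreasing(self, rng):
        A = planted_matrix([4, 3], 0.9, 0.1, rng, 0.05)
        n = A.shape[0]
        x = np.full(n, 1.0 / n)
        payoff_prev = -np.inf
        for _ in range(200):
            Ax = A @ x
            denom = x @ Ax
            x = x * Ax / denom
            assert np.all(x >= -1e-12)
            assert np.isclose(x.sum(), 1.0)
            assert denom >= payoff_prev - 1e-12
            payoff_prev = denom

    def test_converged_vector_concentrates_on_cohesive_block(self):
        A = planted_matrix([5, 3], 0.9, 0.1)
        x = replicator_dynamics(A)
        assert x[:5].sum() > 0.99


class TestDominantSetPeel:
    def test_planted_blocks_recovered_in_order(self):
        # the larger, tighter block has higher internal homogeneity
        A = planted_matrix([5, 3], 0.9, 0.1)
        res = dominant_set_peel(A)
        assert res.clusters[0] == set(range(5))
        assert res.clusters[1] == set(range(5, 8))

    def test_extracted_weights_sum_to_one(self):
        A = planted_matrix([5, 3], 0.9, 0.1)
        res = dominant_set_peel(A)
        # weights are the converged replicator vector restricted to support
        assert sum(res.weights[0].values()) == pytest.approx(1.0, abs=1e-3)

    def test_two_elements_form_single_cluster(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = dominant_set_peel(A)
        assert res.clusters == [{0, 1}]

    def test_zero_matrix_leaves_all_unassigned(self):
        res = dominant_set_peel(np.zeros((4, 4)))
        assert res.clusters == []
        assert res.unassigned == {0, 1, 2, 3}

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            dominant_set_peel(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            dominant_set_peel(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_permutation_equivariance(self, rng):
        A = planted_matrix([4, 4], 0.85, 0.15, rng, 0.04)
        perm = rng.permutation(8)
        Ap = A[np.ix_(perm, perm)]
        res = dominant_set_peel(A)
        resp = dominant_set_peel(Ap)
        mapped = [{int(np.where(perm == i)[0][0]) for i in c} for c in res.clusters]
        assert mapped == resp.clusters

    def test_recovery_rate_on_planted_two_blocks(self):
        """Two-block partitions (within >= 0.8, between <= 0.2, n <= 20)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(3, 11, size=2)
            A = planted_matrix(list(sizes), 0.85, 0.15, rng, 0.05)
            res = dominant_set_peel(A)
            assign = res.assignment()
            truth = np.array([0] * sizes[0] + [1] * sizes[1])
            got = np.array([assign.get(i, -1) for i in range(sizes.sum())])
            same = all(
                (got[i] == got[j]) == (truth[i] == truth[j])
                for i in range(len(got))
                for j in range(i + 1, len(got))
            )
            hits += same
        assert hits >= 99


class TestDsReiterate:
    def test_homogeneous_block_does_not_split(self):
        A = planted_matrix([6], 0.9, 0.0)
        res = ds_reiterate(A, set(range(6)))
        assert len(res.clusters) == 1
        assert res.clusters[0] | res.unassigned == set(range(6))

    def test_hidden_subblocks_split(self):
        # block of 8 hiding two 4-element sub-blocks (0.95 within, 0.7 across)
        A = planted_matrix([4, 4], 0.95, 0.7)
        res = ds_reiterate(A, set(range(8)))
        groups = res.clusters + ([res.unassigned] if res.unassigned else [])
        assert {frozenset(g) for g in groups[:2]} == {
            frozenset(range(4)),
            frozenset(range(4, 8)),
        }

    def test_singleton_cluster_rejected(self):
        with pytest.raises(ValueError):
            ds_reiterate(np.zeros((3, 3)), {1})


class TestAverageLinkage:
    def test_hand_agglomeration(self):
        D = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        tree = average_linkage(D)
        assert tree.merges[0, 2] == pytest.approx(1.0)
        assert tree.merges[1, 2] == pytest.approx(10.0)
        assert tree.leaves_of(3) == {0, 1}

    def test_single_leaf(self):
        tree = average_linkage(np.zeros((1, 1)))
        assert tree.n_leaves == 1 and len(tree.merges) == 0

    def test_matches_scipy_merge_heights(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 16))
            pts = rng.normal(size=(n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            tree = average_linkage(D)
            Z = sch.linkage(squareform(D, checks=False), method="average")
            assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(Z[:, 2]))

    def test_heights_nondecreasing(self, rng):
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        tree = average_linkage(D)
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)

    def test_invalid_distance_matrix_rejected(self):
        with pytest.raises(ValueError):
            average_linkage(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestCutDendrogram:
    @pytest.fixture()
    def tree(self):
        D = planted_matrix([3, 3], 0.0, 0.0)
        # convert a block similarity into a distance: within 1, between 10
        D = np.where(D > 0, 1.0, 10.0)
        blocks = np.zeros((6, 6))
        blocks[:3, :3] = 1.0
        blocks[3:, 3:] = 1.0
        D = np.where(blocks > 0, 1.0, 10.0)
        np.fill_diagonal(D, 0.0)
        return average_linkage(D)

    def test_k_n_gives_singletons(self, tree):
        labels = cut_dendrogram(tree, 6)
        assert len(set(labels.values())) == 6

    def test_k_one_gives_single_cluster(self, tree):
        assert set(cut_dendrogram(tree, 1).values()) == {0}

    def test_two_blocks_recovered(self, tree):
        labels = cut_dendrogram(tree, 2)
        assert {labels[i] for i in range(3)} != {labels[i] for i in range(3, 6)}
        assert len({labels[i] for i in range(3)}) == 1

    def test_out_of_range_k_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_dendrogram(tree, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(tree, 7)


def test_newick_export_parseable():
    D = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
    nwk = to_newick(average_linkage(D, ids=["v0", "v1", "v2"]))
    assert nwk.endswith(");")
    assert "v0" in nwk and "v2" in nwk
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["v0", "v1", "v2"]
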