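"""Pseudolikelihood coupling inference, scoring and contact-map evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from navrin.dca import (
    ContactMap,
    PairScores,
    contact_map,
    encode_msa,
    evaluate_predictions,
    fit_plm,
    frobenius_apc,
    plm_objective,
    sequence_weights,
)
from navrin.msa_stats import MSA
from navrin.synthetic_fixtures import PottsSpec, sample_potts_msa


class TestSequenceWeights:
    def test_distinct_sequences_weight_one(self):
        X = np.array([[0, 1, 2], [2, 1, 0], [1, 0, 2]])
        assert np.allclose(sequence_weights(X, 0.8), 1.0)

    def test_duplicate_pair_half_weight(self):
        X = np.array([[0, 1, 2, 3, 4], [0, 1, 2, 3, 4], [4, 3, 2, 1, 0]])
        w = sequence_weights(X, 0.8)
        assert np.allclose(w, [0.5, 0.5, 1.0])

    def test_effective_size_matches_bruteforce(self, rng):
        X = rng.integers(0, 3, size=(10, 8))
        w = sequence_weights(X, 0.6)
        for i in range(10):
            neighbours = sum(
                1 for j in range(10) if (X[i] == X[j]).mean() >= 0.6
            )
            assert w[i] == pytest.approx(1.0 / neighbours)


class TestPlmFit:
    def test_gradient_matches_finite_differences(self, rng):
        X = rng.integers(0, 3, size=(20, 4))
        q, L = 3, 4
        npar = L * q + L * (L - 1) // 2 * q * q
        theta = rng.normal(0, 0.1, npar)
        w = np.ones(20)
        _, g = plm_objective(theta, X, q, w, 0.01, 0.02)
        eps = 1e-5
        idx = rng.choice(npar, size=40, replace=False)
        for i in idx:
            e = np.zeros(npar)
            e[i] = eps
            fp, _ = plm_objective(theta + e, X, q, w, 0.01, 0.02)
            fm, _ = plm_objective(theta - e, X, q, w, 0.01, 0.02)
            num = (fp - fm) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_single_column_fields_reproduce_frequencies(self):
        X = np.array([[0]] * 70 + [[1]] * 30)
        model = fit_plm(X, q=2, lambda_h=1e-6, lambda_J=1e-6, weights=np.ones(100))
        p = np.exp(model.h[0])
        p /= p.sum()
        kl = 0.7 * np.log(0.7 / p[0]) + 0.3 * np.log(0.3 / p[1])
        assert kl < 1e-3
        assert np.allclose(model.J, 0.0, atol=1e-4)

    def test_covarying_pair_gets_top_score(self):
        rng = np.random.default_rng(0)
        n = 400
        # columns 0 and 2 perfectly covary (AB or BA); others independent
        a = rng.integers(0, 2, size=n)
        X = np.stack([a, rng.integers(0, 2, n), 1 - a, rng.integers(0, 2, n)], axis=1)
        model = fit_plm(X, q=2, weights=np.ones(n))
        scores = frobenius_apc(model)
        top = scores.ranking()[0]
        assert {top[0], top[1]} == {1, 3}  # 1-based positions of columns 0 and 2

    def test_independent_columns_score_near_zero(self):
        rng = np.random.default_rng(1)
        n = 400
        a = rng.integers(0, 2, size=n)
        planted = np.stack([a, 1 - a, rng.integers(0, 2, n)], axis=1)
        indep = rng.integers(0, 2, size=(n, 3))
        m_planted = fit_plm(planted, q=2, weights=np.ones(n))
        m_indep = fit_plm(indep, q=2, weights=np.ones(n))
        s_planted = frobenius_apc(m_planted).raw.max()
        s_indep = frobenius_apc(m_indep).raw.max()
        assert s_indep / s_planted < 0.2


class TestFrobeniusApc:
    def test_zero_couplings_zero_scores(self):
        from navrin.dca import PottsModel

        model = PottsModel(h=np.zeros((4, 3)), J=np.zeros((4, 4, 3, 3)),
                           lambda_h=0.01, lambda_J=0.02)
        scores = frobenius_apc(model)
        assert np.allclose(scores.raw, 0.0) and np.allclose(scores.apc, 0.0)

    def test_scores_symmetric(self, rng):
        X = rng.integers(0, 3, size=(100, 5))
        model = fit_plm(X, q=3, weights=np.ones(100), max_iter=100)
        s = frobenius_apc(model)
        assert np.allclose(s.raw, s.raw.T) and np.allclose(s.apc, s.apc.T)

    def test_apc_annihilates_rank_one_background(self):
        # if F_ij = u_i u_j the correction removes everything off-diagonal
        u = np.array([1.0, 2.0, 3.0, 4.0])
        F = np.outer(u, u)
        np.fill_diagonal(F, 0.0)
        L = 4
        row = F.sum(axis=1) / (L - 1)
        grand = F.sum() / (L * (L - 1))
        apc = F - np.outer(row, row) / grand
        # exact annihilation holds for constant u; for general u it shrinks
        assert np.abs(apc).max() < np.abs(F).max()

    def test_state_relabeling_invariance(self, rng):
        X = rng.integers(0, 3, size=(200, 4))
        perm = np.array([2, 0, 1])
        m1 = fit_plm(X, q=3, weights=np.ones(200))
        m2 = fit_plm(perm[X], q=3, weights=np.ones(200))
        s1, s2 = frobenius_apc(m1), frobenius_apc(m2)
        assert np.allclose(s1.raw, s2.raw, atol=1e-3)


class TestContactMap:
    def test_helix_contacts_match_bruteforce(self, helix_structure):
        cmap = contact_map(helix_structure, cutoff=8.0, min_separation=5)
        residues = helix_structure.residues
        for i, ri in enumerate(residues):
            for rj in residues[i + 1 :]:
                if abs(ri.position - rj.position) < 5:
                    continue
                dmin = min(
                    np.linalg.norm(a.coord - b.coord)
                    for a in ri.atoms
                    for b in rj.atoms
                )
                expected = dmin <= 8.0
                assert ((ri.position, rj.position) in cmap) == expected

    def test_zero_cutoff_empty(self, helix_structure):
        assert contact_map(helix_structure, cutoff=0.0).pairs == set()

    def test_huge_separation_empty(self, helix_structure):
        assert contact_map(helix_structure, cutoff=8.0, min_separation=100).pairs == set()


class TestEvaluatePredictions:
    def _scores(self, apc, positions):
        return PairScores(raw=np.abs(apc), apc=apc, positions=positions)

    def test_all_hits_give_one(self):
        apc = np.array([[0, 3.0, 1.0], [3.0, 0, 2.0], [1.0, 2.0, 0]])
        cm = ContactMap(pairs={(1, 2), (2, 3), (1, 3)}, cutoff=8.0, min_separation=1)
        assert evaluate_predictions(self._scores(apc, [1, 2, 3]), cm, 3) == 1.0

    def test_random_scores_ppv_tracks_density(self, rng):
        L = 20
        positions = list(range(1, L + 1))
        all_pairs = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]
        ppvs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            apc = r.normal(size=(L, L))
            apc = (apc + apc.T) / 2
            np.fill_diagonal(apc, 0.0)
            chosen = {p for p in all_pairs if r.random() < 0.4}
            cm = ContactMap(pairs=chosen, cutoff=8.0, min_separation=1)
            ppvs.append(evaluate_predictions(self._scores(apc, positions), cm, 20))
        assert abs(np.mean(ppvs) - 0.4) < 0.15

    def test_invalid_top_n_rejected(self):
        cm = ContactMap(pairs=set(), cutoff=8.0, min_separation=1)
        with pytest.raises(ValueError):
            evaluate_predictions(self._scores(np.zeros((2, 2)), [1, 2]), cm, 0)


class TestPlantedPottsRecovery:
    def test_recovery_on_planted_fixture(self):
        """Planted 12-site, 8-edge, 4-state model: top-8 precision and AUC."""
        spec = PottsSpec(L=12, q=4, n_edges=8)
        X, edges, _, _ = sample_potts_msa(spec, n_sequences=2000, burn_in=300, seed=11)
        model = fit_plm(X, q=4)
        scores = frobenius_apc(model)
        ranked = scores.ranking(min_separation=1)
        true = {(i + 1, j + 1) for i, j in edges}
        top8 = [(i, j) for i, j, _ in ranked[:8]]
        ppv = sum(1 for p in top8 if p in true) / 8
        assert ppv >= 0.75
        y = [1 if (i, j) in true else 0 for i, j, _ in ranked]
        s = [v for _, _, v in ranked]
        assert roc_auc_score(y, s) > 0.9


def test_contact_overlay_rendering(tmp_path):
    apc = np.array([[0, 3.0, 1.0], [3.0, 0, 2.0], [1.0, 2.0, 0]])
    scores = PairScores(raw=np.abs(apc), apc=apc, positions=[1, 2, 3])
    cm = ContactMap(pairs={(1, 2)}, cutoff=8.0, min_separation=1)
    from navrin.dca import plot_contact_overlay

    out = tmp_path / "overlay.png"
    plot_contact_overlay(scores, cm, 2, out)
    assert out.stat().st_size > 0


def test_encode_msa_roundtrip():
    m = MSA(ids=["a"], matrix=np.array([list("AC-W")]))
    X = encode_msa(m)
    assert X.shape == (1, 4)
    assert X[0, 2] == 20  # gap is the last state
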