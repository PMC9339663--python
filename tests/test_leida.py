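"""Phase-locking tensor, leading eigenvectors, mode clustering and matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import dfckit as dk
from dfckit.leida import _sign_normalize


class TestPhaseLockingTensor:
    def test_equal_phases_give_all_ones(self):
        theta = np.full((4, 3), 0.7)
        ipl = dk.phase_locking_tensor(theta)
        np.testing.assert_allclose(ipl, 1.0)

    def test_antiphase_gives_minus_one(self):
        theta = np.array([[0.0], [np.pi]])
        ipl = dk.phase_locking_tensor(theta)
        assert ipl[0, 0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_quadrature_gives_zero(self):
        theta = np.array([[0.0], [np.pi / 2]])
        ipl = dk.phase_locking_tensor(theta)
        assert ipl[0, 0, 1] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 6), st.integers(1, 5)),
            elements=st.floats(-np.pi + 1e-6, np.pi),
        )
    )
    def test_slices_symmetric_unit_diagonal_bounded(self, theta):
        ipl = dk.phase_locking_tensor(theta)
        np.testing.assert_array_equal(ipl, np.swapaxes(ipl, 1, 2))
        n = theta.shape[0]
        np.testing.assert_array_equal(ipl[:, np.arange(n), np.arange(n)], 1.0)
        assert np.all(ipl >= -1.0) and np.all(ipl <= 1.0)


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        n = 6
        v, lam = dk.leading_eigenvector(np.ones((n, n)))
        assert lam == pytest.approx(n)
        np.testing.assert_allclose(v, -np.ones(n) / np.sqrt(n), atol=1e-12)

    def test_two_block_antiphase_splits_by_block(self):
        # within-block +1, between-block -1: rank-one uuT with u = (+1.., -1..)
        n1, n2 = 3, 5
        u = np.concatenate([np.ones(n1), -np.ones(n2)])
        m = np.outer(u, u)
        np.fill_diagonal(m, 1.0)
        v, _ = dk.leading_eigenvector(m)
        assert np.all(v[:n1] > 0) and np.all(v[n1:] < 0)

    def test_matches_full_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            a = rng.normal(size=(8, 8))
            m = (a + a.T) / 2
            v, lam = dk.leading_eigenvector(m)
            # brute-force oracle over the full spectrum
            vals, vecs = np.linalg.eig(m)
            i = np.argmax(np.abs(vals))
            assert lam == pytest.approx(np.real(vals[i]), rel=1e-10)
            cos = abs(np.dot(v, np.real(vecs[:, i])) / np.linalg.norm(vecs[:, i]))
            assert cos > 1 - 1e-10

    def test_rank_one_reconstruction_is_best(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(5, 5))
        m = (a + a.T) / 2
        v, lam = dk.leading_eigenvector(m)
        best = np.linalg.norm(m - lam * np.outer(v, v))
        vals, vecs = np.linalg.eigh(m)
        for i in range(5):
            other = np.linalg.norm(m - vals[i] * np.outer(vecs[:, i], vecs[:, i]))
            assert best <= other + 1e-10

    def test_sign_convention_total(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            v = _sign_normalize(rng.normal(size=7))
            assert np.sum(v > 0) <= np.sum(v < 0)


class TestClusterModes:
    def _planted_vectors(self, rng, k=3, n=12, per=80, sigma=0.05):
        base = np.linalg.qr(rng.normal(size=(n, k)))[0]
        base = np.column_stack([_sign_normalize(base[:, j]) for j in range(k)])
        cols = []
        for j in range(k):
            pts = base[:, j][:, None] + sigma * rng.normal(size=(n, per))
            cols.append(pts / np.linalg.norm(pts, axis=0))
        x = np.concatenate(cols, axis=1)
        return base, dk.EigenStream(x, np.ones(x.shape[1]))

    def test_recovers_planted_orthogonal_directions(self):
        rng = np.random.default_rng(12)
        base, es = self._planted_vectors(rng)
        ms = dk.cluster_modes(es, k_range=[3], replicates=20, seed=3,
                              compute_silhouette=False)[3]
        sims = np.abs(base.T @ ms.centroids)
        assert np.all(sims.max(axis=1) > 0.99)

    def test_identical_vectors_k1(self):
        v = _sign_normalize(np.array([0.3, -0.5, -0.6, -0.55]))
        v = v / np.linalg.norm(v)
        x = np.tile(v[:, None], (1, 50))
        es = dk.EigenStream(x, np.ones(50))
        ms = dk.cluster_modes(es, k_range=[1], replicates=3, seed=0,
                              compute_silhouette=False)[1]
        np.testing.assert_allclose(ms.centroids[:, 0], v, atol=1e-12)

    def test_fixed_seed_is_bit_deterministic(self):
        rng = np.random.default_rng(13)
        _, es = self._planted_vectors(rng)
        a = dk.cluster_modes(es, k_range=[3], replicates=10, seed=42,
                             compute_silhouette=False)[3]
        b = dk.cluster_modes(es, k_range=[3], replicates=10, seed=42,
                             compute_silhouette=False)[3]
        np.testing.assert_array_equal(a.centroids, b.centroids)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSilhouetteSelection:
    def test_planted_three_clusters_selects_k3(self):
        rng = np.random.default_rng(14)
        base = TestClusterModes()._planted_vectors(rng)[1]
        modesets = dk.cluster_modes(base, k_range=range(2, 6), replicates=10,
                                    seed=1)
        best, table = dk.select_k_silhouette(modesets)
        assert best == 3
        assert table.shape[0] == 4

    def test_isotropic_cloud_has_low_silhouette(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(10, 200))
        x /= np.linalg.norm(x, axis=0)
        es = dk.EigenStream(x, np.ones(200))
        modesets = dk.cluster_modes(es, k_range=range(2, 5), replicates=5, seed=2)
        _, table = dk.select_k_silhouette(modesets)
        assert (table["silhouette"] < 0.3).all()

    def test_exact_tie_prefers_smaller_k(self):
        a = dk.ModeSet(k=2, centroids=np.eye(3)[:, :2], labels=np.array([1, 2]),
                       silhouette=0.5)
        b = dk.ModeSet(k=3, centroids=np.eye(3), labels=np.array([1, 2, 3]),
                       silhouette=0.5)
        best, _ = dk.select_k_silhouette({2: a, 3: b})
        assert best == 2


class TestAssignModes:
    def _modes(self):
        c = np.column_stack([
            _sign_normalize(np.array([-1.0, -1.0, -1.0, -1.0]) / 2.0),
            _sign_normalize(np.array([1.0, -1.0, -1.0, -1.0]) / 2.0),
        ])
        return dk.ModeSet(k=2, centroids=c, labels=np.array([1, 2]))

    def test_exact_centroid_match(self):
        ms = self._modes()
        labels = dk.assign_modes(ms.centroids[:, [1]], ms)
        assert labels[0] == 2

    def test_negated_centroid_prefers_orthogonal(self):
        # distance to -c2 is 2; an orthogonal centroid is nearer (distance 1)
        c1 = np.array([1.0, 0.0, 0.0, 0.0])
        c2 = _sign_normalize(np.array([0.0, -1.0, 0.0, 0.0]))
        ms = dk.ModeSet(k=2, centroids=np.column_stack([c1, c2]),
                        labels=np.array([1, 2]))
        labels = dk.assign_modes(-c2[:, None], ms)
        assert labels[0] == 1

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(16)
        c = rng.normal(size=(9, 4))
        c /= np.linalg.norm(c, axis=0)
        ms = dk.ModeSet(k=4, centroids=c, labels=np.arange(4) + 1)
        x = rng.normal(size=(9, 1000))
        got = dk.assign_modes(x, ms)
        xn = x / np.linalg.norm(x, axis=0)
        for t in range(1000):
            dists = [1 - float(c[:, j] @ xn[:, t]) for j in range(4)]
            assert got[t] == int(np.argmin(dists)) + 1


class TestMatchModes:
    def _random_modeset(self, rng, n=10, k=5, noise=0.0, base=None):
        if base is None:
            base = rng.normal(size=(n, k))
        c = base + noise * rng.normal(size=(n, k))
        c /= np.linalg.norm(c, axis=0)
        c = np.column_stack([_sign_normalize(c[:, j]) for j in range(k)])
        return dk.ModeSet(k=k, centroids=c, labels=rng.integers(1, k + 1, 30))

    def test_self_match_is_identity(self):
        rng = np.random.default_rng(17)
        ms = self._random_modeset(rng)
        perm, sims = dk.match_modes_across_runs(ms, ms)
        np.testing.assert_array_equal(perm, np.arange(5))
        np.testing.assert_allclose(sims, 1.0)

    def test_recovers_known_shuffle(self):
        rng = np.random.default_rng(18)
        ms = self._random_modeset(rng)
        shuffle = np.array([2, 0, 4, 1, 3])
        other = dk.reorder_modes(ms, shuffle)
        perm, sims = dk.match_modes_across_runs(ms, other)
        recovered = dk.reorder_modes(other, perm)
        np.testing.assert_allclose(recovered.centroids, ms.centroids)
        np.testing.assert_allclose(sims, 1.0)

    def test_noisy_shuffle_agrees_with_brute_force(self):
        rng = np.random.default_rng(19)
        base = rng.normal(size=(10, 5))
        ref = self._random_modeset(rng, base=base)
        other = self._random_modeset(rng, base=base[:, [3, 1, 4, 0, 2]], noise=0.05)
        perm, _ = dk.match_modes_across_runs(ref, other)
        sim = ref.centroids.T @ other.centroids
        best_total, best_perm = -np.inf, None
        for p in itertools.permutations(range(5)):
            tot = sum(sim[i, p[i]] for i in range(5))
            if tot > best_total:
                best_total, best_perm = tot, p
        np.testing.assert_array_equal(perm, best_perm)

    def test_low_similarity_warns(self):
        rng = np.random.default_rng(20)
        a = self._random_modeset(rng)
        b = self._random_modeset(rng)
        with pytest.warns(UserWarning, match="below 0.5"):
            dk.match_modes_across_runs(a, b)


class TestExtractCommunity:
    def test_global_mode_spans_all_regions(self):
        v = -np.abs(np.random.default_rng(21).normal(size=8))
        assert dk.extract_community(v).size == 8

    def test_positive_entries_form_community(self):
        v = np.array([-0.5, 0.2, -0.4, 0.3, -0.6, 0.1])
        np.testing.assert_array_equal(dk.extract_community(v), [1, 3, 5])

    def test_counting_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(50):
            v = _sign_normalize(rng.normal(size=11))
            comm = dk.extract_community(v)
            n_pos = sum(1 for x in v if x > 0)
            assert comm.size == (n_pos if n_pos else 11)


class TestModeAgreementIcc:
    def test_identical_centroids_give_unity(self):
        rng = np.random.default_rng(23)
        c = rng.normal(size=(12, 3))
        out = dk.mode_agreement_icc([c, c, c, c], form="1,1")
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_matches_one_way_anova_oracle(self):
        rng = np.random.default_rng(24)
        base = rng.normal(size=(12, 1))
        runs = [base + 0.1 * rng.normal(size=(12, 1)) for _ in range(4)]
        got = dk.mode_agreement_icc(runs, form="1,1")[0]
        # direct mean-squares oracle
        x = np.column_stack([r[:, 0] for r in runs])
        n, k = x.shape
        grand = x.mean()
        bms = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
        wms = np.sum((x - x.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
        expect = (bms - wms) / (bms + (k - 1) * wms)
        assert got == pytest.approx(expect, abs=1e-12)
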