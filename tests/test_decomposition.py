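"""Rank selection, sparse NMF, map thresholding, profiles, clustering."""

import numpy as np
import pytest

from breathmod import decomposition as dc


def jaccard(a, b):
    a, b = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    return len(a & b) / len(a | b)


class TestNormalizeSubjectMI:
    def test_runs_scaled_to_unit_sd_then_averaged(self):
        rng = np.random.default_rng(0)
        r1, r2 = 3.0 * rng.random((36, 50)), 0.2 * rng.random((36, 50))
        out = dc.normalize_subject_mi(r1, r2)
        oracle = 0.5 * (r1 / r1.std() + r2 / r2.std())
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert (r1 / r1.std()).std() == pytest.approx(1.0)

    def test_identical_runs_collapse_to_one(self):
        r = np.random.default_rng(1).random((10, 20))
        np.testing.assert_allclose(
            dc.normalize_subject_mi(r, r), r / r.std(), atol=1e-12
        )

    def test_zero_sd_run_rejected(self):
        with pytest.raises(ValueError):
            dc.normalize_subject_mi(np.ones((4, 4)), np.random.rand(4, 4))


class TestGroupMatrix:
    def test_28_subjects_36_freqs_give_1008_rows(self):
        mats = [np.random.rand(36, 40) for _ in range(28)]
        x = dc.build_group_matrix(mats)
        assert x.shape == (1008, 40)

    def test_single_subject_and_round_trip(self):
        mats = [np.random.default_rng(i).random((36, 10)) for i in range(4)]
        x = dc.build_group_matrix(mats)
        for orig, back in zip(mats, dc.split_group_matrix(x, 4)):
            np.testing.assert_array_equal(orig, back)
        np.testing.assert_array_equal(dc.build_group_matrix(mats[:1]), mats[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dc.build_group_matrix([np.ones((3, 4)), np.ones((3, 5))])


class TestSelectRank:
    def test_exact_singular_value_arithmetic(self):
        assert dc.select_rank(np.outer([1, 2.0], [3, 4.0])) == 1
        # singular values (5, 3, 1, 1): cumulative 5, 8, 9 of 10 -> k=3
        m = np.diag([5.0, 3.0, 1.0, 1.0])
        assert dc.select_rank(m) == 3
        assert dc.select_rank(np.eye(10)) == 9

    def test_monotone_in_fraction(self):
        m = np.random.default_rng(2).random((20, 30))
        ks = [dc.select_rank(m, f) for f in (0.5, 0.7, 0.9, 0.99)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dc.select_rank(np.zeros((5, 5)))

    def test_subject_median_aggregation(self):
        mats = [np.diag([5.0, 3.0, 1.0, 1.0]), np.eye(4), np.outer(
            np.ones(4), np.ones(4))]
        k, ks = dc.select_rank_subjects(mats)
        assert list(ks) == [3, 4, 1]  # identity needs 4 of 4 to reach 90%
        assert k == 3


class TestSparseNMF:
    def test_zero_matrix_gives_zero_factorisation(self):
        res = dc.sparse_nmf(np.zeros((6, 8)), k=2, n_restarts=1)
        assert res.residual == 0.0
        assert not np.any(res.basis) and not np.any(res.coefficients)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            dc.sparse_nmf(-np.ones((3, 3)), 1)

    def test_planted_rank2_disjoint_supports_recovered(self):
        # separable planted basis (rows exclusive to each component)
        # makes the nonnegative factorisation essentially unique
        rng = np.random.default_rng(3)
        a0 = rng.random((30, 2)) + 0.5
        a0[:10, 1] = 0.0
        a0[10:20, 0] = 0.0
        y0 = np.zeros((2, 40))
        y0[0, :18] = rng.random(18) + 0.5
        y0[1, 22:] = rng.random(18) + 0.5
        x = a0 @ y0
        res = dc.sparse_nmf(x, k=2, eta=0.0, lam=0.0, n_restarts=10,
                            max_iter=300, seed=4)
        assert res.residual / np.linalg.norm(x) < 1e-3
        assert np.all(res.basis >= 0) and np.all(res.coefficients >= 0)
        # support threshold sits above the solver's convergence floor
        recovered = [np.flatnonzero(res.coefficients[c] > 1e-3 *
                                    res.coefficients[c].max())
                     for c in range(2)]
        planted = [np.arange(18), np.arange(22, 40)]
        scores = [
            max(jaccard(rec, planted[0]), jaccard(rec, planted[1]))
            for rec in recovered
        ]
        assert min(scores) > 0.9

    def test_objective_monotone_within_restart(self):
        x = np.random.default_rng(5).random((15, 25))
        res = dc.sparse_nmf(x, k=3, lam=0.05, n_restarts=3, max_iter=50, seed=6)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_voxel_permutation_equivariance(self):
        x = np.random.default_rng(7).random((12, 20))
        perm = np.random.default_rng(8).permutation(20)
        a = dc.sparse_nmf(x, k=2, n_restarts=2, max_iter=60, seed=9)
        b = dc.sparse_nmf(x[:, perm], k=2, n_restarts=2, max_iter=60, seed=9)
        assert a.residual == pytest.approx(b.residual, rel=1e-6)

    def test_sparsity_penalty_prunes_small_weights(self):
        rng = np.random.default_rng(10)
        a0 = rng.random((20, 2)) + 0.5
        y0 = np.zeros((2, 30))
        y0[0, :12] = 1.0
        y0[1, 18:] = 1.0
        x = a0 @ y0 + 0.05 * rng.random((20, 30))
        plain = dc.sparse_nmf(x, 2, eta=0.0, lam=0.0, n_restarts=3,
                              max_iter=100, seed=11)
        sparse = dc.sparse_nmf(x, 2, eta=0.0, lam=2.0, n_restarts=3,
                               max_iter=100, seed=11)
        assert (sparse.coefficients < 1e-10).mean() >= (
            plain.coefficients < 1e-10).mean()


class TestThresholdMap:
    def test_fraction_retained_by_ceil_rule(self):
        rng = np.random.default_rng(12)
        assert dc.threshold_map(rng.random(20173), 99.0).size == 202
        assert dc.threshold_map(rng.random(200), 99.0).size == 2

    def test_top_weights_selected(self):
        w = np.array([0.1, 5.0, 0.2, 4.0, 0.3])
        np.testing.assert_array_equal(dc.threshold_map(w, 60.0), [1, 3])

    def test_ties_break_by_ascending_voxel_id(self):
        ids = dc.threshold_map(np.ones(100), 95.0)
        np.testing.assert_array_equal(ids, np.arange(5))


class TestComponentProfiles:
    def test_single_voxel_set_is_zscored_matrix(self):
        rng = np.random.default_rng(13)
        g = rng.random((10, 6, 20))
        profs = dc.component_profiles(g, [np.array([4])])
        expected = (g[4] - g[4].mean()) / g[4].std()
        np.testing.assert_allclose(profs[0].values, expected, atol=1e-12)
        assert profs[0].values.shape == (6, 20)

    def test_empty_voxel_set_rejected(self):
        with pytest.raises(ValueError, match="empty voxel set"):
            dc.component_profiles(np.random.rand(5, 6, 20), [np.array([], int)])


class TestClusterComponents:
    @staticmethod
    def _profiles_from_templates(templates, n_each, noise, seed):
        rng = np.random.default_rng(seed)
        profs, labels = [], []
        for k, tmpl in enumerate(templates):
            for _ in range(n_each):
                v = tmpl + noise * rng.standard_normal(tmpl.shape)
                profs.append(dc.ComponentProfile(values=v, component_id=len(profs)))
                labels.append(k)
        return profs, np.array(labels)

    def test_two_separated_groups_perfectly_recovered(self):
        rng = np.random.default_rng(14)
        t1, t2 = rng.standard_normal((6, 20)), rng.standard_normal((6, 20)) + 5
        profs, truth = self._profiles_from_templates([t1, t2], 5, 0.05, 15)
        res = dc.cluster_components(profs)
        assert res.n_clusters == 2
        # perfect agreement up to label permutation
        for k in (0, 1):
            assert np.unique(res.labels[truth == k]).size == 1
        assert res.labels[truth == 0][0] != res.labels[truth == 1][0]

    def test_seven_templates_recovered_from_18_components(self):
        rng = np.random.default_rng(16)
        templates = [3.0 * rng.standard_normal((6, 20)) for _ in range(7)]
        counts = [4, 3, 3, 2, 2, 2, 2]  # 18 components total
        profs = []
        for k, tmpl in enumerate(templates):
            for _ in range(counts[k]):
                profs.append(dc.ComponentProfile(
                    values=tmpl + 0.2 * rng.standard_normal((6, 20)),
                    component_id=len(profs)))
        res = dc.cluster_components(profs)
        assert res.n_clusters == 7

    def test_identical_profiles_rejected(self):
        profs = [dc.ComponentProfile(values=np.ones((6, 20)), component_id=i)
                 for i in range(4)]
        with pytest.raises(ValueError, match="identical"):
            dc.cluster_components(profs)

    def test_candidate_counts_validated(self):
        rng = np.random.default_rng(17)
        profs = [dc.ComponentProfile(values=rng.standard_normal((6, 20)),
                                     component_id=i) for i in range(5)]
        with pytest.raises(ValueError):
            dc.cluster_components(profs, candidate_counts=[1])


class TestAgainstLibraryNMF:
    def test_unpenalised_residual_comparable_to_sklearn(self):
        """With eta = lam = 0 the objective coincides with classic NMF:
        our ANLS residual should not be worse than scikit-learn's
        multiplicative-update solution by more than a few percent."""
        from sklearn.decomposition import NMF

        x = np.random.default_rng(18).random((25, 35))
        ours = dc.sparse_nmf(x, 4, eta=0.0, lam=0.0, n_restarts=5,
                             max_iter=200, seed=19)
        ref = NMF(n_components=4, init="random", random_state=0,
                  max_iter=2000, tol=1e-8).fit(x)
        ref_resid = np.linalg.norm(x - ref.transform(x) @ ref.components_)
        assert ours.residual <= ref_resid * 1.05
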