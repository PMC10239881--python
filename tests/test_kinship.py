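"""Coancestry estimator calibration, PCoA structure, rank-sum contrasts."""

import numpy as np
import pytest

from conftest import make_dosage_matrix
from ploidypop import synthio
from ploidypop.kinship import (
    CoancestryMatrix,
    cross_group_values,
    group_relatedness_test,
    pairwise_coancestry,
    pcoa,
    relatedness_linkage,
)


def brute_force_coancestry(dosage, ploidy, missing, freqs):
    """Independent loop-based implementation of the estimator."""
    n, l = dosage.shape
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            vals = []
            for s in range(l):
                p = freqs[s]
                if missing[i, s] or missing[j, s] or p <= 0 or p >= 1:
                    continue
                xa = dosage[i, s] / ploidy[i]
                ya = dosage[j, s] / ploidy[j]
                vals.append(xa * ya / p + (1 - xa) * (1 - ya) / (1 - p) - 1)
            if vals:
                out[i, j] = np.mean(vals) * np.sqrt(ploidy[i] * ploidy[j])
    return out


class TestEstimator:
    def test_single_locus_hand_arithmetic(self):
        # both diploids homozygous alternate at p = 0.5:
        # theta = 1*1/0.5 - 1 = 1, rescaled r = 2 (illustrates r > 1)
        m = make_dosage_matrix([[2], [2]], [2, 2])
        coa = pairwise_coancestry(m, np.array([0.5]))
        assert coa.values[0, 1] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        ploidy = np.array([2, 4, 2, 4])
        dosage = np.stack([rng.integers(0, v + 1, size=3) for v in ploidy])
        missing = rng.random((4, 3)) < 0.2
        freqs = np.array([0.3, 0.5, 0.8])
        m = make_dosage_matrix(dosage, ploidy, missing)
        coa = pairwise_coancestry(m, freqs)
        expected = brute_force_coancestry(dosage, ploidy, missing, freqs)
        both = np.isfinite(expected)
        np.testing.assert_allclose(coa.values[both], expected[both], atol=1e-12)

    def test_symmetry_and_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(12, 80))
        m = make_dosage_matrix(dosage, [2] * 12)
        coa = pairwise_coancestry(m)
        np.testing.assert_allclose(coa.values, coa.values.T, atol=1e-12)
        perm = rng.permutation(12)
        coa_p = pairwise_coancestry(m.take_individuals(perm))
        np.testing.assert_allclose(
            coa_p.values, coa.values[np.ix_(perm, perm)], atol=1e-12
        )

    def test_calibration_self_parent_offspring_unrelated(self):
        # pedigreed diploid simulation at 2,000 loci: expectations are
        # self = 1, parent-offspring = 1/2, unrelated = 0 (3-SE tolerance)
        rng = np.random.default_rng(2)
        l, n_pairs = 2000, 40
        p = rng.uniform(0.1, 0.9, l)
        parents = rng.binomial(2, p, size=(n_pairs, l))
        transmitted = rng.binomial(1, parents / 2)
        offspring = transmitted + rng.binomial(1, p, size=(n_pairs, l))
        dosage = np.vstack([parents, offspring])
        m = make_dosage_matrix(dosage, [2] * (2 * n_pairs))
        coa = pairwise_coancestry(m, p)

        selfs = np.diag(coa.values)
        po = np.array([coa.values[i, n_pairs + i] for i in range(n_pairs)])
        unrel = np.array(
            [coa.values[i, j] for i in range(n_pairs) for j in range(i + 1, n_pairs)]
        )
        for vals, expected in ((selfs, 1.0), (po, 0.5), (unrel, 0.0)):
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) < 3 * se + 1e-3

    def test_tetraploid_self_relatedness_calibrates_to_one(self):
        rng = np.random.default_rng(3)
        l = 2000
        p = rng.uniform(0.1, 0.9, l)
        dosage = rng.binomial(4, p, size=(40, l))
        m = make_dosage_matrix(dosage, [4] * 40)
        coa = pairwise_coancestry(m, p)
        selfs = np.diag(coa.values)
        se = selfs.std(ddof=1) / np.sqrt(len(selfs))
        assert abs(selfs.mean() - 1.0) < 3 * se

    def test_unrelated_same_pool_near_zero(self, two_pool_dataset):
        _, truth, dosages, _ = two_pool_dataset
        pool0 = np.where(truth.cluster_of == 0)[0][:40]
        m = dosages.take_individuals(pool0)
        coa = pairwise_coancestry(m, truth.true_cluster_freqs[0])
        off = coa.values[np.triu_indices(len(pool0), k=1)]
        se = off.std(ddof=1) / np.sqrt(len(off))
        assert abs(off.mean()) < 3 * se + 1e-3

    def test_zero_shared_loci_pair_is_missing(self):
        missing = np.array([[False, True], [True, False]])
        m = make_dosage_matrix([[1, 0], [0, 1]], [2, 2], missing)
        coa = pairwise_coancestry(m, np.array([0.5, 0.5]))
        assert np.isnan(coa.values[0, 1])
        assert np.isfinite(coa.values[0, 0])


class TestPCoA:
    def _matrix(self, values):
        n = len(values)
        return CoancestryMatrix(
            np.asarray(values, dtype=float),
            np.full((n, n), 10),
            [f"s{i}" for i in range(n)],
        )

    def test_identity_matrix_has_flat_spectrum(self):
        res = pcoa(self._matrix(np.eye(4)), n_axes=2)
        np.testing.assert_allclose(res.eigenvalues, 1.0)

    def test_two_block_matrix_separates_on_axis_one(self):
        block = np.ones((3, 3))
        m = np.block(
            [[block, np.zeros((3, 3))], [np.zeros((3, 3)), block]]
        )
        res = pcoa(self._matrix(m), n_axes=2)
        signs = np.sign(res.coordinates[:, 0])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_variance_explained_fractions_bounded(self, four_pool_dataset):
        _, _, dosages, _ = four_pool_dataset
        coa = pairwise_coancestry(dosages)
        res = pcoa(coa, n_axes=3)
        lead = res.variance_explained[:3].sum()
        assert 0.0 < lead < 1.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            pcoa(_NonSquare())


class _NonSquare:
    values = np.zeros((2, 3))
    samples = ["a", "b"]


class TestGroupContrast:
    def test_identical_sets_not_significant(self):
        vals = np.arange(50, dtype=float)
        _, p = group_relatedness_test(vals, vals.copy())
        assert p > 0.9

    def test_shifted_sets_highly_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.2, 0.1, 200)
        b = rng.normal(0.0, 0.1, 200)
        _, p = group_relatedness_test(a + 0.0, b)
        assert p < 0.001

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            group_relatedness_test(np.array([]), np.array([1.0]))

    def test_tetraploids_closer_to_their_parental_pool(self):
        # tetraploids built from pool-1 frequencies must show higher
        # relatedness to pool-1 diploids than to pool-2 diploids
        rng = np.random.default_rng(5)
        l = 1500
        base = rng.uniform(0.2, 0.8, l)
        f1 = synthio.simulate_cluster_freqs(base, 0.3, seed=10)[0]
        f2 = synthio.simulate_cluster_freqs(base, 0.3, seed=11)[0]
        d1 = rng.binomial(2, f1, size=(30, l))
        d2 = rng.binomial(2, f2, size=(30, l))
        tet = rng.binomial(4, f1, size=(30, l))
        dosage = np.vstack([d1, d2, tet])
        m = make_dosage_matrix(dosage, [2] * 60 + [4] * 30)
        coa = pairwise_coancestry(m)
        tet_idx = np.arange(60, 90)
        to_p1 = cross_group_values(coa, tet_idx, np.arange(30))
        to_p2 = cross_group_values(coa, tet_idx, np.arange(30, 60))
        assert np.median(to_p1) > np.median(to_p2)
        _, p = group_relatedness_test(to_p1, to_p2)
        assert p < 0.001


def test_linkage_orders_clustered_individuals_together():
    from scipy.cluster.hierarchy import leaves_list

    m = np.zeros((6, 6))
    m[:3, :3] = 0.8
    m[3:, 3:] = 0.8
    np.fill_diagonal(m, 1.0)
    coa = CoancestryMatrix(m, np.full((6, 6), 10), [f"s{i}" for i in range(6)])
    order = leaves_list(relatedness_linkage(coa))
    assert set(order[:3]) in ({0, 1, 2}, {3, 4, 5})
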