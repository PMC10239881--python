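"""Generator contracts: drift moments, segregation models, determinism."""

import numpy as np
import pytest

from ploidypop import synthio
from ploidypop.synthio import (
    SimConfig,
    simulate_cluster_freqs,
    simulate_dosages,
    simulate_fluorescence,
    simulate_reads,
    simulate_truth,
    simulate_vote_grids,
)


class TestClusterFreqs:
    def test_low_drift_limit_recovers_base_freqs(self):
        base = np.full(200, 0.3)
        freqs = simulate_cluster_freqs(base, 1e-6, seed=0)
        assert np.allclose(freqs, 0.3, atol=0.01)

    def test_beta_moments_at_moderate_drift(self):
        # mean of Balding-Nichols draws must sit within 3 SE of the base
        # frequency; SE = sqrt(F p (1-p) / L)
        base = np.full(2000, 0.4)
        freqs = simulate_cluster_freqs(base, 0.3, seed=1)[0]
        se = np.sqrt(0.3 * 0.4 * 0.6 / 2000)
        assert abs(freqs.mean() - 0.4) < 3 * se

    def test_determinism(self):
        base = np.random.default_rng(3).uniform(0.1, 0.9, 50)
        a = simulate_cluster_freqs(base, 0.2, seed=9)
        b = simulate_cluster_freqs(base, 0.2, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, np.nan])
    def test_rejects_out_of_range_drift(self, bad):
        with pytest.raises(ValueError):
            simulate_cluster_freqs(np.array([0.5]), bad, seed=0)

    def test_rejects_out_of_range_base_freqs(self):
        with pytest.raises(ValueError):
            simulate_cluster_freqs(np.array([0.0, 0.5]), 0.2, seed=0)


class TestDosages:
    def _one_cluster(self, ploidy, mode, freq, n=200, l=50, divergence=1.0):
        cfg = SimConfig(
            n_clusters=1,
            cluster_ploidy=(ploidy,),
            n_per_cluster=(n,),
            n_loci=l,
            inheritance_mode=(mode,),
            subgenome_divergence=divergence,
            seed=5,
        )
        truth = simulate_truth(cfg)
        truth.true_cluster_freqs[:] = freq
        return cfg, truth, simulate_dosages(cfg, truth)

    def test_zero_frequency_gives_zero_dosage(self):
        # freq exactly 0 is outside the drift model but valid for dosages
        _, _, dos = self._one_cluster(4, "tetrasomic", 0.0)
        assert np.all(dos.dosage == 0)

    def test_tetrasomic_half_freq_matches_binomial4(self):
        _, _, dos = self._one_cluster(4, "tetrasomic", 0.5, n=200, l=100)
        counts = np.bincount(dos.dosage.ravel(), minlength=5)
        total = counts.sum()
        expected = np.array([1, 4, 6, 4, 1]) / 16
        se = np.sqrt(expected * (1 - expected) / total)
        assert np.all(np.abs(counts / total - expected) < 3 * se)

    def test_disomic_extreme_is_all_duplex(self):
        # maximally divergent subgenomes (freqs 1 and 0) fix dosage 2
        _, _, dos = self._one_cluster(4, "disomic", 0.5, divergence=1.0)
        assert np.all(dos.dosage == 2)

    def test_diploid_cluster_rejects_inheritance_mode(self):
        with pytest.raises(ValueError):
            SimConfig(
                n_clusters=1,
                cluster_ploidy=(2,),
                n_per_cluster=(10,),
                inheritance_mode=("tetrasomic",),
            )

    def test_within_cluster_freq_recovery(self, four_pool_dataset):
        cfg, truth, dosages, _ = four_pool_dataset
        # pooled within-cluster frequencies approach the truth (3 SE)
        for j in range(cfg.n_clusters):
            members = np.where(truth.cluster_of == j)[0]
            v = cfg.cluster_ploidy[j]
            est = dosages.dosage[members].sum(axis=0) / (v * len(members))
            p = truth.true_cluster_freqs[j]
            se = np.sqrt(p * (1 - p) / (v * len(members))) + 1e-9
            frac_in = np.mean(np.abs(est - p) < 3 * se)
            assert frac_in > 0.98


class TestReads:
    def test_no_error_homozygous_ref_gives_zero_alt(self, two_pool_dataset):
        _, _, dosages, _ = two_pool_dataset
        reads = simulate_reads(dosages, 30, 0.0, seed=0)
        hom_ref = dosages.dosage == 0
        assert np.all(reads.alt[hom_ref] == 0)
        hom_alt = dosages.dosage == dosages.ploidy[:, None]
        assert np.all(reads.alt[hom_alt] == reads.total[hom_alt])

    def test_duplex_alt_fraction_near_half(self):
        cfg = SimConfig(
            n_clusters=1, cluster_ploidy=(4,), n_per_cluster=(1,),
            n_loci=10_000, inheritance_mode=("disomic",),
            subgenome_divergence=1.0, seed=2,
        )
        truth = simulate_truth(cfg)
        truth.true_cluster_freqs[:] = 0.5
        dos = simulate_dosages(cfg, truth)  # all duplex (dosage 2 of 4)
        reads = simulate_reads(dos, 50, 0.01, seed=3)
        frac = reads.alt.sum() / reads.total.sum()
        # success prob is exactly 0.5 by the symmetric error fold
        se = np.sqrt(0.25 / reads.total.sum())
        assert abs(frac - 0.5) < 3 * se

    def test_tetraploids_sequenced_at_twice_diploid_depth(self, four_pool_dataset):
        _, _, _, reads = four_pool_dataset
        mean2 = reads.total[reads.ploidy == 2].mean()
        mean4 = reads.total[reads.ploidy == 4].mean()
        assert mean4 / mean2 == pytest.approx(2.0, rel=0.05)

    def test_determinism_bit_identical(self, two_pool_dataset):
        _, _, dosages, _ = two_pool_dataset
        r1 = simulate_reads(dosages, 20, 0.01, seed=77)
        r2 = simulate_reads(dosages, 20, 0.01, seed=77)
        np.testing.assert_array_equal(r1.alt, r2.alt)
        np.testing.assert_array_equal(r1.total, r2.total)
        np.testing.assert_array_equal(r1.error, r2.error)


class TestFluorescence:
    def test_band_means_recovered(self):
        ploidy = np.full(50, 2)
        fluo = simulate_fluorescence(ploidy, {2: (6.73, 0.15)}, replicates=2, seed=0)
        means = fluo.groupby("sample_id")["rf"].mean()
        se = 0.15 / np.sqrt(2 * 50)
        assert abs(means.mean() - 6.73) < 3 * se

    def test_zero_sd_gives_constant_replicates(self):
        fluo = simulate_fluorescence(np.array([4]), {4: (12.2, 0.0)}, seed=1)
        assert fluo["rf"].nunique() == 1
        assert fluo["rf"].iloc[0] == pytest.approx(12.2)

    def test_ploidy_ratio_preserved(self):
        ploidy = np.array([2] * 100 + [4] * 100)
        fluo = simulate_fluorescence(ploidy, seed=4)
        ids2 = [f"ind{i:04d}" for i in range(100)]
        m2 = fluo[fluo.sample_id.isin(ids2)]["rf"].mean()
        m4 = fluo[~fluo.sample_id.isin(ids2)]["rf"].mean()
        assert m4 / m2 == pytest.approx(12.2 / 6.73, rel=0.02)

    def test_missing_band_raises(self):
        with pytest.raises(KeyError):
            simulate_fluorescence(np.array([4]), {2: (6.7, 0.1)}, seed=0)

    def test_minimum_two_replicates(self):
        with pytest.raises(ValueError):
            simulate_fluorescence(np.array([2]), replicates=1, seed=0)


class TestVoteGrids:
    def test_disjoint_pattern_has_zero_overlap(self):
        va, vb, _ = simulate_vote_grids((10, 20), 1.0, "disjoint", seed=0)
        assert not np.any((va > 0.6) & (vb > 0.6))

    def test_identical_pattern_fully_overlaps(self):
        va, vb, _ = simulate_vote_grids((10, 20), 1.0, "identical", seed=0)
        np.testing.assert_array_equal(va > 0.6, vb > 0.6)

    def test_designed_quarter_overlap_is_exact(self):
        va, vb, _ = simulate_vote_grids((10, 20), 1.0, "overlap", 0.25, seed=0)
        a, b = va > 0.6, vb > 0.6
        assert (a & b).sum() / (a | b).sum() == 0.25


def test_full_chain_determinism():
    cfg = SimConfig(n_per_cluster=(5, 5, 5, 5), n_loci=40, seed=123)
    t1, d1, r1 = synthio.simulate_dataset(cfg)
    t2, d2, r2 = synthio.simulate_dataset(cfg)
    np.testing.assert_array_equal(d1.dosage, d2.dosage)
    np.testing.assert_array_equal(r1.alt, r2.alt)
    np.testing.assert_array_equal(t1.true_cluster_freqs, t2.true_cluster_freqs)
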