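"""Generators: kinship models, Gaussian score matrices, discrete dosages,
and the Wishart shortcuts (full-matrix Bartlett and eigenvalue-only)."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from snpherit import (
    make_kinship, sample_scores, sample_dosages, standardize,
    sample_grm_wishart, sample_wishart_eigenvalues, build_grm,
)
from snpherit.synthetic import DosageGenotypeMatrix, DegenerateSNPError


class TestMakeKinship:
    def test_zero_width_uniform_is_identity(self):
        K = make_kinship(2, 0.0, 0.0, seed=5)
        assert np.array_equal(K.matrix, np.eye(2))
        assert K.kind == "identity"

    def test_rejects_single_individual(self):
        with pytest.raises(ValueError):
            make_kinship(1, 0.0, 0.05, seed=0)

    def test_offdiagonals_in_band_unit_diagonal(self):
        K = make_kinship(1000, 0.0, 0.05, seed=3)
        off = K.matrix[np.triu_indices(1000, 1)]
        assert off.min() >= 0.0 and off.max() <= 0.05
        assert np.allclose(np.diag(K.matrix), 1.0)
        assert np.allclose(K.matrix, K.matrix.T)
        # uniform(0, 0.05) noise keeps this size PSD without repair
        assert np.linalg.eigvalsh(K.matrix)[0] >= 0.0

    def test_constant_offdiagonal_closed_form_spectrum(self):
        # I(1-c) + cJ has smallest eigenvalue 1 - c
        K = make_kinship(50, 0.02, 0.02, seed=9)
        assert np.linalg.eigvalsh(K.matrix)[0] == pytest.approx(0.98, abs=1e-10)

    def test_indefinite_draw_is_repaired_and_recorded(self):
        # a wide band at small n forces negative eigenvalues
        K = make_kinship(40, 0.0, 0.9, seed=1)
        assert K.psd_adjusted > 0.0
        assert np.linalg.eigvalsh(K.matrix)[0] >= -1e-12
        assert np.allclose(np.diag(K.matrix), 1.0)


class TestSampleScores:
    def test_identity_rows_have_identity_covariance(self):
        M = 4000
        Z = sample_scores(4, M, make_kinship(4, 0, 0, seed=0), seed=1).values
        C = Z @ Z.T / M
        assert np.abs(C - np.eye(4)).max() < 4.0 / np.sqrt(M)

    def test_grm_expectation_matches_kinship(self):
        # constant off-diagonal c: mean off-diagonal of ZZ'/M converges to c
        c = 0.3
        K = make_kinship(30, c, c, seed=2)
        Z = sample_scores(30, 3000, K, seed=3).values
        G = Z @ Z.T / 3000
        off = G[np.triu_indices(30, 1)]
        assert off.mean() == pytest.approx(c, abs=0.01)

    def test_column_reproducible_from_seed_and_index(self):
        K = make_kinship(8, 0, 0.05, seed=4)
        Z5 = sample_scores(8, 5, K, seed=77).values
        Z9 = sample_scores(8, 9, K, seed=77).values
        np.testing.assert_array_equal(Z5, Z9[:, :5])

    def test_rejects_wrong_dimension(self):
        with pytest.raises(ValueError):
            sample_scores(10, 3, make_kinship(5, 0, 0, seed=0), seed=0)


class TestSampleDosages:
    def test_values_and_frequency_bounds(self):
        g = sample_dosages(200, 300, maf_low=0.05, maf_high=0.4, seed=6)
        assert set(np.unique(g.dosages)) <= {0, 1, 2}
        assert g.freqs.min() >= 0.05 and g.freqs.max() <= 0.4

    def test_mean_dosage_tracks_frequency(self):
        g = sample_dosages(4000, 50, maf_low=0.5, maf_high=0.5, seed=7)
        assert g.dosages.mean(axis=0) == pytest.approx(1.0, abs=0.1)

    def test_independent_snps_uncorrelated(self):
        g = sample_dosages(2000, 40, seed=8)
        d = g.dosages.astype(float)
        r = np.array([np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(39)])
        assert np.abs(r).max() < 3.0 / np.sqrt(2000) * 2.5

    def test_block_ld_exceeds_cross_block_ld(self):
        g = sample_dosages(800, 100, block_len=50, rho=0.9, seed=9)
        d = g.dosages.astype(float)
        r2 = np.corrcoef(d, rowvar=False) ** 2
        within = np.mean([r2[j, j + 1] for j in range(49)])
        cross = np.mean(r2[:50, 50:])
        assert within > 10 * cross

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            sample_dosages(10, 5, maf_low=0.0)
        with pytest.raises(ValueError):
            sample_dosages(10, 5, rho=1.0)


class TestStandardize:
    def test_hand_computed_scores(self):
        g = DosageGenotypeMatrix(np.array([[1], [2], [0]], dtype=np.int8),
                                 freqs=np.array([0.25]))
        Z = standardize(g, freq_mode="supplied").values
        # (d - 2f)/sqrt(2 f (1-f)) at f = 0.25
        s = np.sqrt(2 * 0.25 * 0.75)
        assert Z[0, 0] == pytest.approx(0.5 / s)
        assert Z[1, 0] == pytest.approx(1.5 / s, abs=1e-12)
        assert Z[1, 0] == pytest.approx(2.449489742, abs=1e-6)
        assert Z[2, 0] == pytest.approx(-0.5 / s)

    def test_heterozygote_at_half_frequency_scores_zero(self):
        g = DosageGenotypeMatrix(np.array([[1], [1]], dtype=np.int8),
                                 freqs=np.array([0.5]))
        assert np.all(standardize(g, "supplied").values == 0.0)

    def test_sample_mode_centres_columns(self):
        g = sample_dosages(500, 30, seed=10)
        Z = standardize(g, freq_mode="sample").values
        assert np.abs(Z.mean(axis=0)).max() < 1e-12

    def test_missing_imputed_to_zero_score(self):
        d = np.array([[2, 1], [-1, 0], [0, 1]], dtype=np.int8)
        g = DosageGenotypeMatrix(d, freqs=np.array([0.5, 0.3]))
        Z = standardize(g, freq_mode="supplied").values
        assert Z[1, 0] == 0.0

    def test_degenerate_frequency_names_snp(self):
        g = DosageGenotypeMatrix(np.array([[2], [2]], dtype=np.int8),
                                 snp_ids=["rs_fixed"], freqs=np.array([1.0]))
        with pytest.raises(DegenerateSNPError, match="rs_fixed"):
            standardize(g, freq_mode="supplied")


class TestWishartSampling:
    def test_eigenvalue_law_matches_direct_sampling(self, rng):
        n, M, reps = 5, 20, 800
        direct = np.empty((reps, n))
        fast = np.empty((reps, n))
        for i in range(reps):
            Z = rng.standard_normal((n, M))
            direct[i] = np.linalg.eigvalsh(Z @ Z.T)
            fast[i] = sample_wishart_eigenvalues(n, M, rng)
        # compare largest eigenvalue and trace distributions
        assert ks_2samp(direct[:, -1], fast[:, -1]).pvalue > 0.01
        assert ks_2samp(direct.sum(1), fast.sum(1)).pvalue > 0.01

    def test_singular_case_pads_zeros(self, rng):
        w = sample_wishart_eigenvalues(8, 3, rng)
        assert len(w) == 8
        assert np.all(w[:5] == 0.0) and np.all(w[5:] > 0.0)

    def test_grm_draw_matches_direct_product(self):
        # off-diagonal law of G = ZZ'/M vs the Bartlett draw
        n, M, reps = 5, 200, 800
        K = make_kinship(n, 0.0, 0.0, seed=0)
        rng = np.random.default_rng(42)
        off_direct, off_fast, trgg_d, trgg_f = [], [], [], []
        for i in range(reps):
            Z = rng.standard_normal((n, M))
            G = Z @ Z.T / M
            off_direct.append(G[0, 1])
            trgg_d.append(np.sum(G * G))
            Gf = sample_grm_wishart(n, M, K, seed=10_000 + i).matrix
            off_fast.append(Gf[0, 1])
            trgg_f.append(np.sum(Gf * Gf))
        assert ks_2samp(off_direct, off_fast).pvalue > 0.01
        se = np.std(trgg_d) * np.sqrt(2.0 / reps)
        assert abs(np.mean(trgg_d) - np.mean(trgg_f)) < 4 * se

    def test_grm_diagonal_expectation_is_one(self):
        K = make_kinship(40, 0.0, 0.05, seed=1)
        diags = [np.diag(sample_grm_wishart(40, 100, K, seed=s).matrix).mean()
                 for s in range(200)]
        assert np.mean(diags) == pytest.approx(1.0, abs=0.02)

    def test_wishart_requires_enough_dof(self):
        K = make_kinship(10, 0, 0, seed=0)
        with pytest.raises(ValueError):
            sample_grm_wishart(10, 5, K, seed=0)


class TestReproducibility:
    def test_generators_bitwise_reproducible(self):
        K1 = make_kinship(20, 0, 0.05, seed=3)
        K2 = make_kinship(20, 0, 0.05, seed=3)
        np.testing.assert_array_equal(K1.matrix, K2.matrix)
        Z1 = sample_scores(20, 7, K1, seed=4).values
        Z2 = sample_scores(20, 7, K2, seed=4).values
        np.testing.assert_array_equal(Z1, Z2)
        g1 = sample_dosages(15, 9, block_len=3, rho=0.5, seed=5)
        g2 = sample_dosages(15, 9, block_len=3, rho=0.5, seed=5)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
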