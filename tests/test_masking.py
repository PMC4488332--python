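"""Causal-SNP masking, ridge imputation and the removal trajectory."""

import numpy as np
import pytest

from snpherit import (
    sample_dosages, ld_prune, split_halves, select_causal, impute_masked,
    imputation_r2, removal_trajectory,
)
from snpherit.synthetic import DosageGenotypeMatrix


class TestSplitHalves:
    def test_even_split_disjoint(self):
        ids = [f"S{i}" for i in range(10)]
        ref, main = split_halves(ids, seed=1)
        assert len(ref) == len(main) == 5
        assert not set(ref) & set(main)
        assert sorted(ref + main) == sorted(ids)

    def test_odd_split_reference_gets_extra(self):
        ref, main = split_halves([f"S{i}" for i in range(11)], seed=2)
        assert (len(ref), len(main)) == (6, 5)

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(20)]
        assert split_halves(ids, seed=3) == split_halves(ids, seed=3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_halves(["a", "b", "c"], seed=0)


class TestSelectCausal:
    def test_whole_set_when_requested(self):
        ids = [f"snp{i}" for i in range(8)]
        assert sorted(select_causal(ids, 8, seed=1)) == sorted(ids)

    def test_subset_without_replacement(self):
        ids = [f"snp{i}" for i in range(100)]
        causal = select_causal(ids, 30, seed=2)
        assert len(causal) == len(set(causal)) == 30
        assert set(causal) <= set(ids)

    def test_overlap_between_seeds_near_hypergeometric(self):
        ids = [f"snp{i}" for i in range(200)]
        a = set(select_causal(ids, 50, seed=3))
        b = set(select_causal(ids, 50, seed=4))
        # E overlap = 50*50/200 = 12.5, SD ~ 3
        assert 3 <= len(a & b) <= 25

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            select_causal(["a"], 2, seed=0)


class TestImputation:
    def test_perfect_tag_recovers_masked_snp(self, rng):
        # the masked SNP is duplicated among the observed flankers
        n = 1000
        col = rng.binomial(2, 0.35, size=n).astype(np.int8)
        noise = rng.binomial(2, 0.3, size=(n, 6)).astype(np.int8)
        dos = np.column_stack([noise[:, :3], col, noise[:, 3:], col])
        ids = [f"snp{j+1}" for j in range(8)]
        g = DosageGenotypeMatrix(dos, snp_ids=ids)
        ref = g.subset_samples(list(range(0, n, 2)))
        main = g.subset_samples(list(range(1, n, 2)))
        masked = ["snp8"]  # duplicate of snp4
        imput = impute_masked(ref, main.subset_snps(ids[:7]), masked,
                              flank=6, ridge=0.1)
        truth = main.subset_snps(masked).dosages.astype(float)
        res = imputation_r2(imput, truth, masked)
        assert res.per_snp_r2["snp8"] > 0.99

    def test_no_ld_gives_near_zero_r2(self):
        g = sample_dosages(600, 40, seed=5)
        ref = g.subset_samples(list(range(300)))
        main = g.subset_samples(list(range(300, 600)))
        masked = ["snp20"]
        imput = impute_masked(ref, main.subset_snps(
            [s for s in g.snp_ids if s != "snp20"]), masked, flank=10)
        truth = main.subset_snps(masked).dosages.astype(float)
        assert imputation_r2(imput, truth, masked).mean_r2 < 0.1

    def test_output_clipped_to_dosage_range(self):
        g = sample_dosages(200, 30, block_len=10, rho=0.8, seed=6)
        ref = g.subset_samples(list(range(100)))
        main = g.subset_samples(list(range(100, 200)))
        obs = [s for s in g.snp_ids if s != "snp15"]
        imput = impute_masked(ref, main.subset_snps(obs), ["snp15"], flank=8)
        assert imput.min() >= 0.0 and imput.max() <= 2.0

    def test_masked_snp_present_in_main_rejected(self):
        g = sample_dosages(100, 10, seed=7)
        ref = g.subset_samples(list(range(50)))
        main = g.subset_samples(list(range(50, 100)))
        with pytest.raises(ValueError):
            impute_masked(ref, main, ["snp3"], flank=2)


class TestImputationR2:
    def test_identical_vectors_score_one(self, rng):
        x = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        res = imputation_r2(x, x)
        assert all(v == pytest.approx(1.0) for v in res.per_snp_r2.values())
        assert res.mean_r2 == pytest.approx(1.0)

    def test_anticorrelation_scores_one(self, rng):
        x = rng.binomial(2, 0.4, size=(50, 1)).astype(float)
        assert imputation_r2(2.0 - x, x).mean_r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        imputed = np.array([0.0, 1.0, 1.0, 2.0])
        truth = np.array([0.0, 1.0, 2.0, 2.0])
        r = np.corrcoef(imputed, truth)[0, 1] ** 2
        res = imputation_r2(imputed, truth)
        assert res.mean_r2 == pytest.approx(r)
        assert res.mean_r2 == pytest.approx(8.0 / 11.0, abs=1e-12)

    def test_constant_vector_scores_zero(self):
        res = imputation_r2(np.ones(10), np.arange(10.0))
        assert res.mean_r2 == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            imputation_r2(np.ones((3, 2)), np.ones((3, 3)))


@pytest.fixture(scope="module")
def cohort():
    g = sample_dosages(500, 1200, block_len=25, rho=0.9, seed=8)
    pruned = ld_prune(g, window=50, r2_max=0.25)
    causal = select_causal(pruned, 60, seed=9)
    return g, causal


class TestRemovalTrajectory:

    def test_degenerate_single_fraction_run(self, cohort):
        g, causal = cohort
        rows = removal_trajectory(g, causal, h2=0.5, fractions=[1.0], seed=10)
        assert len(rows) == 1
        r = rows[0]
        assert r.fraction_observed == 1.0
        assert 0.0 <= r.mean_r2 <= 1.0
        assert 0.0 <= r.h2_with_causal <= 1.0

    def test_fractions_sorted_and_observed_counts_nested(self, cohort):
        g, causal = cohort
        rows = removal_trajectory(g, causal, h2=0.5,
                                  fractions=[0.25, 1.0, 0.5], seed=11)
        fracs = [r.fraction_observed for r in rows]
        assert fracs == [1.0, 0.5, 0.25]
        n_obs = [r.n_observed for r in rows]
        assert n_obs[0] > n_obs[1] > n_obs[2]
        assert n_obs[1] == pytest.approx(n_obs[0] / 2, abs=1)

    def test_deterministic_given_seed(self, cohort):
        g, causal = cohort
        a = removal_trajectory(g, causal, fractions=[1.0, 0.5], seed=12)
        b = removal_trajectory(g, causal, fractions=[1.0, 0.5], seed=12)
        assert a == b

    def test_imputation_r2_declines_with_thinning_on_average(self):
        # nested thinning cuts the tagging basis, so mean r2 must fall
        means = np.zeros(4)
        n_seeds = 6
        for s in range(n_seeds):
            g = sample_dosages(260, 900, block_len=30, rho=0.92, seed=100 + s)
            pruned = ld_prune(g, window=50, r2_max=0.25)
            causal = select_causal(pruned, 40, seed=200 + s)
            rows = removal_trajectory(g, causal, h2=0.5, seed=300 + s)
            means += np.array([r.mean_r2 for r in rows]) / n_seeds
        assert (np.diff(means) < 0).all()
        assert means[0] > 0.15
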