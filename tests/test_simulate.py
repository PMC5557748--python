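import json

import numpy as np
import pytest
from scipy import stats

from symh2 import abundance as ab
from symh2 import diversity as dv
from symh2.pedigree import PedigreeError, additive_relationship_matrix
from symh2.simulate import (
    StudyConfig,
    simulate_community_counts,
    simulate_pedigree_design,
    simulate_sequences,
    simulate_study,
    simulate_trait,
)


class TestPedigreeDesigns:
    def test_half_diallel_feasibility_bound(self):
        with pytest.raises(PedigreeError, match="infeasible"):
            simulate_pedigree_design("half_diallel", 4, 7, 1, seed=0)
        ped = simulate_pedigree_design("half_diallel", 4, 6, 1, seed=0)
        assert len(ped) == 10

    def test_maternal_design_99_eggs(self):
        ped = simulate_pedigree_design("maternal_only", 9, 9, 11, seed=0)
        eggs = [r for r in ped.records if r.dam_id is not None]
        assert len(eggs) == 99
        assert len(ped) == 108

    def test_same_seed_identical_pedigree(self):
        a = simulate_pedigree_design("half_diallel", 8, 20, (1, 29), seed=7)
        b = simulate_pedigree_design("half_diallel", 8, 20, (1, 29), seed=7)
        assert a.records == b.records

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree_design("clonal", 4, 4, 1, seed=0)


class TestTraitModel:
    def test_no_additive_variance_leaves_residual_only(self):
        ped = simulate_pedigree_design("half_diallel", 6, 10, 100, seed=1)
        traits, _ = simulate_trait(ped, 0.0, 1.0, 0.0, seed=2)
        offspring = [traits[i] for i in ped.ids if i not in ped.founders]
        var = np.var(offspring, ddof=1)
        n = len(offspring)
        lo = stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert lo < var < hi

    def test_full_sib_covariance_is_half_additive(self):
        # closed form: cov(full sibs) = 0.5 sigma2_A
        sigma2_a = 2.0
        covs = []
        for rep in range(300):
            ped = simulate_pedigree_design("half_diallel", 4, 1, 2, seed=rep)
            traits, _ = simulate_trait(ped, sigma2_a, 1.0, 0.0, seed=rep)
            sibs = [traits[i] for i in ped.ids if i.startswith("F")]
            covs.append(sibs[0] * sibs[1])  # both have mean 0
        assert np.mean(covs) == pytest.approx(0.5 * sigma2_a, abs=0.35)

    def test_founder_breeding_value_variance(self):
        ped = simulate_pedigree_design("maternal_only", 400, 400, 1, seed=3)
        _, truth = simulate_trait(ped, 1.5, 0.5, 0.0, seed=4)
        founder_bv = [truth.breeding_values[d] for d in ped.founders]
        assert np.var(founder_bv, ddof=1) == pytest.approx(1.5, rel=0.2)

    def test_truth_h2_consistency(self):
        ped = simulate_pedigree_design("maternal_only", 3, 3, 2, seed=0)
        _, truth = simulate_trait(ped, 0.6, 0.4, 0.0, seed=0)
        assert truth.h2 == pytest.approx(0.6 / (0.6 + 0.4), abs=1e-12)

    def test_maternal_effect_inflates_between_dam_variance(self):
        def between_dam_var(m2):
            ped = simulate_pedigree_design("maternal_only", 40, 40, 50, seed=5)
            traits, _ = simulate_trait(ped, 0.1, 0.1, m2, seed=6)
            values = np.array([traits[i] for i in ped.ids if "_egg" in i])
            dams = [i.split("_")[0] for i in ped.ids if "_egg" in i]
            means = [values[[x == d for x in dams]].mean() for d in set(dams)]
            return np.var(means, ddof=1)

        assert between_dam_var(0.5) > 2.0 * between_dam_var(0.0)


class TestSequences:
    def test_zero_within_divergence_gives_identical_clades(self):
        seqs = simulate_sequences(9, 120, 3, 0.0, 0.3, seed=1)
        d = dv.raw_distances(seqs)
        for i in range(3):
            block = [j for j in range(9) if j % 3 == i]
            assert np.allclose(d.values[np.ix_(block, block)], 0.0)

    def test_between_clade_distance_near_target(self):
        seqs = simulate_sequences(12, 300, 3, 0.01, 0.25, seed=2)
        d = dv.raw_distances(seqs)
        between = []
        for i in range(12):
            for j in range(i + 1, 12):
                if i % 3 != j % 3:
                    between.append(d.values[i, j])
        assert np.mean(between) == pytest.approx(0.25, abs=0.05)

    def test_same_seed_identical_sequences(self):
        a = simulate_sequences(10, 100, 2, 0.02, 0.2, seed=9)
        b = simulate_sequences(10, 100, 2, 0.02, 0.2, seed=9)
        assert a.sequences == b.sequences

    def test_invalid_divergences_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequences(10, 100, 2, 0.3, 0.2, seed=0)


class TestCommunityCounts:
    def test_low_noise_counts_converge_to_expected_shares(self):
        latent = {f"i{k}": float(k) for k in range(3)}
        seqs = simulate_sequences(6, 60, 2, 0.0, 0.3, seed=0)
        table = simulate_community_counts(
            latent, seqs, n_principal=6, n_background=0,
            library_size_mean=2_000_000, nb_dispersion=0.0, seed=1,
        )
        shares = table.counts / table.counts.sum(axis=0, keepdims=True)
        # geometric shares with logistic evenness of the standardized trait
        z = (np.array([0.0, 1.0, 2.0]) - 1.0) / np.std([0, 1, 2])
        for j, zj in enumerate(z):
            r = 1.0 / (1.0 + np.exp(-zj))
            w = r ** np.arange(6)
            w = w / w.sum()
            assert np.abs(shares[:, j] - w).sum() < 0.01

    def test_latent_trait_drives_diversity(self, rng):
        # generator fidelity contract: rank correlation >= 0.8 at defaults
        latent = {f"i{k}": float(v) for k, v in enumerate(rng.normal(size=200))}
        seqs = simulate_sequences(68, 300, 3, 0.01, 0.25, seed=3)
        table = simulate_community_counts(
            latent, seqs, n_principal=8, n_background=60,
            library_size_mean=20_000, nb_dispersion=0.2, seed=4,
        )
        norm = ab.normalize(table, ab.size_factors(table))
        Z = dv.similarity_from_distances(dv.raw_distances(seqs)).subset(table.otu_ids)
        traits = dv.diversity_phenotypes(norm, Z, q=1.0)
        D = [t.D for t in traits]
        rho = stats.spearmanr(list(latent.values()), D)[0]
        assert rho >= 0.8

    def test_background_otus_are_sparse_and_faint(self):
        latent = {f"i{k}": 0.1 * k for k in range(100)}
        seqs = simulate_sequences(68, 300, 3, 0.01, 0.25, seed=5)
        table = simulate_community_counts(
            latent, seqs, 8, 60, 20_000, 0.2, seed=6
        )
        presence = (table.counts > 0).mean(axis=1)
        shares = table.counts.sum(axis=1) / table.counts.sum()
        assert np.all(presence[8:] < 0.5)
        assert np.all(shares[8:] < 1e-4)

    def test_same_seed_identical_counts(self):
        latent = {f"i{k}": float(k) for k in range(10)}
        seqs = simulate_sequences(10, 100, 2, 0.01, 0.2, seed=7)
        a = simulate_community_counts(latent, seqs, 5, 5, 20_000, 0.2, seed=8)
        b = simulate_community_counts(latent, seqs, 5, 5, 20_000, 0.2, seed=8)
        assert np.array_equal(a.counts, b.counts)


class TestStudyBundle:
    def test_default_study_runs_end_to_end(self, tmp_path, maternal_bundle):
        config = StudyConfig(seed=11)
        bundle = simulate_study(config, tmp_path / "study")
        for name in ("counts.tsv", "otus.fasta", "pedigree.csv", "metadata.csv", "truth.json"):
            assert (tmp_path / "study" / name).exists()
        truth = json.loads((tmp_path / "study" / "truth.json").read_text())
        assert truth["h2"] == pytest.approx(
            config.sigma2_a / (config.sigma2_a + config.sigma2_e)
        )
        # the generated inputs satisfy every reader/validator
        from symh2.io import read_aligned_fasta, read_count_table, read_metadata
        from symh2.pedigree import read_pedigree

        table = read_count_table(tmp_path / "study" / "counts.tsv")
        seqs = read_aligned_fasta(tmp_path / "study" / "otus.fasta")
        ped = read_pedigree(tmp_path / "study" / "pedigree.csv")
        meta = read_metadata(tmp_path / "study" / "metadata.csv")
        assert seqs.matches(table)
        meta.validate_against(table, set(ped.ids))
        additive_relationship_matrix(ped)

    def test_two_seeds_differ_but_share_schema(self):
        a = simulate_study(StudyConfig(seed=1))
        b = simulate_study(StudyConfig(seed=2))
        assert a.table.otu_ids == b.table.otu_ids
        assert not np.array_equal(a.table.counts, b.table.counts)
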