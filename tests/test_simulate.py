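"""The generator must actually plant what it claims to plant."""

import numpy as np
import pandas as pd
import pytest

from resilience_pqtl.simulate import (
    BLOCK_END, BLOCK_START, SimConfig, block_marker_ids, equicorrelated_module,
    generate_cohort, generate_genotypes, generate_peptide_batches,
    gene_positions)


class TestGenotypes:
    def test_block_columns_identical_and_confined(self):
        cfg = SimConfig(n_strains=30, n_chromosomes=2, n_markers_per_chrom=40)
        g = generate_genotypes(cfg, np.random.default_rng(1))
        block = block_marker_ids(g, cfg)
        assert len(block) == cfg.block_markers == 10
        cols = g.codes.loc[block].to_numpy()
        assert (cols == cols[0]).all(), "block markers must share one pattern"
        # no flanking marker on the block chromosome in perfect LD
        pattern = cols[0]
        for m in g.chrom_markers(cfg.block_chrom):
            if m in block:
                continue
            v = g.codes.loc[m].to_numpy()
            assert not ((v == pattern).all() or (v == 1 - pattern).all())

    def test_every_marker_polymorphic(self):
        cfg = SimConfig(n_strains=8, n_chromosomes=4, n_markers_per_chrom=30,
                        recomb_prob=0.02)
        g = generate_genotypes(cfg, np.random.default_rng(2))
        mins = g.codes.min(axis=1)
        maxs = g.codes.max(axis=1)
        assert (mins == 0).all() and (maxs == 1).all()

    def test_no_recombination_freezes_each_chromosome(self):
        cfg = SimConfig(n_strains=20, n_chromosomes=2, n_markers_per_chrom=25,
                        recomb_prob=0.0)
        g = generate_genotypes(cfg, np.random.default_rng(3))
        for chrom in ("1", "2"):
            cols = g.codes.loc[g.chrom_markers(chrom)].to_numpy()
            assert (cols == cols[0]).all()

    def test_switch_frequency_matches_recomb_prob(self):
        # Monte-Carlo check of the Markov rule at p = 0.5 over 10^4 markers
        cfg = SimConfig(n_strains=10, n_chromosomes=2,
                        n_markers_per_chrom=10_000, recomb_prob=0.5)
        g = generate_genotypes(cfg, np.random.default_rng(4))
        codes = g.codes.loc[g.chrom_markers("2")].to_numpy()
        switches = (codes[1:] != codes[:-1]).mean()
        assert abs(switches - 0.5) < 0.02

    def test_positions_strictly_increasing(self):
        cfg = SimConfig(n_strains=10, n_chromosomes=3, n_markers_per_chrom=50)
        g = generate_genotypes(cfg, np.random.default_rng(5))
        for chrom in ("1", "2", "3"):
            bp = g.positions.loc[g.positions["chrom"] == chrom, "bp"].to_numpy()
            assert (np.diff(bp) > 0).all()

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError, match="4 strains"):
            generate_genotypes(SimConfig(n_strains=3), np.random.default_rng(0))


class TestCohort:
    def test_planted_trait_proteins_structure(self, small_cohort):
        _, _, _, _, truth, _ = small_cohort
        tp = truth.trait_proteins
        assert len(tp) == 9
        assert (tp["sign"] == 1).sum() == 7
        assert (tp["sign"] == -1).sum() == 2
        assert (tp["cis_trans"] == "trans").sum() == 1
        assert len(truth.module_proteins) == 8
        assert not tp.loc[tp["cis_trans"] == "trans", "in_module"].any()

    def test_path_decomposition_exact(self, small_cohort):
        _, _, _, _, truth, _ = small_cohort
        p = truth.paths
        assert p["total"] == pytest.approx(p["indirect"] + p["direct"], abs=1e-12)

    def test_zero_module_effect_means_zero_indirect(self):
        cfg = SimConfig(n_strains=10, n_chromosomes=1, n_markers_per_chrom=12,
                        snp_module_effect=0.0, n_null_proteins=4, n_cis_null=0,
                        tf_count=2)
        rng = np.random.default_rng(6)
        g = generate_genotypes(cfg, rng)
        _, _, truth = generate_cohort(cfg, g, rng)
        assert truth.paths["indirect"] == 0.0

    def test_anova_fraction_converges_to_h2_dial(self):
        # variance-component arithmetic on the generator's own draws:
        # at 10^4 strains the between-strain SS fraction of the per-animal
        # trait must sit on the dial to within 0.01
        cfg = SimConfig(n_strains=10_000, replicates_range=(7, 7),
                        ntg_replicates_range=(1, 1), h2_strain=0.26,
                        n_chromosomes=1, n_markers_per_chrom=10,
                        n_null_proteins=0, n_cis_null=0, tf_count=2)
        rng = np.random.default_rng(7)
        g = generate_genotypes(cfg, rng)
        pheno, _, truth = generate_cohort(cfg, g, rng)
        ad = pheno[pheno["group"] == "AD"].copy()
        base = truth.baseline
        ntg_true = pd.Series(base["ntg_strain_means"])
        expected = base["intercept"] + base["slope"] * ntg_true.loc[ad["strain"]]
        trait = ad["cfm"].to_numpy() - expected.to_numpy()
        grand = trait.mean()
        ad["trait"] = trait
        per = ad.groupby("strain")["trait"]
        ss_strain = (per.size() * (per.mean() - grand) ** 2).sum()
        ss_total = ((trait - grand) ** 2).sum()
        assert ss_strain / ss_total == pytest.approx(0.26, abs=0.01)

    def test_infeasible_heritability_raises(self):
        cfg = SimConfig(n_strains=8, n_chromosomes=1, n_markers_per_chrom=12,
                        h2_strain=0.1, replicates_range=(2, 2))
        rng = np.random.default_rng(8)
        g = generate_genotypes(cfg, rng)
        with pytest.raises(ValueError, match="unreachable"):
            generate_cohort(cfg, g, rng)

    def test_infeasible_paths_raise(self):
        cfg = SimConfig(n_strains=8, n_chromosomes=1, n_markers_per_chrom=12,
                        snp_direct_effect=0.9, module_trait_effect=0.9)
        rng = np.random.default_rng(9)
        g = generate_genotypes(cfg, rng)
        with pytest.raises(ValueError, match="infeasible path"):
            generate_cohort(cfg, g, rng)

    def test_infeasible_baseline_r2_raises(self):
        cfg = SimConfig(n_strains=8, n_chromosomes=1, n_markers_per_chrom=12,
                        ntg_within_sd=200.0, replicates_range=(2, 2),
                        h2_strain=0.6)
        rng = np.random.default_rng(10)
        g = generate_genotypes(cfg, rng)
        with pytest.raises(ValueError, match="baseline_r2"):
            generate_cohort(cfg, g, rng)

    def test_planted_tf_correlation_recovered(self):
        # the Nr1d1-like track must correlate with the true strain trait at
        # the dialled strength (up to replicate-averaged measurement noise)
        cfg = SimConfig(n_strains=1000, replicates_range=(4, 4),
                        n_chromosomes=1, n_markers_per_chrom=12,
                        n_null_proteins=0, n_cis_null=0, tf_count=2)
        rng = np.random.default_rng(11)
        g = generate_genotypes(cfg, rng)
        _, proteins, truth = generate_cohort(cfg, g, rng)
        from resilience_pqtl.containers import strain_mean_matrix
        vals = strain_mean_matrix(proteins)
        r = np.corrcoef(vals.loc["Nr1d1", truth.strain_resilience.index],
                        truth.strain_resilience)[0, 1]
        assert r == pytest.approx(0.55, abs=0.05)

    def test_phenotypes_within_range(self, small_cohort):
        _, _, pheno, _, _, _ = small_cohort
        assert pheno["cfm"].between(0, 100).all()
        assert pheno["cfa"].between(0, 100).all()

    def test_gene_positions_respect_planted_classes(self, small_cohort):
        cfg, g, _, _, truth, genes = small_cohort
        for prot in truth.module_proteins:
            assert genes.loc[prot, "chrom"] == truth.block_chrom
            assert genes.loc[prot, "start"] >= BLOCK_START
            assert genes.loc[prot, "end"] <= BLOCK_END + 5_000_000
        trans = truth.trait_proteins.loc[
            truth.trait_proteins["cis_trans"] == "trans", "protein"].iloc[0]
        assert genes.loc[trans, "chrom"] != truth.block_chrom


class TestPeptideBatches:
    def _protein_matrix(self, n_samples=28, n_prot=5, seed=0, bio_sd=1.0):
        from resilience_pqtl.containers import AbundanceMatrix
        rng = np.random.default_rng(seed)
        strains = [f"BXD{i % 7:03d}" for i in range(n_samples)]
        values = pd.DataFrame(
            20 + bio_sd * rng.standard_normal((n_prot, n_samples)),
            index=[f"P{i}" for i in range(n_prot)],
            columns=[f"A{i}" for i in range(n_samples)])
        samples = pd.DataFrame({"strain": strains, "group": "AD"},
                               index=values.columns)
        return AbundanceMatrix(values=values, samples=samples, log2=True)

    def test_batch_layout_14_plus_2(self):
        cfg = SimConfig(batch_size=14, batch_references=2, batch_shift=0.0)
        pep = generate_peptide_batches(self._protein_matrix(28), cfg,
                                       np.random.default_rng(1))
        exp = pep.samples[pep.samples["group"] == "AD"]
        ref = pep.samples[pep.samples["group"] == "Reference"]
        assert exp.groupby("batch").size().max() <= 14
        assert (ref.groupby("batch").size() == 2).all()
        assert not pep.log2 and (pep.values.to_numpy() > 0).all()

    def test_planted_batch_coefficient_recovered(self):
        cfg = SimConfig(batch_count=2, batch_shift=2.0, peptide_noise_sd=0.05)
        pep = generate_peptide_batches(self._protein_matrix(30, bio_sd=0.05),
                                       cfg, np.random.default_rng(2))
        log = np.log2(pep.values)
        batch = pep.samples["batch"]
        diffs = log.T.groupby(batch).mean().T
        coef = (diffs[1] - diffs[0]).mean()
        assert coef == pytest.approx(2.0, abs=0.1)

    def test_zero_shift_leaves_batches_level(self):
        cfg = SimConfig(batch_count=2, batch_shift=0.0, peptide_noise_sd=0.05)
        pep = generate_peptide_batches(self._protein_matrix(30, bio_sd=0.05),
                                       cfg, np.random.default_rng(3))
        log = np.log2(pep.values)
        diffs = log.T.groupby(pep.samples["batch"]).mean().T
        assert (diffs[1] - diffs[0]).abs().max() < 0.2


def test_equicorrelated_module_hits_population_pc1():
    # eigenvalue of the equicorrelation matrix: (1 + 7 rho) / 8
    from resilience_pqtl.mediation import module_pca
    mod = equicorrelated_module(4000, 8, 0.463, np.random.default_rng(12))
    frac = module_pca(mod).variance_fractions[0]
    assert frac == pytest.approx((1 + 7 * 0.463) / 8, abs=0.015)
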