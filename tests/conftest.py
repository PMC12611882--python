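import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from resilience_pqtl.containers import strain_mean_matrix
from resilience_pqtl.simulate import SimConfig, generate_cohort, \
    generate_genotypes, gene_positions

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Conditions for qualitative parameter-recovery checks: large planted
# effects (strong genetic drive of the module, tight module, replicate-rich
# panel) so that every planted signal clears the FDR threshold with margin.
RECOVERY = dict(
    replicates_range=(17, 17),
    h2_strain=0.5,
    module_rho=0.7,
    snp_module_effect=0.95,
    module_trait_effect=0.85,
    measurement_sd=0.2,
    n_cis_null=6,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A light panel for plumbing tests."""
    return SimConfig(n_strains=30, n_chromosomes=3, n_markers_per_chrom=20,
                     n_null_proteins=20, n_cis_null=4, tf_count=4)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    rng = np.random.default_rng(2024)
    g = generate_genotypes(small_cfg, rng)
    pheno, proteins, truth = generate_cohort(small_cfg, g, rng)
    genes = gene_positions(small_cfg, g, truth, rng)
    return small_cfg, g, pheno, proteins, truth, genes


@pytest.fixture(scope="session")
def recovery_cohort():
    cfg = SimConfig(**RECOVERY)
    rng = np.random.default_rng(314)
    g = generate_genotypes(cfg, rng)
    pheno, proteins, truth = generate_cohort(cfg, g, rng)
    genes = gene_positions(cfg, g, truth, rng)
    return cfg, g, pheno, proteins, truth, genes


@pytest.fixture(scope="session")
def strain_values(small_cohort):
    _, _, _, proteins, _, _ = small_cohort
    return strain_mean_matrix(proteins)
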