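import numpy as np
import pytest

from methkin import qc, simdata


@pytest.fixture(scope="session")
def small_config():
    # compact study: one 40-kb chromosome keeps every end-to-end test fast
    return simdata.SimulationConfig(
        seed=11,
        n_chroms=1,
        chrom_length=40_000,
        n_cgis_per_chrom=4,
        n_genes=10,
        n_tissue_dmc=30,
        n_age_dmc=10,
        n_breed_dmc=10,
        n_heritable_windows=1,
        n_coupled_genes=4,
    )


@pytest.fixture(scope="session")
def samples():
    return simdata.simulate_pedigree(simdata.SimulationConfig())


@pytest.fixture(scope="session")
def small_study(small_config):
    genome, cgis, genes = simdata.simulate_genome(small_config)
    samples = simdata.simulate_pedigree(small_config)
    matrix, truth = simdata.simulate_methylomes(
        genome, cgis, samples, small_config, genes=genes
    )
    expr, coupling = simdata.simulate_expression(genes, truth.promoter_truth, small_config)
    truth.coupled_genes = coupling
    return {
        "config": small_config,
        "genome": genome,
        "cgis": cgis,
        "genes": genes,
        "samples": samples,
        "matrix": matrix,
        "truth": truth,
        "expression": expr,
        "filtered": qc.apply_site_filter(matrix),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
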