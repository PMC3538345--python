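import dataclasses

import pytest

from cyclenet import diffexpr, simulate
from cyclenet.config import AnalysisConfig


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def small_params(**overrides):
    """Reduced compendium for fast unit tests (structure preserved)."""
    base = dict(
        n_genes=600,
        n_batches=3,
        experiments_per_batch=10,
        n_module_genes=20,
        n_program_genes=100,
        n_proteasome_kd=4,
        n_eif_kd=3,
        n_myc_kd=3,
        n_uncoupled=2,
    )
    base.update(overrides)
    return simulate.SimParams(**base)


@pytest.fixture(scope="session")
def default_run(config):
    """One default-condition dataset with the DE stage already run."""
    comp, sheet, truth = simulate.generate_compendium(seed=1)
    de = diffexpr.run_de(comp, sheet)
    sig_o = diffexpr.all_significant_sets(
        de, config.lfc_threshold_overlap, config.adj_p_threshold)
    sig_c = diffexpr.all_significant_sets(
        de, config.lfc_threshold_cluster, config.adj_p_threshold)
    shortlist = diffexpr.shortlist_genes(sig_c, config.min_experiments)
    return {"compendium": comp, "sheet": sheet, "truth": truth, "de": de,
            "sig_overlap": sig_o, "sig_cluster": sig_c, "shortlist": shortlist}


@pytest.fixture(scope="session")
def zero_noise_run(config):
    """Noise-free dataset: every planted quantity is exactly recoverable."""
    params = dataclasses.replace(
        simulate.SimParams(), noise_sd=0.0,
        phenotype_noise_sd=0.0, control_phenotype_noise_sd=0.0,
        size_noise_sd=0.0,
    )
    comp, sheet, truth = simulate.generate_compendium(params, seed=2)
    de = diffexpr.run_de(comp, sheet)
    sig_o = diffexpr.all_significant_sets(
        de, config.lfc_threshold_overlap, config.adj_p_threshold)
    sig_c = diffexpr.all_significant_sets(
        de, config.lfc_threshold_cluster, config.adj_p_threshold)
    shortlist = diffexpr.shortlist_genes(sig_c, config.min_experiments)
    pheno = simulate.generate_phenotypes(sheet, truth, seed=2)
    return {"compendium": comp, "sheet": sheet, "truth": truth, "de": de,
            "sig_overlap": sig_o, "sig_cluster": sig_c,
            "shortlist": shortlist, "pheno": pheno}
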