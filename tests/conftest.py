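import numpy as np
import pytest

from foldcons import FoldParams, RunConfig, SimConfig
from foldcons.pipeline import annotate_dataset
from foldcons.simulate import evolve_dataset, prepare_genes

# folding context used throughout the tests: small flank keeps windows short
TEST_FOLD = dict(flank=40, d_min_span=10)


@pytest.fixture(scope="session")
def fold_params():
    return FoldParams(**TEST_FOLD)


@pytest.fixture(scope="session")
def small_planted():
    """A small dataset with a strong planted effect, annotated for analysis.

    Shared across tests: 12 genes x 6 species x 80 codons, beta = 4.
    Returns (dataset, sites_by_gene, prepared).
    """
    cfg = SimConfig(n_genes=12, n_species=6, gene_length=80,
                    effect_beta=4.0, seed=42)
    prepared = prepare_genes(cfg, FoldParams(**TEST_FOLD))
    dataset = evolve_dataset(prepared, cfg)
    sites = annotate_dataset(dataset, prepared=prepared)
    return dataset, sites, prepared


@pytest.fixture(scope="session")
def small_null():
    """Same shape as small_planted but beta = 0 (the exchangeable null)."""
    cfg = SimConfig(n_genes=12, n_species=6, gene_length=80,
                    effect_beta=0.0, seed=43)
    prepared = prepare_genes(cfg, FoldParams(**TEST_FOLD))
    dataset = evolve_dataset(prepared, cfg)
    sites = annotate_dataset(dataset, prepared=prepared)
    return dataset, sites, prepared


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
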