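import numpy as np
import pytest

from genodiff.gene_embedding import encode, fit_codec
from genodiff.synthetic_cohort import CohortConfig, generate_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free diploid cohort: codec round-trip is exactly lossless."""
    cfg = CohortConfig(
        n_samples=200,
        n_genes=30,
        snps_per_gene=(5, 30),
        genotype_error_rate=0.0,
        n_causal_genes=10,
        effect_size=3.0,
        liability_noise=0.5,
        seed=7,
    )
    return generate_genotypes(cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_codec(small_cohort):
    return fit_codec(small_cohort.matrix, small_cohort.gene_map, depth=3)


@pytest.fixture(scope="session")
def small_embedding(small_cohort, small_codec):
    return encode(small_cohort.matrix, small_codec)
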