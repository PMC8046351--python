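import numpy as np
import pytest

from vctwas.genotype_io import GenotypeMatrix
from vctwas.weights import ExpressionVector


def make_genotype_matrix(rng, n, m, chrom="1", start_pos=1000, maf_low=0.1, maf_high=0.5):
    """Random independent-SNP genotype matrix (binomial dosages)."""
    mafs = rng.uniform(maf_low, maf_high, size=m)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(float)
    return GenotypeMatrix(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        snp_ids=[f"{chrom}:{start_pos * (j + 1)}:A:G" for j in range(m)],
        positions=np.arange(1, m + 1) * start_pos,
        dosages=dosages,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_geno(rng):
    return make_genotype_matrix(rng, n=150, m=12)


@pytest.fixture
def expression_for(rng):
    def _make(geno, weights=None, noise_sd=1.0):
        w = np.zeros(geno.m_snps) if weights is None else np.asarray(weights, float)
        values = geno.dosages @ w + rng.normal(0, noise_sd, geno.n_samples)
        return ExpressionVector(list(geno.sample_ids), values)

    return _make
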