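import numpy as np
import pytest

from imprintgp.genotypes import PhasedGenotypes
from imprintgp.simulate import SimulationConfig, simulate_population


def make_genotypes(paternal, maternal, chrom=None):
    """Wrap raw allele matrices in a PhasedGenotypes with generated ids."""
    paternal = np.asarray(paternal, dtype=np.int8)
    n, m = paternal.shape
    return PhasedGenotypes(
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"v{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 100,
        paternal=paternal,
        maternal=np.asarray(maternal, dtype=np.int8),
    )


def random_genotypes(rng, n, m, freqs=None):
    """HWE genotypes with independent paternal/maternal alleles."""
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=m)
    pat = (rng.random((n, m)) < freqs).astype(np.int8)
    mat = (rng.random((n, m)) < freqs).astype(np.int8)
    return make_genotypes(pat, mat)


@pytest.fixture(scope="session")
def small_population():
    """A small simulated population shared by read-only tests."""
    cfg = SimulationConfig(n_individuals=400, n_snps=250, seed=7)
    return simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
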