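import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_genotype_matrix(allele_counts, positions=None, contig="2L"):
    """Build a GenotypeMatrix from a (sites, samples, 4) count tensor."""
    from sweepcnv.containers import GenotypeMatrix

    allele_counts = np.asarray(allele_counts)
    n_sites, n_samples = allele_counts.shape[:2]
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    sample_ids = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(allele_counts, positions, sample_ids, contig)


def random_genotype_matrix(rng, n_sites, n_samples, n_alleles=2):
    """Random diploid allele-count tensor (each site/sample sums to 2)."""
    counts = np.zeros((n_sites, n_samples, 4), dtype=np.int16)
    for i in range(n_sites):
        for j in range(n_samples):
            a, b = rng.integers(n_alleles, size=2)
            counts[i, j, a] += 1
            counts[i, j, b] += 1
    return make_genotype_matrix(counts)
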