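import numpy as np
import pytest
from hypothesis import settings

from dompred.io_genotypes import GenotypeTable, SnpMeta

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_table(rng, n_animals, n_snps, missing_rate=0.0, lines=("L",)):
    """Random genotype table with Binomial(2, p) codes per SNP."""
    p = rng.uniform(0.05, 0.95, n_snps)
    codes = rng.binomial(2, p, size=(n_animals, n_snps)).astype(np.int8)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = -1
    snps = [SnpMeta(f"s{j:04d}", "1", j + 1, "A", "G") for j in range(n_snps)]
    labels = [lines[i % len(lines)] for i in range(n_animals)]
    ids = [f"an{i:04d}" for i in range(n_animals)]
    return GenotypeTable(ids, labels, snps, codes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table(rng):
    return make_table(rng, 12, 8)
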