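import numpy as np
import pandas as pd
import pytest

from crossgwas.emma import GenotypeMatrix


def genotypes_from_calls(calls, chrom="1", spacing=1000, strain_ids=None):
    """Build a GenotypeMatrix from a raw strains x SNPs array of {0,2,nan}."""
    calls = np.asarray(calls, dtype=float)
    n_strains, n_snps = calls.shape
    if strain_ids is None:
        strain_ids = [f"s{i:02d}" for i in range(n_strains)]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{j:04d}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": (np.arange(n_snps) + 1) * spacing,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return GenotypeMatrix(strain_ids=strain_ids, snp_map=snp_map, calls=calls)


@pytest.fixture
def make_genotypes():
    return genotypes_from_calls


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
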