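import numpy as np
import pandas as pd
import pytest

from regmeth.data import GenotypeData
from regmeth.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A 20-site dataset under the default study conditions (true h2 = 0.3)."""
    return simulate_dataset(SimConfig(seed=42, n_sites=20))


@pytest.fixture(scope="session")
def null_sim():
    """A 30-site dataset with zero genetic variance everywhere."""
    return simulate_dataset(
        SimConfig(seed=43, n_sites=30, h2_dist={"default": ("point", 0.0)})
    )


def random_genotypes(rng, n_samples, n_snps, chrom="chr1", maf_lo=0.1, maf_hi=0.5):
    """HWE genotypes with independent SNPs, for unit-level fixtures."""
    p = rng.uniform(maf_lo, maf_hi, n_snps)
    dosages = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, n_snps + 1) * 1000,
         "id": [f"s{j}" for j in range(n_snps)], "ref": "A", "alt": "G"}
    )
    return GenotypeData([f"i{k}" for k in range(n_samples)], snps, dosages)
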