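import numpy as np
import pandas as pd
import pytest

from panelblup import GenotypeMatrix, SimConfig, major_qtl_trait, polygenic_trait, simulate_dataset


def make_genotypes(dosages, chrom=None, pos=None, ids=None, a1="A", a2="B") -> GenotypeMatrix:
    """Small-fixture helper: wrap a dosage array in a GenotypeMatrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j:04d}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "a1": a1,
            "a2": a2,
        }
    )
    ids = ids if ids is not None else [f"an{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, snp_map, np.array(ids, dtype=object))


def random_genotypes(rng, n, m, p=None) -> GenotypeMatrix:
    if p is None:
        p = rng.uniform(0.1, 0.9, m)
    return make_genotypes(rng.binomial(2, p, size=(n, m)))


@pytest.fixture(scope="session")
def small_dataset():
    """Shared desk-scale two-cohort simulation (both architectures)."""
    cfg = SimConfig(
        n_train=300,
        n_external=120,
        m_snps=600,
        n_cg=10,
        seed=2024,
        traits=(major_qtl_trait(n_causal=100), polygenic_trait(n_causal=200)),
    )
    return simulate_dataset(cfg)
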