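"""Shared fixtures: small simulated studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from awmnet.containers import GenotypeMatrix
from awmnet.simulate import SimConfig, simulate_study


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_individuals=200,
        n_snps=2000,
        n_chromosomes=5,
        n_traits=8,
        trait_names=[f"t{i}" for i in range(8)],
        h2_targets=[0.4] * 8,
        n_modules=3,
        genes_per_module=6,
        hub_extra_targets=4,
        n_background_genes=40,
        n_decoy_regulators=10,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """200 individuals x 2,000 SNPs x 8 traits with 3 planted modules."""
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def clean_panel():
    """A QC-clean panel: no missingness, no unmapped SNPs, common alleles."""
    cfg = small_config(
        maf_range=(0.1, 0.5), missing_rate=0.0, high_missing_frac=0.0,
        unmapped_frac=0.0, seed=7,
    )
    return simulate_study(cfg)


def random_genotypes(rng, n, m, maf=(0.1, 0.5), pool=20) -> GenotypeMatrix:
    """Unstructured helper panel (haplotype pool for relatedness)."""
    p = rng.uniform(*maf, m)
    haps = (rng.random((pool, m)) < p).astype(float)
    idx = rng.integers(0, pool, 2 * n)
    dosage = haps[idx[:n]] + haps[idx[n:]]
    freq = dosage.mean(axis=0) / 2
    keep = (freq > 0.02) & (freq < 0.98)
    dosage = dosage[:, keep]
    m = int(keep.sum())
    meta = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "allele_counted": "B",
            "allele_other": "A",
        }
    )
    return GenotypeMatrix(dosage, meta, [f"i{j}" for j in range(n)])
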