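import numpy as np
import pytest

from ethnogene import (
    CohortGenotypes,
    SimConfig,
    VariantKey,
    VariantTable,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 2-group, 300-SNP simulated dataset shared by read-only tests."""
    return simulate_cohort(
        SimConfig(n_groups=2, samples_per_group=30, n_snps=300, n_genes=5, seed=1)
    )


def build_cohort(haplotypes, group_of=None, positions=None, refs=None, alts=None):
    """Hand-build a cohort from a (samples, 2, snps) 0/1 array."""
    haps = np.asarray(haplotypes, dtype=np.uint8)
    n_samples, _, n_snps = haps.shape
    sample_ids = [f"S{i}" for i in range(n_samples)]
    if group_of is None:
        group_of = {s: "G1" for s in sample_ids}
    else:
        group_of = {f"S{i}": g for i, g in enumerate(group_of)}
    positions = positions or [100 * (j + 1) for j in range(n_snps)]
    refs = refs or ["A"] * n_snps
    alts = alts or ["G"] * n_snps
    snps = [VariantKey("1", p, r, a) for p, r, a in zip(positions, refs, alts)]
    return CohortGenotypes(sample_ids, group_of, haps, snps)


@pytest.fixture
def five_diploids():
    """One group of 5 diploids, 1 SNP with 3 alt alleles out of 10 (maf 0.3)."""
    haps = np.zeros((5, 2, 1), dtype=np.uint8)
    haps[0, 0, 0] = 1
    haps[1, 0, 0] = 1
    haps[1, 1, 0] = 1
    return build_cohort(haps)


def variant_table_with_aa(cohort, ancestral):
    return VariantTable.from_cohort(cohort, ancestral)
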