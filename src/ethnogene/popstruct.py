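"""Population structure and genetic diversity on disease-gene SNP subsets.

* PCA on the dosage matrix restricted to a disease's genes, with per-SNP
  centering by mean dosage and scaling by sqrt(p(1-p)) where
  p = (1 + alt count) / (2 + total count) — the pseudocount convention of
  smartpca, so loadings match EIGENSOFT-style analyses.
* Hudson's Fst between group pairs as a ratio of averages, the standard
  recommendation when sample sizes differ across groups.
* Observed vs expected (Hardy–Weinberg) heterozygosity per gene and group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import SnpGeneMap
from .datamodel import CohortGenotypes, GeneTable


@dataclass
class PcaResult:
    """Sample coordinates and variances of the leading principal components."""

    eigenvectors: np.ndarray  # (n_samples, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), non-increasing, non-negative
    snps_used: int
    means: np.ndarray  # per-SNP centering constants
    scales: np.ndarray  # per-SNP scaling constants


def _normalize_dosage(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """smartpca normalization: center by mean, scale by sqrt(p(1-p)), pseudocounted."""
    n = X.shape[0]
    alt = X.sum(axis=0)
    total = 2 * n
    p_hat = (1.0 + alt) / (2.0 + total)
    means = X.mean(axis=0)
    scales = np.sqrt(p_hat * (1.0 - p_hat))
    return (X - means) / scales, means, scales


def pca_genotypes(cohort: CohortGenotypes, snp_indices: np.ndarray, k: int) -> PcaResult:
    """PCA of the cohort restricted to ``snp_indices`` (monomorphic SNPs dropped)."""
    snp_indices = np.asarray(snp_indices, dtype=np.intp)
    X = cohort.dosages()[:, snp_indices].astype(np.float64)
    poly = X.std(axis=0) > 0
    if int(poly.sum()) < k + 1:
        raise ValueError(
            f"only {int(poly.sum())} polymorphic SNPs available; need at least {k + 1} for k={k}"
        )
    X = X[:, poly]
    Xn, means, scales = _normalize_dosage(X)
    m = Xn.shape[1]
    # covariance across samples; eigendecomposition via SVD of the normalized matrix
    U, s, _ = np.linalg.svd(Xn, full_matrices=False)
    eigvals = (s**2) / m
    U, eigvals = U[:, :k], eigvals[:k]
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return PcaResult(U, eigvals, int(m), means, scales)


def pca_disease(
    cohort: CohortGenotypes,
    snp_map: SnpGeneMap,
    genes: GeneTable,
    disease: str,
    k: int = 10,
) -> PcaResult:
    """PCA on the SNPs mapped to the genes of one disease set."""
    members = genes.genes_for_disease(disease)
    if not members:
        raise ValueError(f"no genes annotated for disease {disease!r}")
    idx = np.unique(np.concatenate([snp_map[g] for g in members])).astype(np.intp)
    if idx.size == 0:
        raise ValueError(f"no SNPs mapped to {disease!r} genes")
    return pca_genotypes(cohort, idx, k)


@dataclass
class FstResult:
    """Hudson Fst between two groups: per-SNP components and the ratio of averages."""

    numerators: np.ndarray
    denominators: np.ndarray
    fst: float


def hudson_fst(
    cohort: CohortGenotypes,
    group_a: str,
    group_b: str,
    snp_indices: np.ndarray | None = None,
) -> FstResult:
    """Hudson's Fst estimator, ratio of averages over SNPs.

    Per SNP, with p the alt frequency and n the *allele* count in each group:

        num = (p_a - p_b)^2 - p_a(1-p_a)/(n_a - 1) - p_b(1-p_b)/(n_b - 1)
        den = p_a(1-p_b) + p_b(1-p_a)

    and Fst = sum(num) / sum(den).  Unbiased under unequal sample sizes; can
    be slightly negative when true differentiation is nil.
    """
    for g in (group_a, group_b):
        if cohort.sample_indices(g).size < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples for Hudson Fst")
    alt_a, tot_a = cohort.allele_counts(group_a)
    alt_b, tot_b = cohort.allele_counts(group_b)
    if snp_indices is not None:
        snp_indices = np.asarray(snp_indices, dtype=np.intp)
        alt_a, tot_a = alt_a[snp_indices], tot_a[snp_indices]
        alt_b, tot_b = alt_b[snp_indices], tot_b[snp_indices]
    pa, pb = alt_a / tot_a, alt_b / tot_b
    num = (
        (pa - pb) ** 2
        - pa * (1 - pa) / (tot_a - 1)
        - pb * (1 - pb) / (tot_b - 1)
    )
    den = pa * (1 - pb) + pb * (1 - pa)
    den_sum = float(den.sum())
    fst = float(num.sum() / den_sum) if den_sum > 0 else np.nan
    return FstResult(num, den, fst)


def pairwise_fst(cohort: CohortGenotypes, snp_indices: np.ndarray | None = None) -> pd.DataFrame:
    """Hudson Fst for every unordered group pair (long DataFrame)."""
    groups = cohort.groups
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            rows.append(
                {"group_a": ga, "group_b": gb, "fst": hudson_fst(cohort, ga, gb, snp_indices).fst}
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "fst"])


def snp_heterozygosity(cohort: CohortGenotypes, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (h_obs, h_exp) in one group.

    h_obs is the fraction of heterozygous samples; h_exp = 2p(1-p) with p the
    group alt-allele frequency.
    """
    idx = cohort.sample_indices(group)
    h = cohort.haplotypes[idx]
    h_obs = (h[:, 0, :] != h[:, 1, :]).mean(axis=0)
    p = h.sum(axis=(0, 1)) / (2 * idx.size)
    return h_obs, 2.0 * p * (1.0 - p)


def heterozygosity(
    cohort: CohortGenotypes, snp_map: SnpGeneMap, group: str
) -> pd.DataFrame:
    """Per-gene unweighted means of per-SNP observed/expected heterozygosity."""
    h_obs, h_exp = snp_heterozygosity(cohort, group)
    rows = []
    for gene, idx in snp_map.items():
        if idx.size == 0:
            rows.append({"gene": gene, "n_snps": 0, "h_obs": np.nan, "h_exp": np.nan})
        else:
            rows.append(
                {
                    "gene": gene,
                    "n_snps": int(idx.size),
                    "h_obs": float(h_obs[idx].mean()),
                    "h_exp": float(h_exp[idx].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "n_snps", "h_obs", "h_exp"])
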