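"""SNP-to-gene mapping and gene-level aggregation.

SNPs are mapped to a gene when their position lies within
``[start - window_bp, end + window_bp]`` (default window 40 kb each side,
clipped at position 1); a SNP may map to several genes.  Per-SNP values in
[0, 1] — allele frequencies or derived-allele proportions — are aggregated to
gene level by an unweighted mean and, separately, by the Stouffer–Liptak
combination with a correlation-corrected variance:

    q_k = Phi^{-1}(P_k),    Z = sum_k q_k / sqrt(1' Sigma 1),    P = Phi(Z)

where Sigma is the Pearson correlation of alt-allele dosages between the
gene's SNPs within the group (the linkage-disequilibrium structure).  With
Sigma = I this reduces to the classical Stouffer combination.  Positive
dependence inflates the denominator, shrinking |Z| — the correction that
keeps the combined value calibrated when neighbouring SNPs are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortGenotypes, GeneTable, VariantKey

logger = logging.getLogger("ethnogene")

#: alias: mapping gene name -> sorted array of SNP indices into the cohort order
SnpGeneMap = dict

_EPS = 1e-15


def map_snps(snps: list[VariantKey], genes: GeneTable) -> SnpGeneMap:
    """Map each gene to the indices of SNPs inside its aggregation window.

    ``snps`` must be sorted by (chromosome, position), as produced by the
    loader; mapped indices are returned in position order.  A gene whose
    chromosome carries no SNPs maps to an empty list (with a warning).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = np.array([k.chrom for k in snps])
    positions = np.array([k.pos for k in snps], dtype=np.int64)
    for c in dict.fromkeys(chroms):
        mask = chroms == c
        by_chrom[c] = (positions[mask], np.flatnonzero(mask))

    out: SnpGeneMap = {}
    for row in genes.windows().itertuples(index=False):
        if row.chrom not in by_chrom:
            logger.warning("gene %s: chromosome %s absent from variants", row.gene, row.chrom)
            out[row.gene] = np.array([], dtype=np.intp)
            continue
        pos, idx = by_chrom[row.chrom]
        lo = np.searchsorted(pos, row.wstart, side="left")
        hi = np.searchsorted(pos, row.wend, side="right")
        out[row.gene] = idx[lo:hi]
    return out


def ld_correlation(
    cohort: CohortGenotypes, snp_indices: np.ndarray, group: str
) -> np.ndarray:
    """Pearson correlation of per-sample alt dosage between SNP pairs.

    Monomorphic SNPs (zero dosage variance in the group) get unit diagonal and
    zero off-diagonals.  The matrix is projected to the nearest positive
    semidefinite matrix by clipping negative eigenvalues at zero, so it is
    always usable as a combination covariance.
    """
    snp_indices = np.asarray(snp_indices, dtype=np.intp)
    if snp_indices.size == 0:
        raise ValueError("need at least one SNP")
    X = cohort.dosages(group)[:, snp_indices].astype(np.float64)
    L = X.shape[1]
    sd = X.std(axis=0)
    poly = sd > 0
    corr = np.eye(L)
    if poly.sum() >= 2:
        sub = np.corrcoef(X[:, poly], rowvar=False)
        sub = np.nan_to_num(sub, nan=0.0)
        np.fill_diagonal(sub, 1.0)
        ix = np.flatnonzero(poly)
        corr[np.ix_(ix, ix)] = sub
    corr = 0.5 * (corr + corr.T)
    w, V = np.linalg.eigh(corr)
    if w[0] < -1e-10:
        corr = (V * np.clip(w, 0.0, None)) @ V.T
        corr = 0.5 * (corr + corr.T)
    return corr


def stouffer_liptak(
    p_values: np.ndarray, corr: np.ndarray | None = None, literal: bool = False
) -> float:
    """Combine values in [0, 1] into one, correcting for correlation.

    Values are clamped to [1e-15, 1 - 1e-15] before the normal-quantile
    transform.  ``literal=True`` instead applies the naive arithmetic
    ``Phi(mean(P_k))`` — emitted for comparison output only; it is not a
    calibrated combination and is never used by the pipeline proper.
    """
    p = np.clip(np.asarray(p_values, dtype=np.float64), _EPS, 1.0 - _EPS)
    L = p.size
    if L == 0:
        raise ValueError("need at least one value to combine")
    if literal:
        return float(stats.norm.cdf(p.mean()))
    if corr is None:
        corr = np.eye(L)
    corr = np.asarray(corr, dtype=np.float64)
    if corr.shape != (L, L):
        raise ValueError(f"correlation matrix must be {L}x{L}")
    denom2 = float(np.sum(corr))
    if denom2 <= 0:
        raise ValueError("correlation matrix is not positive semidefinite (1'S1 <= 0)")
    q = stats.norm.ppf(p)
    z = q.sum() / np.sqrt(denom2)
    return float(stats.norm.cdf(z))


@dataclass
class GeneAggregate:
    """Per-gene aggregation of one per-SNP statistic."""

    table: pd.DataFrame  # columns: gene, L, mean, combined_P


def aggregate_gene(
    snp_map: SnpGeneMap,
    per_snp_values: np.ndarray,
    cohort: CohortGenotypes,
    group: str,
    combine: bool = True,
    min_group_size_for_ld: int = 3,
) -> pd.DataFrame:
    """Aggregate per-SNP values in [0, 1] to gene level.

    Returns a DataFrame (gene, L, mean, combined_P): L the number of mapped
    SNPs with a non-null value, ``mean`` their unweighted mean, ``combined_P``
    the LD-aware Stouffer–Liptak combination (identity correlation when the
    group has fewer than ``min_group_size_for_ld`` samples).  Genes with L = 0
    report nulls.  Null (NaN) per-SNP values are dropped with a logged count.
    """
    values = np.asarray(per_snp_values, dtype=np.float64)
    if values.shape != (cohort.n_snps,):
        raise ValueError("per_snp_values must align with the cohort SNP index")
    finite = np.isfinite(values)
    if finite.any() and (
        (values[finite] < 0).any() or (values[finite] > 1).any()
    ):
        raise ValueError("per-SNP values must lie in [0, 1]")
    n_group = cohort.sample_indices(group).size
    use_ld = n_group >= min_group_size_for_ld
    if not use_ld:
        logger.warning(
            "group %s has %d samples (< %d): identity correlation substituted",
            group, n_group, min_group_size_for_ld,
        )
    n_dropped = 0
    rows = []
    for gene, idx in snp_map.items():
        keep = idx[finite[idx]]
        n_dropped += idx.size - keep.size
        if keep.size == 0:
            rows.append({"gene": gene, "L": 0, "mean": np.nan, "combined_P": np.nan})
            continue
        vals = values[keep]
        combined = np.nan
        if combine:
            corr = ld_correlation(cohort, keep, group) if use_ld else None
            combined = stouffer_liptak(vals, corr)
        rows.append(
            {"gene": gene, "L": int(keep.size), "mean": float(vals.mean()), "combined_P": combined}
        )
    if n_dropped:
        logger.info("aggregate_gene: %d null per-SNP values dropped", n_dropped)
    return pd.DataFrame(rows)
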