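"""Consensus pathogenicity calling and per-gene pathogenic burden.

A variant passes the *casting vote* when at least ``threshold`` of the
``n_predictors`` functional-predictor statuses are damaging (``D`` or ``A``);
it is called pathogenic when it additionally satisfies the required
candidate-set flags (rare, exonic, nonsynonymous).  Voting and flag filtering
are conjunctive, so their order does not affect the result.

The per-gene, per-group burden is the proportion of pathogenic variants among
the variants mapped to the gene that *segregate* in that group; monomorphic
sites carry no information about a group's burden, so genes with no
segregating mapped SNPs report a null (NaN) proportion rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import SnpGeneMap, map_snps
from .datamodel import CohortGenotypes, GeneTable, PredictionMatrix, VariantKey

DAMAGING_STATUSES = ("D", "A")


@dataclass
class VoteConfig:
    threshold: int = 17
    n_predictors: int = 21
    require_rare: bool = True
    require_exonic: bool = True
    require_nonsynonymous: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= self.n_predictors):
            raise ValueError("threshold must lie in [0, n_predictors]")


@dataclass
class PathogenicCallSet:
    """Per-SNP damaging-vote counts and the final pathogenic calls."""

    keys: list[VariantKey]
    votes: np.ndarray
    is_pathogenic: np.ndarray

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.int64)
        self.is_pathogenic = np.asarray(self.is_pathogenic, dtype=bool)
        if self.votes.shape != (len(self.keys),) or self.is_pathogenic.shape != self.votes.shape:
            raise ValueError("votes/is_pathogenic must have one entry per SNP")


def casting_vote(pred: PredictionMatrix, cfg: VoteConfig | None = None) -> PathogenicCallSet:
    """Apply the consensus vote: pathogenic iff votes >= threshold and flags hold.

    A missing status (any character outside {D, A}, including the explicit
    missing marker) counts as a non-damaging vote, keeping vote totals
    comparable across SNPs.
    """
    cfg = cfg or VoteConfig()
    if pred.n_predictors != cfg.n_predictors:
        bad = pred.keys[0] if pred.keys else "?"
        raise ValueError(
            f"prediction matrix has {pred.n_predictors} status slots per SNP "
            f"(expected {cfg.n_predictors}; first SNP {bad})"
        )
    damaging = np.isin(pred.statuses, DAMAGING_STATUSES)
    votes = damaging.sum(axis=1).astype(np.int64)
    passed = votes >= cfg.threshold
    if cfg.require_rare:
        passed &= pred.is_rare
    if cfg.require_exonic:
        passed &= pred.is_exonic
    if cfg.require_nonsynonymous:
        passed &= pred.is_nonsynonymous
    return PathogenicCallSet(list(pred.keys), votes, passed)


def pathogenic_proportion(
    calls: PathogenicCallSet,
    cohort: CohortGenotypes,
    genes: GeneTable,
    group: str,
    snp_map: SnpGeneMap | None = None,
) -> pd.Series:
    """Per-gene proportion of pathogenic variants among segregating mapped SNPs.

    ``calls`` must share the cohort's SNP index.  Returns a Series indexed by
    gene name; NaN where no mapped SNP segregates in the group.
    """
    if list(calls.keys) != list(cohort.snps):
        raise ValueError("call set and cohort must share the same SNP index")
    if group not in cohort.groups:
        raise KeyError(f"unknown group label: {group!r}")
    if snp_map is None:
        snp_map = map_snps(cohort.snps, genes)
    alt, total = cohort.allele_counts(group)
    segregating = (alt > 0) & (alt < total)
    out = {}
    for gene in genes.genes:
        idx = snp_map[gene]
        seg_idx = idx[segregating[idx]]
        if seg_idx.size == 0:
            out[gene] = np.nan
        else:
            out[gene] = float(calls.is_pathogenic[seg_idx].mean())
    return pd.Series(out, name="pathogenic_proportion")
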