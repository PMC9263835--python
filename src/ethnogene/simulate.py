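"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without external genotype data:

* group-differentiated allele frequencies under the Balding–Nichols model —
  for each SNP an ancestral frequency ``p ~ Beta(a, b)`` and per-group
  frequencies ``p_g ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, so the differentiation
  parameter ``F`` maps directly onto the Fst the pipeline estimates;
* haplotype alleles drawn ``Bernoulli(p_g)`` independently (Hardy–Weinberg
  within each group; sites independent, i.e. no linkage along the chromosome);
* an ancestral-allele label per SNP (the reference allele for a configurable
  fraction of SNPs, the alternate otherwise);
* genes tiled along one simulated chromosome, with disease memberships and
  odds-ratio directions cycled deterministically;
* a 21-predictor status matrix with a latent true-pathogenicity state: each
  predictor independently calls D/A with probability ``predictor_sensitivity``
  for latent-pathogenic SNPs and ``1 - predictor_specificity`` otherwise.

Everything is reproducible from ``SimConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .datamodel import (
    DEFAULT_WINDOW_BP,
    DISEASES,
    N_PREDICTORS,
    CohortGenotypes,
    GeneTable,
    PredictionMatrix,
    VariantKey,
    VariantTable,
)
import pandas as pd


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``fst`` is the Balding–Nichols differentiation parameter F in (0, 1);
    ``ancestral_freq_dist`` the Beta(a, b) of the global ancestral allele
    frequency; ``frac_pathogenic`` the latent pathogenic SNP fraction;
    ``predictor_sensitivity``/``predictor_specificity`` the per-predictor
    probability of a correct damaging / benign call.  ``frac_aa_ref`` is the
    fraction of SNPs whose ancestral allele is the reference allele (derived
    alleles are usually the alternate allele).  Flag rates default to 1.0,
    emulating a prediction matrix already restricted to the rare exonic
    nonsynonymous candidate set.
    """

    n_groups: int = 4
    samples_per_group: int = 50
    n_snps: int = 2000
    n_genes: int = 10
    fst: float = 0.1
    ancestral_freq_dist: tuple[float, float] = (2.0, 2.0)
    frac_pathogenic: float = 0.1
    predictor_sensitivity: float = 0.9
    predictor_specificity: float = 0.9
    seed: int = 0
    frac_aa_ref: float = 0.8
    aa_low_confidence_rate: float = 0.1
    rare_rate: float = 1.0
    exonic_rate: float = 1.0
    nonsynonymous_rate: float = 1.0
    window_bp: int = DEFAULT_WINDOW_BP
    gene_length_bp: int = 20_000
    gene_gap_bp: int = 10_000
    overlap_genes: bool = False

    def __post_init__(self) -> None:
        for name in ("n_groups", "samples_per_group", "n_snps", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        a, b = self.ancestral_freq_dist
        if a <= 0 or b <= 0:
            raise ValueError("ancestral_freq_dist Beta parameters must be > 0")
        for name in ("frac_pathogenic", "frac_aa_ref", "aa_low_confidence_rate",
                     "rare_rate", "exonic_rate", "nonsynonymous_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("predictor_sensitivity", "predictor_specificity"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


class SimResult(NamedTuple):
    cohort: CohortGenotypes
    variants: VariantTable
    predictions: PredictionMatrix
    genes: GeneTable
    latent_pathogenic: np.ndarray  # ground truth, for validation only


def _sample_frame(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    sample_ids, group_of = [], {}
    for g in range(cfg.n_groups):
        label = f"G{g + 1:02d}"
        for s in range(cfg.samples_per_group):
            sid = f"{label}_S{s + 1:04d}"
            sample_ids.append(sid)
            group_of[sid] = label
    return sample_ids, group_of


def _tile_genes(cfg: SimConfig) -> tuple[GeneTable, int]:
    """Tile n_genes along chromosome 1; returns (table, chromosome length).

    By default the stride exceeds gene length + 2*window, so aggregation
    windows do not overlap; with ``overlap_genes`` the stride shrinks to half
    a window and neighbouring genes share mapped SNPs.
    """
    if cfg.overlap_genes:
        stride = cfg.window_bp // 2 + cfg.gene_length_bp
    else:
        stride = cfg.gene_length_bp + 2 * cfg.window_bp + cfg.gene_gap_bp
    rows = []
    directions = ("risk", "protective", "risk", "protective", "unknown")
    for i in range(cfg.n_genes):
        start = cfg.window_bp + 1 + i * stride
        rows.append(
            {
                "gene": f"GENE{i + 1:03d}",
                "chrom": "1",
                "start": start,
                "end": start + cfg.gene_length_bp - 1,
                "diseases": frozenset({DISEASES[i % len(DISEASES)]}),
                "or_direction": directions[i % len(directions)],
                "window_bp": cfg.window_bp,
            }
        )
    chrom_len = cfg.window_bp + cfg.n_genes * stride + cfg.window_bp
    return GeneTable(pd.DataFrame(rows)), chrom_len


def _draw_sites(cfg: SimConfig, rng: np.random.Generator, chrom_len: int):
    positions = np.sort(rng.choice(chrom_len, size=cfg.n_snps, replace=False)) + 1
    refs = rng.integers(0, 4, size=cfg.n_snps)
    alts = (refs + rng.integers(1, 4, size=cfg.n_snps)) % 4
    bases = np.array(["A", "C", "G", "T"])
    keys = [
        VariantKey("1", int(p), bases[r], bases[a])
        for p, r, a in zip(positions, refs, alts)
    ]
    return keys


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic dataset under ``cfg`` (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)
    sample_ids, group_of = _sample_frame(cfg)
    genes, chrom_len = _tile_genes(cfg)
    keys = _draw_sites(cfg, rng, chrom_len)

    a, b = cfg.ancestral_freq_dist
    p = rng.beta(a, b, size=cfg.n_snps)
    p = np.clip(p, 1e-4, 1 - 1e-4)
    F = cfg.fst
    scale = (1.0 - F) / F
    # (n_groups, n_snps) group-specific frequencies
    p_g = rng.beta(p * scale, (1.0 - p) * scale, size=(cfg.n_groups, cfg.n_snps))

    haps = np.empty((len(sample_ids), 2, cfg.n_snps), dtype=np.uint8)
    for g in range(cfg.n_groups):
        sl = slice(g * cfg.samples_per_group, (g + 1) * cfg.samples_per_group)
        u = rng.random((cfg.samples_per_group, 2, cfg.n_snps))
        haps[sl] = (u < p_g[g][None, None, :]).astype(np.uint8)

    aa_is_ref = rng.random(cfg.n_snps) < cfg.frac_aa_ref
    aa = [k.ref if is_ref else k.alt for k, is_ref in zip(keys, aa_is_ref)]
    aa_lowconf = rng.random(cfg.n_snps) < cfg.aa_low_confidence_rate

    cohort = CohortGenotypes(sample_ids, group_of, haps, keys)
    variants = VariantTable.from_cohort(cohort, aa, aa_lowconf)

    latent = rng.random(cfg.n_snps) < cfg.frac_pathogenic
    p_damaging = np.where(latent, cfg.predictor_sensitivity, 1.0 - cfg.predictor_specificity)
    damaging = rng.random((cfg.n_snps, N_PREDICTORS)) < p_damaging[:, None]
    # damaging calls are mostly "D", occasionally "A"; benign calls "T"
    use_a = rng.random((cfg.n_snps, N_PREDICTORS)) < 0.25
    statuses = np.where(damaging, np.where(use_a, "A", "D"), "T").astype("<U1")
    pred = PredictionMatrix(
        keys,
        statuses,
        rng.random(cfg.n_snps) < cfg.rare_rate,
        rng.random(cfg.n_snps) < cfg.exonic_rate,
        rng.random(cfg.n_snps) < cfg.nonsynonymous_rate,
    )
    return SimResult(cohort, variants, pred, genes, latent)


def simulate_under_hwe_null(cfg: SimConfig, fixed_p: float | None = None) -> CohortGenotypes:
    """Generate genotypes with no group differentiation (F -> 0 limit).

    All groups share the ancestral frequency ``p`` of each SNP, so observed
    heterozygosity should match the Hardy–Weinberg expectation ``2p(1-p)``
    up to binomial sampling noise.  ``fixed_p`` pins every SNP's frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids, group_of = _sample_frame(cfg)
    _, chrom_len = _tile_genes(cfg)
    keys = _draw_sites(cfg, rng, chrom_len)
    if fixed_p is not None:
        p = np.full(cfg.n_snps, float(fixed_p))
    else:
        a, b = cfg.ancestral_freq_dist
        p = np.clip(rng.beta(a, b, size=cfg.n_snps), 1e-4, 1 - 1e-4)
    n = len(sample_ids)
    haps = (rng.random((n, 2, cfg.n_snps)) < p[None, None, :]).astype(np.uint8)
    return CohortGenotypes(sample_ids, group_of, haps, keys)
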