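"""Per-group minor-allele frequencies, the six-bin MAF spectrum, the
odds-ratio risk-allele rule, and ancestral/derived allele fractions.

The minor allele is defined *per group*: for a gene reported to increase
disease risk (odds ratio > 1) the risk allele of every SNP mapped to the gene
is that group's minor allele; for a protective gene (OR < 1) it is the major
allele.  The risk allele can therefore differ between groups for the same SNP.

The ancestral fraction of a SNP counts, among the group's alternate-allele
copies, those that are the risk allele and match the ancestral allele (the
``AA`` VCF tag); the derived fraction is its exact complement.  When the risk
allele and the ancestral allele are both the reference allele no alternate
copy can match, the fraction is 0 by construction, and the row is QC-flagged
(``qc_ref_risk_ancestral``) because the count-based definition is blind to
reference-allele matches.  An alternative denominator — risk-allele copies
over total allele copies — is available via ``denominator="risk-over-total"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import SnpGeneMap, map_snps
from .datamodel import CohortGenotypes, GeneTable, VariantTable

logger = logging.getLogger("ethnogene")

#: six-bin boundaries: (0-0.05], (0.05-0.1], (0.1-0.2], (0.2-0.3], (0.3-0.4], (0.4-0.5]
MAF_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
N_BINS = 6

RULE_RISK = "minor-because-OR>1"
RULE_PROTECTIVE = "major-because-OR<1"
RULE_NONE = "none-unknown-OR"


def compute_maf(cohort: CohortGenotypes, group: str) -> np.ndarray:
    """Per-SNP minor allele frequency min(f_alt, 1 - f_alt) within a group.

    The minimum is taken on integer allele counts before a single division,
    so the result is exact up to one rounding and invariant under ref/alt
    label swap (no ``1 - f`` accumulation error at bin boundaries).
    """
    alt, total = cohort.allele_counts(group)
    return np.minimum(alt, total - alt) / total


@dataclass
class MafSpectrum:
    """Six-bin MAF spectrum of one group.

    ``bin_index[i]`` is the bin (0..5) of SNP i, or -1 when monomorphic
    (maf = 0, excluded from the spectrum and counted separately).  Bins are
    lower-exclusive / upper-inclusive, so a boundary value such as 0.05 falls
    in the lower bin.
    """

    mafs: np.ndarray
    bin_index: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray
    monomorphic_count: int

    @property
    def n_snps(self) -> int:
        return self.mafs.size


def bin_spectrum(mafs: np.ndarray) -> MafSpectrum:
    """Bin per-SNP MAFs into the six fixed intervals."""
    mafs = np.asarray(mafs, dtype=np.float64)
    if (mafs < 0).any() or (mafs > 0.5 + 1e-12).any():
        raise ValueError("MAF outside [0, 0.5]: upstream invariant violated")
    inner = np.array(MAF_BIN_EDGES[1:])
    bin_index = np.digitize(mafs, inner, right=True)
    bin_index[mafs == 0] = -1
    counts = np.bincount(bin_index[bin_index >= 0], minlength=N_BINS).astype(np.int64)
    seg = counts.sum()
    proportions = counts / seg if seg else np.full(N_BINS, np.nan)
    return MafSpectrum(mafs, bin_index, counts, proportions, int((mafs == 0).sum()))


def call_risk_alleles(
    cohort: CohortGenotypes,
    genes: GeneTable,
    group: str,
    snp_map: SnpGeneMap | None = None,
) -> pd.DataFrame:
    """Apply the OR-direction rule per gene x mapped SNP within a group.

    Returns a long DataFrame (gene, snp_idx, chrom, pos, ref, alt,
    risk_allele, rule_used).  A SNP mapped to genes with conflicting
    directions gets one row per gene — calls are never merged.  At
    f_alt = 0.5 the alternate allele is deemed minor (deterministic tie).
    """
    if snp_map is None:
        snp_map = map_snps(cohort.snps, genes)
    alt_count, total = cohort.allele_counts(group)
    f_alt = alt_count / total
    minor_is_alt = f_alt <= 0.5  # tie broken to alt
    rows = []
    directions = dict(zip(genes.df["gene"], genes.df["or_direction"]))
    for gene, idx in snp_map.items():
        direction = directions[gene]
        for i in idx:
            key = cohort.snps[i]
            if direction == "risk":
                risk = key.alt if minor_is_alt[i] else key.ref
                rule = RULE_RISK
            elif direction == "protective":
                risk = key.ref if minor_is_alt[i] else key.alt
                rule = RULE_PROTECTIVE
            else:
                risk, rule = None, RULE_NONE
            rows.append(
                {
                    "gene": gene,
                    "snp_idx": int(i),
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "risk_allele": risk,
                    "rule_used": rule,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "snp_idx", "chrom", "pos", "ref", "alt", "risk_allele", "rule_used"],
    )


def allele_fractions(
    cohort: CohortGenotypes,
    variants: VariantTable,
    risk: pd.DataFrame,
    group: str,
    denominator: str = "literal",
) -> pd.DataFrame:
    """Ancestral/derived fractions per risk-allele call (see module docstring).

    ``denominator="literal"`` divides matched risk-allele copies by the
    group's alternate-allele copies; ``"risk-over-total"`` divides risk-allele
    copies (when risk matches ancestral) by total allele copies.  SNPs whose
    denominator is zero report null fractions; ancestral-unresolved SNPs are
    excluded with a logged count.
    """
    if denominator not in ("literal", "risk-over-total"):
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    alt_count = variants.group_alt_counts[group]
    total = variants.group_total_counts[group]
    resolved = variants.ancestral_resolved

    rows = []
    n_unresolved = 0
    for r in risk.itertuples(index=False):
        i = r.snp_idx
        if r.risk_allele is None or (isinstance(r.risk_allele, float) and np.isnan(r.risk_allele)):
            continue
        if not resolved[i]:
            n_unresolved += 1
            continue
        anc = variants.ancestral_allele[i]
        risk_is_alt = r.risk_allele == r.alt
        risk_copies = int(alt_count[i] if risk_is_alt else total[i] - alt_count[i])
        matched = r.risk_allele == anc
        if denominator == "literal":
            # matches are counted among alternate-allele copies, so a
            # reference risk allele can never match (QC-flagged below)
            num = alt_count[i] if (matched and risk_is_alt) else 0
            den = alt_count[i]
        else:
            num = risk_copies if matched else 0
            den = total[i]
        frac = float(num) / float(den) if den > 0 else np.nan
        rows.append(
            {
                "gene": r.gene,
                "snp_idx": i,
                "chrom": r.chrom,
                "pos": r.pos,
                "risk_allele": r.risk_allele,
                "ancestral_allele": anc,
                "ancestral_fraction": frac,
                "derived_fraction": 1.0 - frac if np.isfinite(frac) else np.nan,
                "qc_ref_risk_ancestral": bool(matched and not risk_is_alt),
            }
        )
    if n_unresolved:
        logger.info("allele_fractions: %d ancestral-unresolved calls excluded", n_unresolved)
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "snp_idx", "chrom", "pos", "risk_allele", "ancestral_allele",
            "ancestral_fraction", "derived_fraction", "qc_ref_risk_ancestral",
        ],
    )


def derived_by_maf_bin(fracs: pd.DataFrame, spectrum: MafSpectrum) -> np.ndarray:
    """Unweighted mean derived fraction per MAF bin; NaN for empty bins.

    ``fracs`` and ``spectrum`` must come from the same group and SNP index;
    a SNP mapped to several genes contributes one row per call.
    """
    if len(fracs) and fracs["snp_idx"].max() >= spectrum.n_snps:
        raise ValueError("fraction table and spectrum cover different SNP sets")
    out = np.full(N_BINS, np.nan)
    if not len(fracs):
        return out
    bins = spectrum.bin_index[fracs["snp_idx"].to_numpy()]
    derived = fracs["derived_fraction"].to_numpy()
    ok = (bins >= 0) & np.isfinite(derived)
    for b in range(N_BINS):
        sel = ok & (bins == b)
        if sel.any():
            out[b] = float(derived[sel].mean())
    return out
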