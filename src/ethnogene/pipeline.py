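"""End-to-end driver: simulate -> write inputs -> reload -> all statistics.

Produces the tabular twins of the study's figures: per gene x group tables of
pathogenic proportion, gene-level MAF, derived-allele proportion, the
Stouffer–Liptak combined statistic, and observed/expected heterozygosity,
plus pairwise Hudson Fst and disease-specific PCA coordinates.  All outputs
are plain TSV with fixed ordering and formatting, so identical configuration
and seed give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import aggregate_gene, map_snps
from .datamodel import (
    DISEASES,
    read_cohort,
    read_gene_table,
    read_predictions,
    write_cohort,
    write_gene_table,
    write_predictions,
    write_summaries,
)
from .pathogenicity import VoteConfig, casting_vote, pathogenic_proportion
from .popstruct import pairwise_fst, pca_disease, heterozygosity
from .simulate import SimConfig, simulate_cohort
from .spectrum import (
    MAF_BIN_EDGES,
    allele_fractions,
    bin_spectrum,
    call_risk_alleles,
    compute_maf,
    derived_by_maf_bin,
)

_FLOAT_FMT = "%.10g"


def write_inputs(sim, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the pipeline's four standard input files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "groups": out_dir / "groups.tsv",
        "genes": out_dir / "genes.tsv",
        "predictions": out_dir / "predictions.tsv",
    }
    write_cohort(sim.cohort, sim.variants, paths["vcf"], paths["groups"])
    write_gene_table(sim.genes, paths["genes"])
    write_predictions(sim.predictions, paths["predictions"])
    return paths


def run_pipeline(
    sim_cfg: SimConfig,
    out_dir: str | Path,
    vote_cfg: VoteConfig | None = None,
    pca_components: int = 2,
) -> pd.DataFrame:
    """Run the full analysis on a freshly simulated cohort.

    Simulated inputs are written to ``out_dir/inputs`` and read back through
    the standard loaders, so the run exercises the same I/O path as an
    analysis of external data.  Returns the long-form gene x group summary
    table (also written to ``out_dir``).
    """
    vote_cfg = vote_cfg or VoteConfig()
    out_dir = Path(out_dir)
    sim = simulate_cohort(sim_cfg)
    paths = write_inputs(sim, out_dir / "inputs")

    cohort, variants = read_cohort(paths["vcf"], paths["groups"])
    genes = read_gene_table(paths["genes"])
    pred = read_predictions(paths["predictions"])
    snp_map = map_snps(cohort.snps, genes)
    calls = casting_vote(pred, vote_cfg)

    rows = []
    bin_rows = []
    for group in cohort.groups:
        mafs = compute_maf(cohort, group)
        spec = bin_spectrum(mafs)
        risk = call_risk_alleles(cohort, genes, group, snp_map)
        fracs = allele_fractions(cohort, variants, risk, group)
        by_bin = derived_by_maf_bin(fracs, spec)
        for b in range(len(by_bin)):
            bin_rows.append(
                {
                    "group": group,
                    "bin": f"({MAF_BIN_EDGES[b]:g},{MAF_BIN_EDGES[b + 1]:g}]",
                    "n_snps": int(spec.counts[b]),
                    "mean_derived_fraction": by_bin[b],
                }
            )
        agg = aggregate_gene(snp_map, mafs, cohort, group).set_index("gene")
        path_prop = pathogenic_proportion(calls, cohort, genes, group, snp_map)
        het = heterozygosity(cohort, snp_map, group).set_index("gene")
        derived_gene = (
            fracs.groupby("gene")["derived_fraction"].mean()
            if len(fracs)
            else pd.Series(dtype=float)
        )
        for gene in genes.genes:
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n_snps_mapped": int(agg.loc[gene, "L"]),
                    "pathogenic_proportion": path_prop.get(gene, np.nan),
                    "gene_maf": agg.loc[gene, "mean"],
                    "derived_proportion": derived_gene.get(gene, np.nan),
                    "combined_stat": agg.loc[gene, "combined_P"],
                    "h_obs": het.loc[gene, "h_obs"],
                    "h_exp": het.loc[gene, "h_exp"],
                }
            )
    summaries = pd.DataFrame(rows)

    metadata = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "n_groups": sim_cfg.n_groups,
        "samples_per_group": sim_cfg.samples_per_group,
        "n_snps": sim_cfg.n_snps,
        "n_genes": sim_cfg.n_genes,
        "fst": sim_cfg.fst,
        "window_bp": sim_cfg.window_bp,
        "vote_threshold": vote_cfg.threshold,
        "risk_allele_note": "minor allele defined per group; risk allele may differ between groups",
    }
    write_summaries(summaries, out_dir, metadata)
    pd.DataFrame(bin_rows).to_csv(
        out_dir / "derived_by_maf_bin.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pairwise_fst(cohort).to_csv(
        out_dir / "fst_pairs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    for disease in DISEASES:
        if not genes.genes_for_disease(disease):
            continue
        try:
            pca = pca_disease(cohort, snp_map, genes, disease, k=pca_components)
        except ValueError:
            continue  # too few polymorphic SNPs for this disease subset
        coords = pd.DataFrame(
            pca.eigenvectors, columns=[f"PC{i + 1}" for i in range(pca.eigenvectors.shape[1])]
        )
        coords.insert(0, "sample", cohort.sample_ids)
        coords.insert(1, "group", [cohort.group_of[s] for s in cohort.sample_ids])
        coords.to_csv(
            out_dir / f"pca_{disease}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        with (out_dir / f"pca_{disease}_eigenvalues.tsv").open("w") as fh:
            fh.write("component\teigenvalue\n")
            for i, ev in enumerate(pca.eigenvalues):
                fh.write(f"PC{i + 1}\t{ev:.10g}\n")
    return summaries
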