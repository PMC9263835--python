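"""Core data types and standard-format I/O.

Every downstream statistic is computed on :class:`CohortGenotypes` — a phased,
biallelic genotype matrix with a group label per sample — together with the
per-SNP :class:`VariantTable` (ancestral-allele annotation and per-group allele
counts), a :class:`PredictionMatrix` of functional-predictor status codes, and
a :class:`GeneTable` of gene regions with disease membership and odds-ratio
direction.

Coordinates are VCF-style 1-based throughout; gene intervals are 1-based
inclusive.  Chromosome labels are normalized by stripping a leading ``chr``
so that ``chr1`` and ``1`` compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ethnogene")

DISEASES = ("HIV", "TB", "malaria", "SCD", "ACG")
OR_DIRECTIONS = ("risk", "protective", "unknown")
DEFAULT_WINDOW_BP = 40_000
N_PREDICTORS = 21
BASES = ("A", "C", "G", "T")


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix so both dialects share one internal form."""
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def chrom_sort_key(chrom: str):
    """Numeric chromosomes before named ones, each in natural order."""
    c = normalize_chrom(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


class VariantKey(NamedTuple):
    """Identity of a biallelic SNV: normalized chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class CohortGenotypes:
    """Phased biallelic genotypes for a grouped cohort.

    Attributes
    ----------
    sample_ids
        Sample identifiers, in matrix row order.
    group_of
        Map sample id -> group label; every sample has exactly one label.
    haplotypes
        uint8 array of shape ``(n_samples, 2, n_snps)`` with entries in {0, 1}
        (0 = reference allele, 1 = alternate allele).  No missing data: SNPs
        with any missing genotype are dropped at load time.
    snps
        Ordered :class:`VariantKey` list, strictly increasing by
        (chromosome, position) within each chromosome.
    """

    sample_ids: list[str]
    group_of: dict[str, str]
    haplotypes: np.ndarray
    snps: list[VariantKey]
    filter_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n_samples = len(self.sample_ids)
        if self.haplotypes.shape != (n_samples, 2, len(self.snps)):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{n_samples} samples x 2 x {len(self.snps)} SNPs"
            )
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("genotype entries must be 0 or 1 (biallelic)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def sample_indices(self, group: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_of[s] == group],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"unknown or empty group: {group!r}")
        return idx

    def dosages(self, group: str | None = None) -> np.ndarray:
        """Alt-allele dosage (0/1/2) matrix, samples x SNPs."""
        h = self.haplotypes
        if group is not None:
            h = h[self.sample_indices(group)]
        return h.sum(axis=1).astype(np.int64)

    def allele_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, total allele count) within a group."""
        idx = self.sample_indices(group)
        alt = self.haplotypes[idx].sum(axis=(0, 1)).astype(np.int64)
        total = np.full(self.n_snps, 2 * idx.size, dtype=np.int64)
        return alt, total


@dataclass
class VariantTable:
    """Per-SNP annotation: ancestral allele and per-group allele counts.

    ``ancestral_allele`` holds the uppercased base from the VCF ``AA`` INFO
    tag, or ``None`` when absent/unresolvable.  A lowercase tag (low-confidence
    call) is accepted, uppercased, and flagged in ``aa_low_confidence``.
    """

    keys: list[VariantKey]
    ancestral_allele: list[str | None]
    aa_low_confidence: np.ndarray
    group_alt_counts: dict[str, np.ndarray]
    group_total_counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.aa_low_confidence = np.asarray(self.aa_low_confidence, dtype=bool)
        n = len(self.keys)
        if len(self.ancestral_allele) != n or self.aa_low_confidence.shape != (n,):
            raise ValueError("annotation arrays must match the number of SNPs")
        for g, alt in self.group_alt_counts.items():
            tot = self.group_total_counts[g]
            if np.any(alt < 0) or np.any(alt > tot):
                raise ValueError(f"alt counts outside [0, total] for group {g!r}")

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortGenotypes,
        ancestral_allele: Sequence[str | None] | None = None,
        aa_low_confidence: np.ndarray | None = None,
    ) -> "VariantTable":
        aa = list(ancestral_allele) if ancestral_allele is not None else [None] * cohort.n_snps
        lowconf = (
            np.asarray(aa_low_confidence, dtype=bool)
            if aa_low_confidence is not None
            else np.zeros(cohort.n_snps, dtype=bool)
        )
        alt_counts, total_counts = {}, {}
        for g in cohort.groups:
            alt_counts[g], total_counts[g] = cohort.allele_counts(g)
        return cls(list(cohort.snps), aa, lowconf, alt_counts, total_counts)

    @property
    def ancestral_resolved(self) -> np.ndarray:
        """True where the ancestral allele is present and equals ref or alt."""
        return np.array(
            [
                a is not None and a in (k.ref, k.alt)
                for a, k in zip(self.ancestral_allele, self.keys)
            ],
            dtype=bool,
        )

    def ancestral_is_ref(self) -> np.ndarray:
        """True where ancestral == ref; only meaningful where resolved."""
        return np.array(
            [a == k.ref for a, k in zip(self.ancestral_allele, self.keys)], dtype=bool
        )


@dataclass
class PredictionMatrix:
    """Status codes from 21 functional predictors plus candidate-set flags.

    A status is damaging iff it is ``D`` (deleterious / probably damaging /
    disease-causing) or ``A`` (disease-causing-automatic); anything else,
    including the explicit missing marker ``.``, is non-damaging.
    """

    keys: list[VariantKey]
    statuses: np.ndarray  # (n_snps, n_predictors) of single characters
    is_rare: np.ndarray
    is_exonic: np.ndarray
    is_nonsynonymous: np.ndarray

    def __post_init__(self) -> None:
        self.statuses = np.asarray(self.statuses, dtype="<U1")
        n = len(self.keys)
        if self.statuses.ndim != 2 or self.statuses.shape[0] != n:
            raise ValueError("statuses must be a 2-D matrix with one row per SNP")
        for name in ("is_rare", "is_exonic", "is_nonsynonymous"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per SNP")

    @property
    def n_predictors(self) -> int:
        return self.statuses.shape[1]


@dataclass
class GeneTable:
    """Gene regions with disease membership and odds-ratio direction.

    ``df`` columns: gene, chrom (normalized), start, end (1-based inclusive),
    diseases (frozenset), or_direction, window_bp.  The aggregation window of
    a gene is ``[start - window_bp, end + window_bp]`` clipped at 1.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end", "diseases", "or_direction", "window_bp"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene"].duplicated().any():
            dups = self.df.loc[self.df["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate gene names: {dups}")
        bad = self.df["start"] > self.df["end"]
        if bad.any():
            raise ValueError(
                f"start > end for gene(s): {self.df.loc[bad, 'gene'].tolist()}"
            )
        if (self.df["window_bp"] < 0).any():
            raise ValueError("window_bp must be >= 0")
        unknown_dir = ~self.df["or_direction"].isin(OR_DIRECTIONS)
        if unknown_dir.any():
            raise ValueError(
                f"invalid or_direction for gene(s): {self.df.loc[unknown_dir, 'gene'].tolist()}"
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return self.df["gene"].tolist()

    def windows(self) -> pd.DataFrame:
        """Per-gene aggregation window [wstart, wend], clipped at 1."""
        w = self.df.copy()
        w["wstart"] = np.maximum(1, w["start"] - w["window_bp"])
        w["wend"] = w["end"] + w["window_bp"]
        return w

    def genes_for_disease(self, disease: str) -> list[str]:
        return [g for g, d in zip(self.df["gene"], self.df["diseases"]) if disease in d]


# ---------------------------------------------------------------------------
# VCF + table reading
# ---------------------------------------------------------------------------

def _parse_aa(raw, ref: str, alt: str, where: str) -> tuple[str | None, bool]:
    """Parse an AA INFO value -> (uppercased base or None, low-confidence flag)."""
    if raw is None:
        return None, False
    aa = str(raw).strip()
    lowconf = aa.islower()
    aa = aa.upper()
    if len(aa) != 1 or aa not in BASES:
        logger.warning("malformed AA tag %r at %s; SNP flagged ancestral-unresolved", raw, where)
        return None, False
    if aa not in (ref, alt):
        # present but matching neither allele: unresolved for fraction purposes,
        # kept verbatim so round-trips preserve it
        return aa, lowconf
    return aa, lowconf


def read_groups(path: str | Path) -> dict[str, str]:
    """Read the 2-column (sample_id, group) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    return dict(zip(df["sample_id"], df["group"]))


def read_cohort(vcf_path: str | Path, groups_path: str | Path):
    """Load a phased VCF plus group map into (CohortGenotypes, VariantTable).

    Only biallelic SNVs are retained; indels and multi-allelic records are
    dropped and counted.  A SNP with any missing genotype is dropped
    (``dropped_missing_gt``), keeping downstream arithmetic total.  The AA
    INFO tag, when parseable as a single base, becomes the ancestral allele.
    Counts are logged and attached as ``cohort.filter_counts``.
    """
    from cyvcf2 import VCF

    group_of = read_groups(groups_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in group_of]
    if unmapped:
        raise ValueError(f"VCF samples missing from group map: {unmapped[:5]}")

    keys: list[VariantKey] = []
    aa_list: list[str | None] = []
    lowconf_list: list[bool] = []
    hap_cols: list[np.ndarray] = []
    counts = {"input": 0, "retained": 0, "dropped_indel_multiallelic": 0, "dropped_missing_gt": 0}

    for v in vcf:
        counts["input"] += 1
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1 or v.REF == alts[0]:
            counts["dropped_indel_multiallelic"] += 1
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        if (gts < 0).any():
            counts["dropped_missing_gt"] += 1
            continue
        key = VariantKey(normalize_chrom(v.CHROM), int(v.POS), v.REF, alts[0])
        aa, lowconf = _parse_aa(v.INFO.get("AA"), key.ref, key.alt, f"{v.CHROM}:{v.POS}")
        keys.append(key)
        aa_list.append(aa)
        lowconf_list.append(lowconf)
        hap_cols.append(gts.astype(np.uint8))
    counts["retained"] = len(keys)
    logger.info(
        "read_cohort: %(input)d records, %(retained)d retained, "
        "%(dropped_indel_multiallelic)d indel/multiallelic dropped, "
        "%(dropped_missing_gt)d with missing GT dropped",
        counts,
    )

    order = sorted(
        range(len(keys)), key=lambda i: (chrom_sort_key(keys[i].chrom), keys[i].pos)
    )
    keys = [keys[i] for i in order]
    aa_list = [aa_list[i] for i in order]
    lowconf = np.array([lowconf_list[i] for i in order], dtype=bool)
    if hap_cols:
        haps = np.stack([hap_cols[i] for i in order], axis=2)  # (samples, 2, snps)
    else:
        haps = np.zeros((len(samples), 2, 0), dtype=np.uint8)

    cohort = CohortGenotypes(samples, group_of, haps, keys, filter_counts=counts)
    variants = VariantTable.from_cohort(cohort, aa_list, lowconf)
    return cohort, variants


def write_cohort(
    cohort: CohortGenotypes,
    variants: VariantTable | None,
    vcf_path: str | Path,
    groups_path: str | Path | None = None,
) -> None:
    """Write the cohort back out as a phased VCF (plus optional groups TSV).

    Low-confidence ancestral alleles are written lowercase, restoring the
    convention they were read with, so write-then-read round-trips exactly.
    """
    vcf_path = Path(vcf_path)
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral Allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(k.chrom for k in cohort.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        haps = cohort.haplotypes
        for j, key in enumerate(cohort.snps):
            if variants is not None and variants.ancestral_allele[j] is not None:
                aa = variants.ancestral_allele[j]
                if variants.aa_low_confidence[j]:
                    aa = aa.lower()
                info = f"AA={aa}"
            else:
                info = "."
            gts = "\t".join(f"{haps[i, 0, j]}|{haps[i, 1, j]}" for i in range(cohort.n_samples))
            fh.write(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t{info}\tGT\t{gts}\n")
    if groups_path is not None:
        with Path(groups_path).open("w") as fh:
            for s in cohort.sample_ids:
                fh.write(f"{s}\t{cohort.group_of[s]}\n")


def read_gene_table(path: str | Path, default_window_bp: int = DEFAULT_WINDOW_BP) -> GeneTable:
    """Read the TSV of gene regions (gene, chrom, start, end, diseases, or_direction[, window_bp])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["diseases"] = [
        frozenset(x for x in str(d).split(",") if x and x != "nan") for d in df["diseases"]
    ]
    if "window_bp" not in df.columns:
        df["window_bp"] = default_window_bp
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["window_bp"] = df["window_bp"].astype(np.int64)
    return GeneTable(df)


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    out = genes.df.copy()
    out["diseases"] = [",".join(sorted(d)) for d in out["diseases"]]
    out.to_csv(path, sep="\t", index=False)


_PRED_COLS = [f"pred{i + 1:02d}" for i in range(N_PREDICTORS)]
_FLAG_COLS = ["is_rare", "is_exonic", "is_nonsynonymous"]


def read_predictions(path: str | Path) -> PredictionMatrix:
    """Read the per-SNP predictor-status TSV (21 single-character columns plus flags)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PRED_COLS + _FLAG_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    keys = [
        VariantKey(normalize_chrom(c), int(p), r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    statuses = df[_PRED_COLS].astype(str).to_numpy(dtype="<U1")
    return PredictionMatrix(
        keys,
        statuses,
        df["is_rare"].astype(bool).to_numpy(),
        df["is_exonic"].astype(bool).to_numpy(),
        df["is_nonsynonymous"].astype(bool).to_numpy(),
    )


def write_predictions(pred: PredictionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [k.chrom for k in pred.keys],
            "pos": [k.pos for k in pred.keys],
            "ref": [k.ref for k in pred.keys],
            "alt": [k.alt for k in pred.keys],
        }
    )
    for i, col in enumerate(_PRED_COLS):
        df[col] = pred.statuses[:, i]
    df["is_rare"] = pred.is_rare.astype(int)
    df["is_exonic"] = pred.is_exonic.astype(int)
    df["is_nonsynonymous"] = pred.is_nonsynonymous.astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summary output
# ---------------------------------------------------------------------------

SUMMARY_STATS = (
    "n_snps_mapped",
    "pathogenic_proportion",
    "gene_maf",
    "derived_proportion",
    "combined_stat",
    "h_obs",
    "h_exp",
)


def _fmt(x) -> str:
    if pd.isna(x):
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".10g")


def write_summaries(
    summaries: pd.DataFrame,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> list[Path]:
    """Write one genes x groups TSV per statistic, plus a run-metadata file.

    ``summaries`` is long-form with columns ``gene``, ``group`` and any subset
    of :data:`SUMMARY_STATS`.  Rows and columns are emitted in sorted order so
    identical inputs give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    genes = sorted(summaries["gene"].unique()) if len(summaries) else []
    groups = sorted(summaries["group"].unique()) if len(summaries) else []
    for stat in SUMMARY_STATS:
        if stat not in summaries.columns:
            continue
        path = out_dir / f"{stat}.tsv"
        if genes:
            wide = summaries.pivot(index="gene", columns="group", values=stat)
            wide = wide.reindex(index=genes, columns=groups)
        else:
            wide = pd.DataFrame(index=pd.Index([], name="gene"))
        with path.open("w") as fh:
            fh.write("gene\t" + "\t".join(groups) + "\n")
            for g in genes:
                fh.write(g + "\t" + "\t".join(_fmt(v) for v in wide.loc[g]) + "\n")
        written.append(path)
    meta_path = out_dir / "run_metadata.yaml"
    with meta_path.open("w") as fh:
        yaml.safe_dump(dict(sorted((metadata or {}).items())), fh, sort_keys=True)
    written.append(meta_path)
    return written
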