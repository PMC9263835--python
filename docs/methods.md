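# Methods

## Scope and data model

The package analyses a phased, biallelic SNV cohort stratified into G group
labels (ethnolinguistic, ancestry, or any other sample partition). All
statistics operate on alt-allele indicators per haplotype; phase is read and
preserved for reproducibility but no implemented statistic depends on it.
Coordinates are VCF 1-based; gene intervals 1-based inclusive; chromosome
labels `chr1` and `1` are normalized to `1`. On load, indels and
multi-allelic records are dropped, and any SNP with a missing genotype is
dropped entirely (counts logged and attached to the cohort), so downstream
arithmetic never handles missingness. The ancestral allele comes from the
`AA` INFO tag; a lowercase tag (the low-confidence convention of
multi-species alignments) is uppercased and flagged; a tag that is not a
single A/C/G/T base leaves the SNP ancestral-unresolved, and unresolved SNPs
are excluded from ancestral/derived computations with a logged count.

## Consensus pathogenicity (casting vote)

Each SNP carries 21 single-character predictor statuses; damaging is
`D` or `A`, everything else — including an explicit missing marker — counts
as a non-damaging vote, keeping totals comparable across SNPs. A variant is
pathogenic when `votes ≥ threshold` (default 17) **and** the rare, exonic and
nonsynonymous flags hold; both conditions are conjunctive, so vote-then-flag
and flag-then-vote orders give identical results. The per-gene burden in a
group divides pathogenic mapped SNPs by *segregating* mapped SNPs
(0 < alt count < total); monomorphic sites say nothing about a group's
burden, and a gene with no segregating mapped SNPs reports null, not zero.

## Allele spectra

MAF is computed as `min(alt, total − alt) / total` — minimum on integer
counts, one division — so the value is exact to one rounding and invariant
under ref/alt relabeling (taking `min(f, 1 − f)` in floats can flip a
boundary SNP across a bin edge). Bins are lower-exclusive/upper-inclusive,
`(0, 0.05], (0.05, 0.1], (0.1, 0.2], (0.2, 0.3], (0.3, 0.4], (0.4, 0.5]`;
maf = 0 is excluded and counted separately, so monomorphic + binned = total.

Risk alleles follow the odds-ratio direction of the gene a SNP maps to:
OR > 1 → the group's minor allele, OR < 1 → the major allele, unknown → no
call. The minor allele is defined *per group*, so the same SNP can have
different risk alleles in different groups; a tie at f = 0.5 deterministically
deems alt the minor allele. SNPs mapped to genes with conflicting directions
get one call per gene, never merged.

The ancestral fraction of a SNP divides the risk-allele copies that match the
ancestral allele by the group's alternate-allele copies; derived = 1 −
ancestral exactly. Matches are counted among alternate-allele copies, so
when the risk allele and ancestral allele are both the reference allele the
fraction is 0 by construction; this count-based definition is deliberately
kept (it guarantees the complement identity and the [0, 1] range) and such
rows carry a `qc_ref_risk_ancestral` flag. An alternative denominator —
matched risk-allele copies over total allele copies — is available as
`denominator="risk-over-total"` for sensitivity analysis. Zero-denominator
SNPs report null.

## Gene-level aggregation

SNPs map to a gene when their position lies in
`[start − window_bp, end + window_bp]` (default 40 000 bp each side, clipped
at 1, boundaries inclusive). Gene-level means are unweighted. The combined
statistic is Stouffer–Liptak: values clamped to `[1e−15, 1 − 1e−15]`,
`q_k = Φ⁻¹(P_k)`, `Z = Σ q_k / √(1ᵀΣ1)`, `P = Φ(Z)`, with Σ the Pearson
correlation of alt dosages between the gene's SNPs in the group. Small
inputs give small combined values (Φ⁻¹ applied to the values directly).
Σ is symmetrized and eigenvalue-clipped at zero; monomorphic SNPs contribute
unit diagonal and zero off-diagonals; groups with fewer than 3 samples fall
back to the identity correlation (with a warning), since a 2-sample Pearson
estimate is degenerate. With Σ = I the statistic reduces to the classical
Stouffer combination `Φ(Σq/√L)`, which the tests verify to 1e−12, and under
i.i.d. uniform inputs the combined value is itself uniform (checked by a
Kolmogorov–Smirnov test on 10 000 simulated genes). A `literal=True` mode
computes the naive `Φ(mean(P_k))` for comparison output only — that
arithmetic is not a calibrated combination and the pipeline never uses it.

## Population structure and diversity

PCA runs on the dosage matrix restricted to the SNPs of one disease's genes,
monomorphic SNPs dropped, each column centered by its mean and scaled by
`√(p̂(1−p̂))` with `p̂ = (1 + alt count)/(2 + total count)` — the
pseudocounted frequency smartpca uses, so results are comparable to
EIGENSOFT-based analyses. Components come from the SVD of the normalized
matrix (equivalently the eigendecomposition of the sample covariance); each
eigenvector's largest-magnitude entry is made positive for determinism.

Fst uses Hudson's estimator as a ratio of averages,

    num_k = (p_a − p_b)² − p_a(1−p_a)/(n_a−1) − p_b(1−p_b)/(n_b−1)
    den_k = p_a(1−p_b) + p_b(1−p_a),      Fst = Σ num_k / Σ den_k

with n the allele counts. Hudson is chosen because it is the standard
recommendation when sample sizes differ across groups, which is the norm for
ethnolinguistic cohorts; it is unbiased under the Balding–Nichols model and
can be slightly negative when true differentiation is nil.

Heterozygosity: per SNP, `h_obs` is the fraction of heterozygous samples and
`h_exp = 2p(1−p)`; per gene, unweighted means over mapped SNPs. Gene-level
tables are emitted (per-SNP values are available through
`snp_heterozygosity`).

## Synthetic cohort generator

The generator emulates exactly the structure the estimators assume:

* **Differentiation.** Ancestral frequency `p ~ Beta(2, 2)` per SNP (clipped
  to [1e−4, 1−1e−4]), group frequencies
  `p_g ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`. Beta(2, 2) keeps frequencies away
  from fixation so every stage sees segregating sites; the Balding–Nichols F
  is the quantity Hudson Fst estimates, which the acceptance run verifies at
  F ∈ {0.05, 0.1, 0.2} within ±0.02.
* **Genotypes.** Haplotype alleles Bernoulli(p_g), independent across sites
  and haplotypes — Hardy–Weinberg within groups, no linkage disequilibrium
  along the chromosome and no admixture. Consequently the LD correction in
  the gene combination is exercised mostly near identity on simulated data;
  the correlated path is validated against a Monte-Carlo oracle instead.
* **Ancestral labels.** The ancestral allele is the reference allele for 80%
  of SNPs (derived alleles are predominantly the alternate/minor allele, as
  in real cohorts), with a 10% low-confidence (lowercase) rate to exercise
  the parsing path.
* **Genes.** `n_genes` genes of 20 kb tile one chromosome with a stride
  exceeding gene length + 2 windows, so aggregation windows are disjoint by
  default; `overlap_genes=True` shrinks the stride to test multi-membership.
  Disease labels cycle through HIV, TB, malaria, SCD, ACG and odds-ratio
  directions through risk/protective/unknown, deterministically.
* **Predictors.** A latent pathogenic state (default rate 0.1) drives 21
  independent predictor calls with sensitivity and specificity 0.9. Real
  predictor scores are correlated; independence is a conservative
  simplification that makes the 17/21 vote *harder* to pass by chance
  (P(Bin(21, 0.1) ≥ 17) ≈ 1e−13). The rare/exonic/nonsynonymous flags
  default to rate 1.0, emulating a matrix already restricted to the
  candidate exonic set; the rates are configurable and independent of the
  latent state.

Everything derives from one `numpy` Generator seeded by `SimConfig.seed`;
identical configs give byte-identical pipeline output, which the end-to-end
test checks file by file.

What passing tests on this generator do **not** show: behaviour under real
LD, under correlated predictors, under genotype missingness, or under
admixed/cline structure — the generator draws exchangeable samples within
discrete groups.

## Numerical choices and degenerate inputs

* Stouffer clamp ε = 1e−15 keeps Φ⁻¹ finite at 0/1 inputs.
* Empty gene windows, monomorphic genes, groups absent from a chromosome,
  and empty summary collections all produce nulls/empty outputs, never
  silent zeros.
* Output floats are formatted with `%.10g` and rows/columns sorted, so
  re-runs are byte-identical; NaN prints as `NA`.
* Problem sizes in the test and acceptance runs (≤ 5000 SNPs, ≤ 400
  diploids, 10⁶ Monte-Carlo draws) were chosen so each statistical check has
  standard errors several times smaller than its tolerance.

## Known limitations

* No coalescent simulation: sites are independent given group frequencies.
* The ancestral-fraction definition is count-based by design; analyses where
  the risk allele is frequently the reference allele should use the
  `risk-over-total` denominator and the QC flag.
* PCA offers no projection of new samples, and no ADMIXTURE-style model is
  fitted.
* Eagle-style phasing, variant calling, and predictor execution are out of
  scope: the VCF is assumed phased and QC'd, and predictor statuses are
  inputs.
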