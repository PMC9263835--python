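"""MAF computation, six-bin spectrum, risk-allele rule, allele fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ethnogene import (
    GeneTable,
    SimConfig,
    allele_fractions,
    bin_spectrum,
    call_risk_alleles,
    compute_maf,
    derived_by_maf_bin,
    map_snps,
    simulate_cohort,
)
from ethnogene.datamodel import CohortGenotypes, VariantKey, VariantTable
from ethnogene.spectrum import MAF_BIN_EDGES, RULE_NONE, RULE_PROTECTIVE, RULE_RISK
from tests.conftest import build_cohort


class TestComputeMaf:
    def test_three_of_ten_alt_alleles(self, five_diploids):
        assert compute_maf(five_diploids, "G1")[0] == pytest.approx(0.3)

    def test_all_homozygous_ref_is_zero(self):
        cohort = build_cohort(np.zeros((4, 2, 2), dtype=np.uint8))
        assert compute_maf(cohort, "G1").tolist() == [0.0, 0.0]

    def test_folding_above_half(self):
        haps = np.ones((5, 2, 1), dtype=np.uint8)
        haps[0, 0, 0] = 0  # f_alt = 0.9
        assert compute_maf(build_cohort(haps), "G1")[0] == pytest.approx(0.1)

    def test_empty_group_is_error(self, five_diploids):
        with pytest.raises(KeyError):
            compute_maf(five_diploids, "missing-group")

    def test_matches_independent_recount(self, small_sim):
        """500-SNP-scale fixture: maf equals a direct allele recount."""
        cohort = small_sim.cohort
        for group in cohort.groups:
            idx = [i for i, s in enumerate(cohort.sample_ids) if cohort.group_of[s] == group]
            expected = []
            for j in range(cohort.n_snps):
                alt = sum(int(cohort.haplotypes[i, h, j]) for i in idx for h in (0, 1))
                f = alt / (2 * len(idx))
                expected.append(min(f, 1 - f))
            np.testing.assert_allclose(compute_maf(cohort, group), expected, rtol=0, atol=1e-15)


class TestBinSpectrum:
    def test_boundary_falls_in_lower_bin(self):
        spec = bin_spectrum(np.array([0.05, 0.051]))
        assert spec.bin_index.tolist() == [0, 1]

    @pytest.mark.parametrize("edge,expected_bin", [(0.1, 1), (0.2, 2), (0.3, 3), (0.4, 4), (0.5, 5)])
    def test_every_upper_edge_inclusive(self, edge, expected_bin):
        assert bin_spectrum(np.array([edge])).bin_index[0] == expected_bin

    def test_all_monomorphic(self):
        spec = bin_spectrum(np.zeros(7))
        assert spec.counts.sum() == 0 and spec.monomorphic_count == 7

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bin_spectrum(np.array([0.6]))

    def test_counts_equal_brute_force_histogram(self):
        """1000 random MAFs: counts equal a per-value scan with the
        lower-exclusive/upper-inclusive boundary convention."""
        rng = np.random.default_rng(21)
        mafs = np.round(rng.random(1000) * 0.5, 4)
        spec = bin_spectrum(mafs)
        brute = [0] * 6
        mono = 0
        for m in mafs:
            if m == 0:
                mono += 1
                continue
            for b in range(6):
                if MAF_BIN_EDGES[b] < m <= MAF_BIN_EDGES[b + 1]:
                    brute[b] += 1
                    break
        assert spec.counts.tolist() == brute
        assert spec.monomorphic_count == mono

    @given(st.lists(st.floats(0, 0.5), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_totals_invariant(self, mafs):
        """monomorphic + sum of bin counts = number of SNPs, always."""
        spec = bin_spectrum(np.array(mafs))
        assert spec.monomorphic_count + spec.counts.sum() == len(mafs)
        if spec.counts.sum():
            assert spec.proportions.sum() == pytest.approx(1.0)


def one_gene(or_direction, window_bp=10_000):
    return GeneTable(pd.DataFrame([{
        "gene": "GX", "chrom": "1", "start": 1, "end": 5000,
        "diseases": frozenset({"TB"}), "or_direction": or_direction,
        "window_bp": window_bp,
    }]))


class TestRiskAlleles:
    def cohort_with_falt(self, f_alt):
        """10 diploids, one SNP, the requested alt frequency."""
        haps = np.zeros((10, 2, 1), dtype=np.uint8)
        haps.reshape(-1, 1)[: int(f_alt * 20), 0] = 1
        return build_cohort(haps)

    def test_or_gt1_risk_is_minor_alt(self):
        calls = call_risk_alleles(self.cohort_with_falt(0.2), one_gene("risk"), "G1")
        assert calls.loc[0, "risk_allele"] == "G" and calls.loc[0, "rule_used"] == RULE_RISK

    def test_or_lt1_risk_is_major_ref(self):
        calls = call_risk_alleles(self.cohort_with_falt(0.2), one_gene("protective"), "G1")
        assert calls.loc[0, "risk_allele"] == "A" and calls.loc[0, "rule_used"] == RULE_PROTECTIVE

    def test_unknown_direction_no_call(self):
        calls = call_risk_alleles(self.cohort_with_falt(0.2), one_gene("unknown"), "G1")
        assert calls.loc[0, "risk_allele"] is None and calls.loc[0, "rule_used"] == RULE_NONE

    def test_half_frequency_tie_alt_is_minor(self):
        calls = call_risk_alleles(self.cohort_with_falt(0.5), one_gene("risk"), "G1")
        assert calls.loc[0, "risk_allele"] == "G"

    def test_matches_brute_force_rule(self):
        """Simulated fixture with mixed OR directions: calls equal a direct
        re-application of the minor/major rule."""
        sim = simulate_cohort(SimConfig(n_groups=2, samples_per_group=25, n_snps=200,
                                        n_genes=6, seed=17))
        group = "G02"
        snp_map = map_snps(sim.cohort.snps, sim.genes)
        calls = call_risk_alleles(sim.cohort, sim.genes, group, snp_map)
        alt, total = sim.cohort.allele_counts(group)
        directions = dict(zip(sim.genes.df["gene"], sim.genes.df["or_direction"]))
        for row in calls.itertuples(index=False):
            f = alt[row.snp_idx] / total[row.snp_idx]
            minor = row.alt if f <= 0.5 else row.ref
            major = row.ref if f <= 0.5 else row.alt
            d = directions[row.gene]
            expected = minor if d == "risk" else major if d == "protective" else None
            assert row.risk_allele == expected


class TestAlleleFractions:
    def with_aa(self, cohort, aa):
        return VariantTable.from_cohort(cohort, aa)

    def test_risk_matches_ancestral_alt(self):
        haps = np.zeros((5, 2, 1), dtype=np.uint8)
        haps[:4, :, 0] = 1  # f_alt = 0.8 -> minor is ref; protective -> risk = alt
        cohort = build_cohort(haps)
        variants = self.with_aa(cohort, ["G"])  # ancestral = alt
        risk = call_risk_alleles(cohort, one_gene("protective"), "G1")
        fr = allele_fractions(cohort, variants, risk, "G1")
        assert fr.loc[0, "ancestral_fraction"] == 1.0
        assert fr.loc[0, "derived_fraction"] == 0.0

    def test_risk_differs_from_ancestral(self):
        haps = np.zeros((5, 2, 1), dtype=np.uint8)
        haps[0, 0, 0] = 1  # f_alt = 0.1 -> minor is alt; risk gene -> risk = alt
        cohort = build_cohort(haps)
        variants = self.with_aa(cohort, ["A"])  # ancestral = ref
        fr = allele_fractions(cohort, variants,
                              call_risk_alleles(cohort, one_gene("risk"), "G1"), "G1")
        assert fr.loc[0, "ancestral_fraction"] == 0.0
        assert fr.loc[0, "derived_fraction"] == 1.0

    def test_ref_risk_ancestral_anomaly_flagged(self):
        """risk = ancestral = ref: literal fraction is 0 and QC-flagged."""
        haps = np.zeros((5, 2, 1), dtype=np.uint8)
        haps[0, 0, 0] = 1  # minor is alt; protective -> risk = ref
        cohort = build_cohort(haps)
        variants = self.with_aa(cohort, ["A"])
        fr = allele_fractions(cohort, variants,
                              call_risk_alleles(cohort, one_gene("protective"), "G1"), "G1")
        assert fr.loc[0, "ancestral_fraction"] == 0.0
        assert bool(fr.loc[0, "qc_ref_risk_ancestral"])

    def test_alternative_denominator(self):
        haps = np.zeros((5, 2, 1), dtype=np.uint8)
        haps[0, 0, 0] = 1  # protective -> risk = ref = ancestral; 9 ref copies of 10
        cohort = build_cohort(haps)
        variants = self.with_aa(cohort, ["A"])
        fr = allele_fractions(cohort, variants,
                              call_risk_alleles(cohort, one_gene("protective"), "G1"), "G1",
                              denominator="risk-over-total")
        assert fr.loc[0, "ancestral_fraction"] == pytest.approx(0.9)

    def test_zero_denominator_is_null(self):
        cohort = build_cohort(np.zeros((5, 2, 1), dtype=np.uint8))  # monomorphic ref
        variants = self.with_aa(cohort, ["A"])
        fr = allele_fractions(cohort, variants,
                              call_risk_alleles(cohort, one_gene("risk"), "G1"), "G1")
        assert np.isnan(fr.loc[0, "ancestral_fraction"])

    def test_unresolved_snps_excluded(self):
        haps = np.zeros((5, 2, 2), dtype=np.uint8)
        haps[0, 0, :] = 1
        cohort = build_cohort(haps)
        variants = self.with_aa(cohort, ["A", None])
        fr = allele_fractions(cohort, variants,
                              call_risk_alleles(cohort, one_gene("risk"), "G1"), "G1")
        assert len(fr) == 1 and fr.loc[0, "snp_idx"] == 0

    def test_fractions_sum_to_one_exactly_and_match_recount(self, small_sim):
        """Simulated fixture: complement identity exact; values equal an
        independent plain-Python recount of the count-based definition."""
        cohort, variants, genes = small_sim.cohort, small_sim.variants, small_sim.genes
        group = "G01"
        risk = call_risk_alleles(cohort, genes, group)
        fr = allele_fractions(cohort, variants, risk, group)
        finite = fr["ancestral_fraction"].notna()
        assert ((fr.loc[finite, "ancestral_fraction"] + fr.loc[finite, "derived_fraction"]) == 1.0).all()
        alt, total = cohort.allele_counts(group)
        for row in fr.itertuples(index=False):
            i = row.snp_idx
            anc = variants.ancestral_allele[i]
            k = cohort.snps[i]
            num = alt[i] if (row.risk_allele == anc == k.alt) else 0
            expected = num / alt[i] if alt[i] > 0 else np.nan
            if np.isnan(expected):
                assert np.isnan(row.ancestral_fraction)
            else:
                assert row.ancestral_fraction == expected


class TestDerivedByBin:
    def test_mean_of_zero_and_one_is_half(self):
        spec = bin_spectrum(np.array([0.03, 0.04]))
        fracs = pd.DataFrame({"snp_idx": [0, 1], "derived_fraction": [0.0, 1.0]})
        out = derived_by_maf_bin(fracs, spec)
        assert out[0] == pytest.approx(0.5) and np.isnan(out[1:]).all()

    def test_all_derived_gives_one_everywhere(self):
        spec = bin_spectrum(np.array([0.03, 0.15, 0.45]))
        fracs = pd.DataFrame({"snp_idx": [0, 1, 2], "derived_fraction": [1.0, 1.0, 1.0]})
        out = derived_by_maf_bin(fracs, spec)
        for b in (0, 2, 5):
            assert out[b] == 1.0

    def test_mismatched_snp_sets_error(self):
        spec = bin_spectrum(np.array([0.1]))
        fracs = pd.DataFrame({"snp_idx": [5], "derived_fraction": [1.0]})
        with pytest.raises(ValueError, match="different SNP sets"):
            derived_by_maf_bin(fracs, spec)

    def test_matches_oracle_when_ancestral_is_ref(self):
        """With ancestral=ref everywhere, a risk-gene SNP's derived fraction is
        1 whenever it segregates; bin means recomputed directly agree."""
        sim = simulate_cohort(SimConfig(n_groups=1, samples_per_group=40, n_snps=400,
                                        n_genes=4, frac_aa_ref=1.0, seed=23))
        group = "G01"
        risk = call_risk_alleles(sim.cohort, sim.genes, group)
        fr = allele_fractions(sim.cohort, sim.variants, risk, group)
        spec = bin_spectrum(compute_maf(sim.cohort, group))
        out = derived_by_maf_bin(fr, spec)
        bins = spec.bin_index[fr["snp_idx"].to_numpy()]
        derived = fr["derived_fraction"].to_numpy()
        for b in range(6):
            sel = (bins == b) & np.isfinite(derived)
            if sel.any():
                assert out[b] == pytest.approx(derived[sel].mean())
            else:
                assert np.isnan(out[b])


class TestInvariances:
    def test_allele_swap_leaves_maf_and_bins_unchanged(self, small_sim):
        """Exchanging ref/alt labels and complementing genotypes is a pure
        relabeling: maf and the spectrum are invariant."""
        cohort = small_sim.cohort
        swapped = CohortGenotypes(
            cohort.sample_ids,
            cohort.group_of,
            1 - cohort.haplotypes,
            [VariantKey(k.chrom, k.pos, k.alt, k.ref) for k in cohort.snps],
        )
        for group in cohort.groups:
            a, b = compute_maf(cohort, group), compute_maf(swapped, group)
            np.testing.assert_allclose(a, b, atol=1e-15)
            assert bin_spectrum(a).counts.tolist() == bin_spectrum(b).counts.tolist()

    def test_within_group_sample_permutation_invariant(self, small_sim):
        cohort = small_sim.cohort
        rng = np.random.default_rng(3)
        order = rng.permutation(cohort.n_samples)
        shuffled = CohortGenotypes(
            [cohort.sample_ids[i] for i in order],
            cohort.group_of,
            cohort.haplotypes[order],
            cohort.snps,
        )
        np.testing.assert_allclose(
            compute_maf(cohort, "G01"), compute_maf(shuffled, "G01"), atol=1e-15
        )
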