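"""Generator behaviour: determinism, construction guarantees, signal model."""

import numpy as np
import pandas as pd
import pytest

from dasescan import (SimConfig, generate_annotation, plant_effects,
                      simulate_cohort, simulate_genotypes,
                      simulate_intensities, simulate_sanger_peaks)
from dasescan.io import write_export

from conftest import zero_noise_config


class TestAnnotation:
    def test_construction_guarantees(self):
        ann = generate_annotation(SimConfig(n_snps=1000, n_genes=200, seed=1))
        assert len(ann) == 1000
        assert ann["snp_id"].is_unique
        assert (ann["chromosome"] == "Y").sum() >= 1
        assert ann["is_cnv_marker"].sum() >= 1
        # transcribed SNPs carry a gene; every gene has >=1 SNP and the
        # extra budget gives some genes >=3 so aggregation is exercised
        trans = ann[ann["is_transcribed"]]
        assert (trans["gene_id"] != "").all()
        per_gene = trans.groupby("gene_id").size()
        assert len(per_gene) == 200
        assert (per_gene >= 3).any()

    def test_deterministic_per_seed(self):
        cfg = SimConfig(n_snps=1000, n_genes=200, seed=1)
        pd.testing.assert_frame_equal(generate_annotation(cfg),
                                      generate_annotation(cfg))
        other = generate_annotation(SimConfig(n_snps=1000, n_genes=200, seed=2))
        assert not generate_annotation(cfg).equals(other)

    def test_zero_cnv_rate(self):
        ann = generate_annotation(
            SimConfig(n_snps=10, n_genes=2, fraction_cnv=0.0, seed=1))
        assert ann["is_cnv_marker"].sum() == 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_snps=0)
        with pytest.raises(ValueError):
            SimConfig(n_snps=10, n_genes=20)
        with pytest.raises(ValueError):
            # not enough transcribed SNPs to cover the genes
            generate_annotation(
                SimConfig(n_snps=10, n_genes=5, fraction_transcribed=0.1))


class TestGenotypes:
    def test_heterozygosity_matches_binomial_oracle(self):
        cfg = SimConfig(n_snps=10_000, n_genes=1000, maf_range=(0.5, 0.5),
                        fraction_transcribed=1.0, seed=4)
        ann = generate_annotation(cfg)
        geno = simulate_genotypes(ann, cfg)
        het = (geno == "AB").to_numpy().mean()
        n = geno.size
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * se

    def test_degenerate_maf_gives_all_reference_homozygotes(self):
        cfg = SimConfig(n_snps=50, n_genes=10, maf_range=(0.0, 0.0), seed=1)
        ann = generate_annotation(cfg)
        geno = simulate_genotypes(ann, cfg)
        assert (geno == "AA").all().all()

    def test_deterministic_and_y_fixed(self):
        cfg = SimConfig(n_snps=500, n_genes=50, seed=7)
        ann = generate_annotation(cfg)
        g1, g2 = simulate_genotypes(ann, cfg), simulate_genotypes(ann, cfg)
        pd.testing.assert_frame_equal(g1, g2)
        y_snps = ann.loc[ann["chromosome"] == "Y", "snp_id"]
        assert (g1.loc[y_snps] == "AA").all().all()


class TestPlantEffects:
    def test_zero_fraction_all_null(self):
        cfg = SimConfig(n_snps=200, n_genes=40, fraction_dase=0.0, seed=1)
        eff = plant_effects(generate_annotation(cfg), cfg)
        assert (eff["log2fc"] == 0).all()

    def test_degenerate_range_full_fraction(self):
        cfg = SimConfig(n_snps=200, n_genes=40, fraction_dase=1.0,
                        effect_log2fc_range=(2.0, 2.0), seed=1)
        ann = generate_annotation(cfg)
        eff = plant_effects(ann, cfg)
        eligible = (ann["is_transcribed"] & ~ann["is_cnv_marker"]
                    & (ann["chromosome"] != "Y")).to_numpy()
        assert (eff.loc[eligible, "log2fc"] == 2.0).all()
        assert (eff.loc[~eligible, "log2fc"] == 0.0).all()

    def test_exact_affected_count_by_enumeration(self):
        cfg = SimConfig(n_snps=2000, n_genes=300, fraction_dase=0.1, seed=5)
        ann = generate_annotation(cfg)
        eff = plant_effects(ann, cfg)
        eligible = (ann["is_transcribed"] & ~ann["is_cnv_marker"]
                    & (ann["chromosome"] != "Y")).sum()
        assert (eff["log2fc"] > 0).sum() == round(0.1 * eligible)

    def test_effects_shared_within_genes(self):
        cfg = SimConfig(n_snps=2000, n_genes=300, fraction_dase=0.1, seed=5)
        ann = generate_annotation(cfg)
        eff = plant_effects(ann, cfg)
        hit = eff[eff["log2fc"] > 0]
        # every affected gene carries a single effect value and allele
        per_gene = hit.groupby("gene_id")[["log2fc", "affected_allele"]].nunique()
        assert (per_gene == 1).all().all()

    def test_negative_effect_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(effect_log2fc_range=(-1.0, 2.0))


class TestIntensities:
    def test_balanced_heterozygote_without_noise(self):
        cfg = zero_noise_config(fraction_dase=0.0, seed=2)
        cohort = simulate_cohort(cfg)
        rec = cohort["records"]
        ab = rec["genotype"] == "AB"
        gdna = rec[(rec["source"] == "gDNA") & ab]
        assert (gdna["x_raw"] == gdna["y_raw"]).all()
        cdna = rec[(rec["source"] == "cDNA") & ab]
        trans = cohort["annotation"].loc[
            cohort["annotation"]["is_transcribed"], "snp_id"]
        cdna = cdna[cdna["snp_id"].isin(trans)]
        assert (cdna["x_raw"] == cdna["y_raw"]).all()

    def test_planted_effect_two_gives_fourfold_cdna(self):
        cfg = zero_noise_config(fraction_dase=1.0, seed=2)
        cohort = simulate_cohort(cfg)
        rec, eff = cohort["records"], cohort["effects"].set_index("snp_id")
        cdna = rec[(rec["source"] == "cDNA") & (rec["genotype"] == "AB")]
        hit = cdna[eff.loc[cdna["snp_id"], "log2fc"].to_numpy() == 2.0]
        hi = np.maximum(hit["x_raw"], hit["y_raw"])
        lo = np.minimum(hit["x_raw"], hit["y_raw"])
        assert (hi == 4 * lo).all()

    def test_intensity_range_and_dtype(self, small_cohort):
        cfg, cohort = small_cohort
        rec = cohort["records"]
        for col in ("x_raw", "y_raw"):
            assert rec[col].dtype == np.int64
            assert rec[col].between(0, cfg.intensity_cap).all()

    def test_identical_seed_reproduces_byte_identical_export(self, tmp_path):
        cfg = SimConfig(n_snps=300, n_genes=50, seed=13)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_export(a["records"], pa)
        write_export(b["records"], pb)
        assert pa.read_bytes() == pb.read_bytes()
        c = simulate_cohort(SimConfig(n_snps=300, n_genes=50, seed=14))
        pc = tmp_path / "c.tsv"
        write_export(c["records"], pc)
        assert pa.read_bytes() != pc.read_bytes()

    def test_crosstalk_conserves_total_signal(self):
        base = SimConfig(n_snps=300, n_genes=50, crosstalk=0.0, seed=21)
        mixed = SimConfig(n_snps=300, n_genes=50, crosstalk=0.2, seed=21)
        ann = generate_annotation(base)
        geno = simulate_genotypes(ann, base)
        eff = plant_effects(ann, base)
        r0 = simulate_intensities(geno, ann, eff, base)
        r1 = simulate_intensities(geno, ann, eff, mixed)
        # the mixing matrix has unit row sums, so X+Y per record is
        # unchanged up to integer rounding
        assert (np.abs((r0["x_raw"] + r0["y_raw"])
                       - (r1["x_raw"] + r1["y_raw"])) <= 1).all()

    def test_misaligned_inputs_rejected(self, small_cohort):
        cfg, cohort = small_cohort
        with pytest.raises(ValueError):
            simulate_intensities(cohort["genotypes"].iloc[:-1],
                                 cohort["annotation"], cohort["effects"], cfg)

    def test_null_dase_grows_with_noise(self):
        """Mean observed DASE at null loci increases with channel noise."""
        from dasescan import (PipelineConfig, apply_filters,
                              build_dase_matrix, matrix_to_long)
        means = []
        for sdlog in (0.05, 0.15, 0.4):
            cfg = SimConfig(n_snps=1500, n_genes=300, fraction_dase=0.0,
                            noise_sdlog=sdlog, seed=30)
            cohort = simulate_cohort(cfg)
            paired, _ = apply_filters(cohort["records"], cohort["annotation"],
                                      PipelineConfig())
            long = matrix_to_long(build_dase_matrix(paired))
            means.append(long["dase"].mean())
        assert means[0] < means[1] < means[2]
        assert means[0] < 0.5


class TestSangerPeaks:
    def test_null_locus_without_noise_has_equal_peaks(self):
        cfg = zero_noise_config(fraction_dase=0.0, sanger_sdlog=0.0, seed=2)
        cohort = simulate_cohort(cfg)
        loci = cohort["annotation"]["snp_id"].iloc[:5].tolist()
        peaks = simulate_sanger_peaks(cohort["effects"], cohort["genotypes"],
                                      loci, cfg)
        assert (peaks["peak_x"] == peaks["peak_y"]).all()

    def test_planted_effect_sets_peak_ratio(self):
        cfg = zero_noise_config(fraction_dase=1.0, sanger_sdlog=0.0, seed=2)
        cohort = simulate_cohort(cfg)
        eff = cohort["effects"]
        loci = eff.loc[eff["log2fc"] == 2.0, "snp_id"].iloc[:5].tolist()
        peaks = simulate_sanger_peaks(eff, cohort["genotypes"], loci, cfg)
        cdna = peaks[peaks["source"] == "cDNA"]
        hi = np.maximum(cdna["peak_x"], cdna["peak_y"])
        lo = np.minimum(cdna["peak_x"], cdna["peak_y"])
        assert (hi == 4 * lo).all()
        gdna = peaks[peaks["source"] == "gDNA"]
        assert (gdna["peak_x"] == gdna["peak_y"]).all()

    def test_noisy_peaks_are_positive_ints_in_range(self, small_cohort):
        cfg, cohort = small_cohort
        loci = cohort["annotation"]["snp_id"].iloc[:200].tolist()
        peaks = simulate_sanger_peaks(cohort["effects"], cohort["genotypes"],
                                      loci, cfg)
        assert len(peaks) > 1000
        for col in ("peak_x", "peak_y"):
            assert peaks[col].dtype == np.int64
            assert peaks[col].between(1, cfg.sanger_peak_cap).all()

    def test_unknown_locus_rejected(self, small_cohort):
        cfg, cohort = small_cohort
        with pytest.raises(KeyError):
            simulate_sanger_peaks(cohort["effects"], cohort["genotypes"],
                                  ["rs_not_there"], cfg)
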