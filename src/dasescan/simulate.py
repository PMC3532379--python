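"""Synthetic paired gDNA/ds-cDNA two-channel SNP-array cohorts.

The generator emulates the data an Infinium-style genotyping array produces
when run on paired genomic DNA and double-stranded cDNA from the same
individuals: per-SNP two-channel (allele A = X, allele B = Y) fluorescence
intensities in a 16-bit range, genotype calls with a GenCall-like quality
score, probe-to-probe affinity variation, additive optical background,
multiplicative lognormal intensity noise and a small X/Y crosstalk.

Ground truth is explicit: a configurable fraction of transcribed, non-CNV
loci carries a planted absolute log2 allelic fold-change, assigned per gene
(allelic imbalance is a transcript-level phenomenon, so every SNP of an
affected gene reports the same effect).  A matched Sanger peak-height
simulator produces chromatogram-style pixel heights for validation loci.

All randomness flows from ``SimConfig.seed`` through named substreams, so
each generation step is individually reproducible.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig

AUTOSOMES = [str(i) for i in range(1, 23)]
CHROMOSOMES = AUTOSOMES + ["X", "Y"]
GENE_CHROMOSOMES = AUTOSOMES + ["X"]  # transcribed loci of the female genome

_STREAMS = {
    "annotation": 11,
    "genotypes": 12,
    "effects": 13,
    "intensities": 14,
    "sanger": 15,
}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stream]])


def _sample_ids(config: SimConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_samples)]


def generate_annotation(config: SimConfig) -> pd.DataFrame:
    """Build a marker-annotation table for a synthetic cohort.

    Returns one row per SNP with columns ``snp_id``, ``chromosome``
    (1..22, X, Y), 1-based ``position``, ``gene_id`` (empty for
    non-transcribed markers), ``is_transcribed`` and ``is_cnv_marker``.
    Every gene receives at least one SNP and, when the SNP budget allows,
    some genes receive three or more so gene-level aggregation has work to
    do.  At least one Y-chromosome SNP and (for a positive CNV fraction) at
    least one CNV marker are guaranteed.
    """
    rng = _rng(config, "annotation")
    n_snps, n_genes = config.n_snps, config.n_genes
    n_trans = int(round(config.fraction_transcribed * n_snps))
    if n_trans < n_genes:
        raise ValueError(
            f"only {n_trans} transcribed SNPs for {n_genes} genes; "
            "raise fraction_transcribed or lower n_genes"
        )

    gene_ids = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    gene_chrom = rng.choice(GENE_CHROMOSOMES, size=n_genes)
    gene_start = rng.integers(1, 200_000_000, size=n_genes)

    # one SNP per gene, then the rest of the transcribed budget at random
    gene_of_snp = np.concatenate(
        [np.arange(n_genes), rng.integers(0, n_genes, size=n_trans - n_genes)]
    )
    offsets = rng.integers(0, 50_000, size=n_trans)

    n_free = n_snps - n_trans
    free_chrom = rng.choice(CHROMOSOMES, size=n_free) if n_free else np.array([], dtype=object)
    if n_free and not np.any(free_chrom == "Y"):
        free_chrom[0] = "Y"
    free_pos = rng.integers(1, 200_000_000, size=n_free)

    chrom = np.concatenate([gene_chrom[gene_of_snp], free_chrom])
    pos = np.concatenate([gene_start[gene_of_snp] + offsets, free_pos])
    gene_col = np.concatenate(
        [np.array(gene_ids, dtype=object)[gene_of_snp],
         np.full(n_free, "", dtype=object)]
    )
    is_trans = np.concatenate(
        [np.ones(n_trans, dtype=bool), np.zeros(n_free, dtype=bool)]
    )

    is_cnv = np.zeros(n_snps, dtype=bool)
    if config.fraction_cnv > 0:
        n_cnv = max(1, int(round(config.fraction_cnv * n_snps)))
        is_cnv[rng.choice(n_snps, size=n_cnv, replace=False)] = True

    return pd.DataFrame(
        {
            "snp_id": [f"rs{1_000_000 + i}" for i in range(n_snps)],
            "chromosome": chrom,
            "position": pos.astype(np.int64),
            "gene_id": gene_col,
            "is_transcribed": is_trans,
            "is_cnv_marker": is_cnv,
        }
    )


def simulate_genotypes(annotation: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw AA/AB/BB genotypes per SNP x sample under Hardy-Weinberg.

    Each SNP gets a B-allele frequency drawn uniformly from
    ``config.maf_range``; samples are independent.  Y-chromosome SNPs get a
    fixed homozygous AA call (the cohort models female donors, so Y markers
    carry no biology and exist only to exercise the Y filter).
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    rng = _rng(config, "genotypes")
    n_snps = len(annotation)
    samples = _sample_ids(config)

    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=n_snps) if hi > lo else np.full(n_snps, lo)
    p_aa = (1 - maf) ** 2
    p_ab = 2 * maf * (1 - maf)

    u = rng.random((n_snps, config.n_samples))
    codes = np.where(u < p_aa[:, None], 0, np.where(u < (p_aa + p_ab)[:, None], 1, 2))
    codes[(annotation["chromosome"] == "Y").to_numpy()] = 0

    labels = np.array(["AA", "AB", "BB"], dtype=object)
    return pd.DataFrame(labels[codes], index=annotation["snp_id"].to_numpy(),
                        columns=samples)


def plant_effects(annotation: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign true absolute log2 allelic fold-changes to a fraction of loci.

    Exactly ``round(fraction_dase * n_eligible)`` transcribed, non-CNV,
    non-Y SNPs receive a nonzero effect, drawn per gene (uniform in
    ``effect_log2fc_range``) so that SNPs of one gene agree; the gene drawn
    last may be only partially covered when whole genes cannot sum to the
    exact SNP budget.  Returns one row per SNP: ``snp_id``, ``gene_id``,
    ``log2fc`` (0 at null loci) and ``affected_allele`` ('A' or 'B' for
    affected loci, '' otherwise).
    """
    elo, ehi = config.effect_log2fc_range
    if elo < 0:
        raise ValueError("effect_log2fc_range must be non-negative")
    rng = _rng(config, "effects")

    eligible = (
        annotation["is_transcribed"]
        & ~annotation["is_cnv_marker"]
        & (annotation["chromosome"] != "Y")
    ).to_numpy()
    n_eligible = int(eligible.sum())
    target = int(round(config.fraction_dase * n_eligible))

    log2fc = np.zeros(len(annotation))
    allele = np.full(len(annotation), "", dtype=object)

    if target > 0:
        elig_idx = np.flatnonzero(eligible)
        genes = annotation["gene_id"].to_numpy()
        gene_order = pd.unique(genes[elig_idx])
        rng.shuffle(gene_order)
        remaining = target
        for g in gene_order:
            members = elig_idx[genes[elig_idx] == g]
            take = members if len(members) <= remaining else rng.choice(
                members, size=remaining, replace=False)
            eff = rng.uniform(elo, ehi)
            aff = rng.choice(["A", "B"])
            log2fc[take] = eff
            allele[take] = aff
            remaining -= len(take)
            if remaining == 0:
                break

    return pd.DataFrame(
        {
            "snp_id": annotation["snp_id"].to_numpy(),
            "gene_id": annotation["gene_id"].to_numpy(),
            "log2fc": log2fc,
            "affected_allele": allele,
        }
    )


def _dosage_from_genotype(geno: np.ndarray) -> np.ndarray:
    """A-allele copy number (2, 1, 0) for AA/AB/BB calls."""
    d = np.empty(geno.shape, dtype=float)
    d[geno == "AA"] = 2.0
    d[geno == "AB"] = 1.0
    d[geno == "BB"] = 0.0
    return d


def simulate_intensities(
    genotypes: pd.DataFrame,
    annotation: pd.DataFrame,
    effects: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Generate the paired two-channel intensity export for the cohort.

    Signal model per SNP x sample:

    * gDNA allele signals are proportional to allele dosage
      (AA -> (2,0), AB -> (1,1), BB -> (0,2)) times a per-SNP, per-channel
      probe affinity (lognormal).
    * cDNA signals are a per-gene x sample expression level (lognormal
      around ``expression_mean``) split between alleles; a heterozygote
      under fold-change f expresses fractions f/(1+f) vs 1/(1+f),
      homozygotes express one allele, non-transcribed SNPs give background
      only.
    * Each channel is multiplied by lognormal noise, an additive lognormal
      background (mean ``background_mean``) is added, the two channels are
      mixed by the crosstalk matrix [[1-c, c], [c, 1-c]], and the result is
      rounded and clipped to [0, intensity_cap].

    A genotype-quality score in [0, 1] accompanies every record; a
    ``low_quality_fraction`` of gDNA calls is contaminated with low scores
    (some becoming NC) so the quality filter has work to do.

    Returns a long DataFrame with columns ``snp_id``, ``sample_id``,
    ``source`` (gDNA/cDNA), ``genotype``, ``quality``, ``x_raw``, ``y_raw``.
    """
    ann = annotation.set_index("snp_id")
    if not genotypes.index.equals(pd.Index(annotation["snp_id"])):
        raise ValueError("genotypes and annotation list different SNPs")
    eff = effects.set_index("snp_id")
    if not eff.index.equals(genotypes.index):
        raise ValueError("effects and genotypes list different SNPs")

    rng = _rng(config, "intensities")
    n_snps, n_samples = genotypes.shape
    samples = list(genotypes.columns)

    geno = genotypes.to_numpy(dtype=object)
    dos_a = _dosage_from_genotype(geno)

    aff_x = _lognormal(rng, config.probe_affinity_sdlog, n_snps)[:, None]
    aff_y = _lognormal(rng, config.probe_affinity_sdlog, n_snps)[:, None]

    base = config.expression_mean
    gdna_x = (dos_a / 2.0) * base * aff_x
    gdna_y = ((2.0 - dos_a) / 2.0) * base * aff_y

    # per-gene x sample expression; genes share a level within a sample
    gene_ids = ann["gene_id"].to_numpy()
    transcribed = ann["is_transcribed"].to_numpy()
    uniq_genes, gene_idx = np.unique(gene_ids, return_inverse=True)
    expr_gene = base * _lognormal(
        rng, config.expression_sdlog, (len(uniq_genes), n_samples))
    expr = expr_gene[gene_idx, :]
    expr[~transcribed, :] = 0.0

    f = np.exp2(eff["log2fc"].to_numpy())[:, None]
    frac_a_het = np.where(
        (eff["affected_allele"].to_numpy() == "B")[:, None], 1.0 / (1.0 + f),
        f / (1.0 + f))
    frac_a = np.where(dos_a == 2.0, 1.0, np.where(dos_a == 0.0, 0.0, frac_a_het))

    cdna_x = expr * frac_a * aff_x
    cdna_y = expr * (1.0 - frac_a) * aff_y

    channels = {}
    for name, sig in (("GX", gdna_x), ("GY", gdna_y),
                      ("DX", cdna_x), ("DY", cdna_y)):
        noisy = sig * _lognormal(rng, config.noise_sdlog, sig.shape)
        if config.background_mean > 0:
            noisy = noisy + config.background_mean * _lognormal(
                rng, config.noise_sdlog, sig.shape)
        channels[name] = noisy

    c = config.crosstalk
    gx = (1 - c) * channels["GX"] + c * channels["GY"]
    gy = c * channels["GX"] + (1 - c) * channels["GY"]
    dx = (1 - c) * channels["DX"] + c * channels["DY"]
    dy = c * channels["DX"] + (1 - c) * channels["DY"]

    def _quantize(a: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(a), 0, config.intensity_cap).astype(np.int64)

    gx, gy, dx, dy = map(_quantize, (gx, gy, dx, dy))

    # GenCall-like quality: mostly high Beta(9,1); a contaminated fraction
    # Beta(1,9), with the worst of those reported as no-calls
    quality_g = rng.beta(9, 1, size=(n_snps, n_samples))
    contaminated = rng.random((n_snps, n_samples)) < config.low_quality_fraction
    low_q = rng.beta(1, 9, size=(n_snps, n_samples))
    quality_g = np.where(contaminated, low_q, quality_g)
    geno_out = geno.copy()
    geno_out[contaminated & (quality_g < 0.05)] = "NC"
    quality_d = rng.beta(9, 1, size=(n_snps, n_samples))

    snp_rep = np.repeat(genotypes.index.to_numpy(), n_samples)
    sample_rep = np.tile(np.array(samples, dtype=object), n_snps)

    def _records(source, x, y, q):
        return pd.DataFrame(
            {
                "snp_id": snp_rep,
                "sample_id": sample_rep,
                "source": source,
                "genotype": geno_out.ravel(),
                "quality": q.ravel(),
                "x_raw": x.ravel(),
                "y_raw": y.ravel(),
            }
        )

    out = pd.concat(
        [_records("gDNA", gx, gy, quality_g), _records("cDNA", dx, dy, quality_d)],
        ignore_index=True,
    )
    return out


def _lognormal(rng: np.random.Generator, sdlog: float, shape) -> np.ndarray:
    """Lognormal(0, sdlog) factors; exactly 1 when sdlog is 0."""
    if sdlog == 0:
        return np.ones(shape)
    return rng.lognormal(0.0, sdlog, size=shape)


def simulate_sanger_peaks(
    effects: pd.DataFrame,
    genotypes: pd.DataFrame,
    loci: Sequence[str] | Iterable[str],
    config: SimConfig,
) -> pd.DataFrame:
    """Emulate chromatogram peak heights for validation loci.

    For every requested SNP and each sample heterozygous there, emits a
    gDNA trace with (noisily) equal allele peaks and a cDNA trace whose
    peak ratio reflects the planted fold-change, on a pixel scale of a few
    dozen (``sanger_peak_height``), clipped to [1, sanger_peak_cap].
    """
    rng = _rng(config, "sanger")
    eff = effects.set_index("snp_id")
    rows = []
    h = config.sanger_peak_height
    for snp in loci:
        if snp not in genotypes.index:
            raise KeyError(f"unknown locus id: {snp}")
        f = float(np.exp2(eff.at[snp, "log2fc"]))
        if eff.at[snp, "affected_allele"] == "B":
            f = 1.0 / f
        frac_a = f / (1.0 + f)
        for sample in genotypes.columns:
            if genotypes.at[snp, sample] != "AB":
                continue
            gx, gy = h * _lognormal(rng, config.sanger_sdlog, 2)
            dx, dy = 2 * h * np.array([frac_a, 1 - frac_a]) * _lognormal(
                rng, config.sanger_sdlog, 2)
            rows.append((snp, sample, "gDNA", gx, gy))
            rows.append((snp, sample, "cDNA", dx, dy))
    out = pd.DataFrame(
        rows, columns=["snp_id", "sample_id", "source", "peak_x", "peak_y"])
    for col in ("peak_x", "peak_y"):
        out[col] = np.clip(np.rint(out[col]), 1, config.sanger_peak_cap).astype(
            np.int64) if len(out) else out[col].astype(np.int64)
    return out


def simulate_cohort(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Run the full generation chain and return all tables.

    Keys: ``annotation``, ``genotypes``, ``effects``, ``records`` (the
    combined gDNA+cDNA export), ``truth`` (snp_id, gene_id, true_log2fc).
    """
    annotation = generate_annotation(config)
    genotypes = simulate_genotypes(annotation, config)
    effects = plant_effects(annotation, config)
    records = simulate_intensities(genotypes, annotation, effects, config)
    truth = effects.rename(columns={"log2fc": "true_log2fc"})[
        ["snp_id", "gene_id", "true_log2fc"]]
    return {
        "annotation": annotation,
        "genotypes": genotypes,
        "effects": effects,
        "records": records,
        "truth": truth,
    }
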