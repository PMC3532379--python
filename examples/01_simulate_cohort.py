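"""Generate a synthetic paired gDNA/ds-cDNA array cohort with known truth.

Eight samples are genotyped on a two-channel array; a fraction of
transcribed genes carries a planted allelic fold-change that the rest of
the pipeline should recover.
"""

from dasescan import SimConfig, simulate_cohort

config = SimConfig(n_snps=5_000, n_genes=1_000, fraction_dase=0.05, seed=1)
cohort = simulate_cohort(config)

ann = cohort["annotation"]
eff = cohort["effects"]
records = cohort["records"]

print(f"SNPs: {len(ann)}  (transcribed: {ann['is_transcribed'].sum()}, "
      f"CNV markers: {ann['is_cnv_marker'].sum()}, "
      f"chrY: {(ann['chromosome'] == 'Y').sum()})")
print(f"intensity records: {len(records)} "
      f"({config.n_samples} samples x 2 sources)")
planted = eff[eff["log2fc"] > 0]
print(f"planted DASE loci: {len(planted)} SNPs in "
      f"{planted['gene_id'].nunique()} genes, "
      f"|log2 fold-change| in [{planted['log2fc'].min():.2f}, "
      f"{planted['log2fc'].max():.2f}]")

# The planted fold-change acts on transcripts, so every SNP of an affected
# gene shares its gene's effect; null loci have log2fc = 0 and should come
# out with DASE near 0 downstream.
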