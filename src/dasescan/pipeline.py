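"""End-to-end orchestration: ingest -> filter -> DASE -> test -> aggregate.

A run consumes the paired intensity exports plus the marker annotation and
writes every analysis artifact (filter report, DASE matrix, per-locus
results, candidate table, Circos track, histogram, QQ table) together with
a machine-readable manifest recording the configuration, input checksums
and stage counts.  The analysis itself is deterministic: rerunning with
identical inputs and configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import aggregate, dase, io, qc, significance
from .config import PipelineConfig, SimConfig
from .simulate import simulate_cohort, simulate_sanger_peaks


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    matrix: pd.DataFrame
    null_params: significance.GammaParams
    snp_table: pd.DataFrame
    gene_table: pd.DataFrame
    candidates: aggregate.CandidateSet
    report: qc.FilterReport
    fraction_ge_2: float
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, gdna_path: str | Path,
                 cdna_path: str | Path, annotation_path: str | Path,
                 outdir: str | Path) -> PipelineResult:
    """Run the full DASE analysis and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gdna = io.read_export(gdna_path)
    cdna = io.read_export(cdna_path)
    annotation = io.read_annotation(annotation_path)
    records = pd.concat([gdna, cdna], ignore_index=True)

    paired, report = qc.apply_filters(records, annotation, config)
    matrix = dase.build_dase_matrix(paired, pseudocount=config.pseudocount)
    long = dase.matrix_to_long(matrix)

    null_params = significance.fit_gamma_mle(long["dase"].clip(lower=1e-6))
    qq = significance.qq_gamma(long["dase"].clip(lower=1e-6), null_params)

    snp_table = aggregate.snp_based(
        matrix, min_het=config.min_het, null_params=null_params,
        method=config.pvalue_method, two_sided=config.two_sided)
    gene_table, n_unmapped = aggregate.gene_based(
        matrix, annotation, min_samples=config.min_het,
        null_params=null_params, method=config.pvalue_method,
        two_sided=config.two_sided)
    candidates = aggregate.intersect_candidates(
        snp_table, gene_table, annotation, dase_min=config.dase_min,
        p_max=config.p_max, fdr_max=config.fdr_max)

    snp_mean = matrix.mean(axis=1, skipna=True)
    hist, fraction_ge_2 = io.dase_histogram(long["dase"])

    # artifacts
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t",
                             index=False, lineterminator="\n")
    long.to_csv(outdir / "dase_matrix.tsv", sep="\t", index=False,
                lineterminator="\n", float_format="%.10g")
    io.write_results(aggregate.results_long(snp_table, gene_table, annotation),
                     outdir / "results.tsv")
    candidates.to_table().to_csv(outdir / "candidates.tsv", sep="\t",
                                 index=False, lineterminator="\n",
                                 float_format="%.10g")
    io.write_circos_track(snp_mean.rename("dase"), annotation,
                          outdir / "dase_track.txt")
    hist.to_csv(outdir / "dase_histogram.tsv", sep="\t", index=False,
                lineterminator="\n")
    qq.to_csv(outdir / "qq_gamma.tsv", sep="\t", index=False,
              lineterminator="\n", float_format="%.10g")

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            "gdna": _sha256(gdna_path),
            "cdna": _sha256(cdna_path),
            "annotation": _sha256(annotation_path),
        },
        "stages": [[name, count] for name, count in report.stages],
        "null_gamma": {"shape": null_params.shape, "scale": null_params.scale,
                       "n": null_params.n},
        "n_snps_tested": int(len(snp_table)),
        "n_genes_tested": int(len(gene_table)),
        "n_unmapped_snps": n_unmapped,
        "n_candidates": len(candidates),
        "fraction_dase_ge_2": fraction_ge_2,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(matrix=matrix, null_params=null_params,
                          snp_table=snp_table, gene_table=gene_table,
                          candidates=candidates, report=report,
                          fraction_ge_2=fraction_ge_2, manifest=manifest)


def write_simulation(config: SimConfig, outdir: str | Path,
                     sanger_loci: int = 0) -> dict[str, Path]:
    """Generate a cohort and write its exports, annotation and truth table.

    Optionally also writes Sanger peak heights for the ``sanger_loci``
    planted loci with the largest effects.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    records = cohort["records"]

    paths = {
        "gdna": outdir / "gdna.tsv",
        "cdna": outdir / "cdna.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
    }
    io.write_export(records[records["source"] == "gDNA"], paths["gdna"])
    io.write_export(records[records["source"] == "cDNA"], paths["cdna"])
    io.write_annotation(cohort["annotation"], paths["annotation"])
    cohort["truth"].to_csv(paths["truth"], sep="\t", index=False,
                           lineterminator="\n", float_format="%.10g")

    if sanger_loci > 0:
        eff = cohort["effects"]
        top = eff[eff["log2fc"] > 0].nlargest(sanger_loci, "log2fc")["snp_id"]
        peaks = simulate_sanger_peaks(eff, cohort["genotypes"], list(top),
                                      config)
        paths["peaks"] = outdir / "sanger_peaks.tsv"
        io.write_peaks(peaks, paths["peaks"])
    return paths
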