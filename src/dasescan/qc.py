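"""Marker, expression and genotype-quality filters, background correction,
and pairing of gDNA with cDNA records into heterozygous observations.

The canonical order mirrors the analysis protocol: discard CNV markers,
Y-chromosome markers and non-transcribed markers; impose the combined cDNA
intensity cut-off (X_raw + Y_raw >= 500, inclusive) to drop non-expressed
SNPs; remove ambiguous genotype calls (no-calls and low quality scores);
background-correct each channel; then keep only SNP x sample pairs whose
gDNA call is heterozygous.  Heterozygosity is judged from the gDNA call
only — the cDNA call can be distorted by the very imbalance being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig


@dataclass
class FilterReport:
    """Record counts entering/surviving each stage, in application order."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError(
                f"stage {stage!r} grew the record set ({count} > "
                f"{self.stages[-1][1]})")
        self.stages.append((stage, int(count)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "records"])


def filter_markers(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep records at transcribed, non-CNV, non-Y-chromosome markers."""
    ann = annotation.set_index("snp_id")
    missing = pd.Index(records["snp_id"].unique()).difference(ann.index)
    if len(missing):
        raise KeyError(
            "unannotated SNP(s): " + ", ".join(map(str, missing[:10])))
    keep_snp = ann.index[
        ann["is_transcribed"] & ~ann["is_cnv_marker"] & (ann["chromosome"] != "Y")
    ]
    return records[records["snp_id"].isin(keep_snp)].reset_index(drop=True)


def filter_expression(records: pd.DataFrame, threshold: float = 500.0) -> pd.DataFrame:
    """Drop SNP x sample pairs whose cDNA combined intensity is below cut-off.

    The test is on the raw (pre-correction) cDNA X + Y sum, boundary
    inclusive (sum >= threshold survives).  Both the cDNA record and its
    gDNA partner are removed, since an unexpressed SNP cannot contribute an
    observation.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    cdna = records[records["source"] == "cDNA"]
    expressed = cdna.loc[
        (cdna["x_raw"] + cdna["y_raw"]) >= threshold, ["snp_id", "sample_id"]]
    keep = pd.MultiIndex.from_frame(expressed)
    idx = pd.MultiIndex.from_frame(records[["snp_id", "sample_id"]])
    return records[idx.isin(keep)].reset_index(drop=True)


def filter_genotype_quality(records: pd.DataFrame,
                            min_score: float = 0.15) -> pd.DataFrame:
    """Remove SNP x sample pairs with ambiguous gDNA genotyping.

    Ambiguous means a no-call ("NC") or a gDNA quality score below
    ``min_score``; the pair is dropped from both sources because a usable
    observation needs a trustworthy gDNA call.
    """
    if not 0 <= min_score <= 1:
        raise ValueError("min_score must be in [0, 1]")
    gdna = records[records["source"] == "gDNA"]
    good = gdna.loc[
        (gdna["genotype"] != "NC") & (gdna["quality"] >= min_score),
        ["snp_id", "sample_id"]]
    keep = pd.MultiIndex.from_frame(good)
    idx = pd.MultiIndex.from_frame(records[["snp_id", "sample_id"]])
    out = records[idx.isin(keep)]
    out = out[(out["genotype"] != "NC")]
    return out.reset_index(drop=True)


def estimate_background(records: pd.DataFrame,
                        percentile: float = 5.0) -> dict[tuple[str, str], float]:
    """Estimate one background level per source x channel.

    Uses opposite-homozygote signal: at a BB SNP the X (allele A) channel
    carries no allele signal, and vice versa, so those intensities are pure
    background.  The given percentile of each pooled set is returned, keyed
    by (source, channel).
    """
    out: dict[tuple[str, str], float] = {}
    for source in ("gDNA", "cDNA"):
        sub = records[records["source"] == source]
        for channel, opposite in (("x_raw", "BB"), ("y_raw", "AA")):
            pool = sub.loc[sub["genotype"] == opposite, channel]
            out[(source, channel)] = (
                float(np.percentile(pool, percentile)) if len(pool) else 0.0)
    return out


def background_correct(records: pd.DataFrame, percentile: float = 5.0,
                       floor: float = 1.0) -> pd.DataFrame:
    """Subtract the estimated background from every channel, flooring at 1.

    The floor keeps downstream log-ratios finite without special-casing
    zero intensities.
    """
    levels = estimate_background(records, percentile=percentile)
    out = records.copy()
    out["x_raw"] = out["x_raw"].astype(float)
    out["y_raw"] = out["y_raw"].astype(float)
    for (source, channel), bg in levels.items():
        mask = out["source"] == source
        out.loc[mask, channel] = np.maximum(
            out.loc[mask, channel] - bg, floor)
    return out


def pair_and_select_het(records: pd.DataFrame) -> pd.DataFrame:
    """Join gDNA and cDNA records and keep heterozygous observations.

    Returns one row per SNP x sample whose gDNA call is AB and for which
    both sources are present, with columns snp_id, sample_id, genotype,
    GX, GY (gDNA channels) and DX, DY (cDNA channels).  Pairs missing one
    source are silently dropped (their count is visible in the filter
    report); duplicate records for a SNP x sample x source are an error.
    """
    if records.duplicated(["snp_id", "sample_id", "source"]).any():
        dup = records[records.duplicated(["snp_id", "sample_id", "source"])]
        raise ValueError(
            f"duplicate record(s) for SNP x sample x source, e.g. "
            f"{dup.iloc[0][['snp_id', 'sample_id', 'source']].tolist()}")
    gdna = records[records["source"] == "gDNA"]
    cdna = records[records["source"] == "cDNA"]
    merged = pd.merge(
        gdna[["snp_id", "sample_id", "genotype", "x_raw", "y_raw"]],
        cdna[["snp_id", "sample_id", "x_raw", "y_raw"]],
        on=["snp_id", "sample_id"], how="inner",
        suffixes=("_g", "_d"))
    merged = merged[merged["genotype"] == "AB"]
    merged = merged.rename(columns={
        "x_raw_g": "GX", "y_raw_g": "GY", "x_raw_d": "DX", "y_raw_d": "DY"})
    return merged[["snp_id", "sample_id", "genotype",
                   "GX", "GY", "DX", "DY"]].reset_index(drop=True)


def apply_filters(records: pd.DataFrame, annotation: pd.DataFrame,
                  config: PipelineConfig | None = None
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full QC chain in protocol order and report stage counts.

    Returns the heterozygous paired observations and a
    :class:`FilterReport` whose counts are monotone non-increasing in
    records (observations count as two records, one per source).
    """
    config = config or PipelineConfig()
    report = FilterReport()
    report.add("input", len(records))

    step = filter_markers(records, annotation)
    report.add("markers", len(step))

    step = filter_expression(step, threshold=config.intensity_min)
    report.add("expression", len(step))

    step = filter_genotype_quality(step, min_score=config.genotype_quality_min)
    report.add("genotype_quality", len(step))

    if config.background_method == "percentile":
        step = background_correct(step)
    report.add("background_corrected", len(step))

    paired = pair_and_select_het(step)
    report.add("het_paired", 2 * len(paired))
    return paired, report
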