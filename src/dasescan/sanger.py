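"""Sanger peak-height DASE calling and array-vs-sequencing concordance.

The sequencing-based statistic reuses the array formula on chromatogram
peak heights: the cDNA trace's two allele peaks, each normalized by the
matching gDNA peak.  Because usable peak heights span only a few dozen
pixels (versus the array's 16-bit range), the event threshold differs by
platform: an array DASE event is DASE >= 2 (inclusive), a sequencing event
requires one peak to be less than half the other, i.e. DASE strictly > 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dase import compute_dase


def sequencing_dase(cdna_x: float, cdna_y: float, gdna_x: float,
                    gdna_y: float) -> float:
    """|log2((cDNA_x/gDNA_x)/(cDNA_y/gDNA_y))| from peak heights in pixels.

    Zero heights are floored to 1 pixel — a chromatogram cannot evidence a
    truly absent allele below its noise floor.
    """
    heights = np.array([cdna_x, cdna_y, gdna_x, gdna_y], dtype=float)
    if (heights < 0).any():
        raise ValueError("peak heights must be non-negative")
    cx, cy, gx, gy = np.maximum(heights, 1.0)
    return compute_dase(cx, cy, gx, gy, pseudocount=1.0)


def call_seq_event(value: float, threshold: float = 1.0) -> bool:
    """Positive sequencing event iff DASE strictly exceeds the threshold.

    At the default threshold 1 this encodes "one peak less than half the
    other": a ratio of exactly 2 (DASE exactly 1) is negative.
    """
    if value < 0:
        raise ValueError("DASE value must be non-negative")
    return bool(value > threshold)


def call_array_event(dase_value: float, threshold: float = 2.0) -> bool:
    """Positive array event iff DASE reaches the threshold (inclusive)."""
    if dase_value < 0:
        raise ValueError("DASE value must be non-negative")
    return bool(dase_value >= threshold)


def sequencing_dase_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Pair gDNA/cDNA traces and compute sequencing DASE per SNP x sample.

    Expects peak rows with columns snp_id, sample_id, source, peak_x,
    peak_y (both sources present per pair); returns snp_id, sample_id,
    seq_dase.
    """
    gdna = peaks[peaks["source"] == "gDNA"]
    cdna = peaks[peaks["source"] == "cDNA"]
    merged = cdna.merge(gdna, on=["snp_id", "sample_id"],
                        suffixes=("_c", "_g"))
    cx = np.maximum(merged["peak_x_c"].to_numpy(dtype=float), 1.0)
    cy = np.maximum(merged["peak_y_c"].to_numpy(dtype=float), 1.0)
    gx = np.maximum(merged["peak_x_g"].to_numpy(dtype=float), 1.0)
    gy = np.maximum(merged["peak_y_g"].to_numpy(dtype=float), 1.0)
    return pd.DataFrame({
        "snp_id": merged["snp_id"],
        "sample_id": merged["sample_id"],
        "seq_dase": np.abs(np.log2((cx / gx) / (cy / gy))),
    })


def concordance_table(array_calls: pd.DataFrame, seq_calls: pd.DataFrame,
                      loci: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-locus event counts and overall confirmation fractions.

    ``array_calls``/``seq_calls`` carry one row per assessed SNP x sample
    with a boolean ``event`` column; ``loci`` maps snp_id -> gene_id.
    Returns a table with columns gene_id, snp_id, n_het_samples,
    n_array_events, n_seq_events (n_het_samples = samples with an array
    assessment), plus totals including two confirmation fractions: among
    array-positive pairs that sequencing could assess, and among all
    sequencing-assessed pairs — the two denominators published summaries
    may differ on.
    """
    key = ["snp_id", "sample_id"]
    merged = array_calls[key + ["event"]].rename(
        columns={"event": "array_event"}).merge(
        seq_calls[key + ["event"]].rename(columns={"event": "seq_event"}),
        on=key, how="left")
    merged["assessed"] = merged["seq_event"].notna()
    gene_of = loci.set_index("snp_id")["gene_id"]

    merged["array_event"] = merged["array_event"].astype(bool)
    merged["seq_pos"] = merged["seq_event"].eq(True)

    rows = []
    for snp, grp in merged.groupby("snp_id", sort=True):
        rows.append({
            "gene_id": gene_of.get(snp, ""),
            "snp_id": snp,
            "n_het_samples": len(grp),
            "n_array_events": int(grp["array_event"].sum()),
            "n_seq_events": int(grp["seq_pos"].sum()),
        })
    table = pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "n_het_samples",
                       "n_array_events", "n_seq_events"])

    both = merged[merged["assessed"].to_numpy(dtype=bool)]
    array_pos = both[both["array_event"].to_numpy(dtype=bool)]
    n_confirmed = int(array_pos["seq_pos"].sum())
    totals = {
        "n_het_samples": int(table["n_het_samples"].sum()) if len(table) else 0,
        "n_array_events": int(table["n_array_events"].sum()) if len(table) else 0,
        "n_seq_events": int(table["n_seq_events"].sum()) if len(table) else 0,
        "n_array_pos_assessed": int(len(array_pos)),
        "n_confirmed": n_confirmed,
        "confirmation_fraction_array_pos": (
            n_confirmed / len(array_pos) if len(array_pos) else float("nan")),
        "confirmation_fraction_all_assessed": (
            int(both["seq_pos"].sum()) / len(both)
            if len(both) else float("nan")),
    }
    return table, totals
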