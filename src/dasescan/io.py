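"""Readers and writers for the pipeline's tab-delimited interchange formats.

Formats: the BeadStudio-style intensity export (columns ``SNP_Name``,
``Sample_ID``, ``Source``, ``GType``, ``Score``, ``X_Raw``, ``Y_Raw``), the
marker-annotation table, the locus-result table, Sanger peak-height tables,
a DASE histogram table and a Circos 2D-value data track.  All files are
UTF-8 TSV with Unix newlines; extra columns in inputs are ignored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

EXPORT_COLUMNS = {
    "SNP_Name": "snp_id",
    "Sample_ID": "sample_id",
    "Source": "source",
    "GType": "genotype",
    "Score": "quality",
    "X_Raw": "x_raw",
    "Y_Raw": "y_raw",
}
ANNOTATION_COLUMNS = ["snp_id", "chromosome", "position", "gene_id",
                      "is_transcribed", "is_cnv_marker"]
RESULT_COLUMNS = ["gene_id", "snp_id", "approach", "mean_dase", "n_het",
                  "p_value", "fdr"]
PEAK_COLUMNS = ["snp_id", "sample_id", "source", "peak_x", "peak_y"]


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited layout."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_export(path: str | Path) -> pd.DataFrame:
    """Parse a BeadStudio-style intensity export into canonical records.

    Returns a DataFrame with columns snp_id, sample_id, source, genotype,
    quality, x_raw, y_raw; row order and count are preserved.  A missing
    required column raises :class:`FormatError` naming it; a non-numeric
    intensity raises :class:`FormatError` citing the 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, EXPORT_COLUMNS, path)
    df = df[list(EXPORT_COLUMNS)].rename(columns=EXPORT_COLUMNS)
    for col in ("quality", "x_raw", "y_raw"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & (df[col] != "")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, 1-based
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col} at line {line}")
        df[col] = parsed
    df["x_raw"] = df["x_raw"].astype(np.int64)
    df["y_raw"] = df["y_raw"].astype(np.int64)
    if (df[["x_raw", "y_raw"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative raw intensity")
    bad_src = ~df["source"].isin(["gDNA", "cDNA"])
    if bad_src.any():
        raise FormatError(
            f"{path}: unknown Source value {df['source'][bad_src].iloc[0]!r}")
    return df


def write_export(records: pd.DataFrame, path: str | Path) -> None:
    """Write canonical records back to the BeadStudio-style export layout."""
    inverse = {v: k for k, v in EXPORT_COLUMNS.items()}
    out = records[list(EXPORT_COLUMNS.values())].rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str},
                     keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    df = df[ANNOTATION_COLUMNS]
    df["is_transcribed"] = df["is_transcribed"].astype(bool)
    df["is_cnv_marker"] = df["is_cnv_marker"].astype(bool)
    df["position"] = df["position"].astype(np.int64)
    if df["snp_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate snp_id")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation[ANNOTATION_COLUMNS].copy()
    out["is_transcribed"] = out["is_transcribed"].astype(int)
    out["is_cnv_marker"] = out["is_cnv_marker"].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a locus-result table (SNP- or gene-level rows, or both).

    Columns: gene_id, snp_id (empty for gene-level rows), approach,
    mean_dase, n_het, p_value, fdr.  Floats carry enough digits to
    round-trip exactly.
    """
    out = results.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n",
               float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"gene_id": str, "snp_id": str, "approach": str})
    _require_columns(df, RESULT_COLUMNS, path)
    df = df[RESULT_COLUMNS]
    for col in ("mean_dase", "p_value", "fdr"):
        df[col] = pd.to_numeric(df[col])
    df["n_het"] = df["n_het"].astype(np.int64)
    return df


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_peaks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"snp_id": str, "sample_id": str, "source": str})
    _require_columns(df, PEAK_COLUMNS, path)
    df = df[PEAK_COLUMNS]
    df["peak_x"] = df["peak_x"].astype(np.int64)
    df["peak_y"] = df["peak_y"].astype(np.int64)
    return df


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}


def write_circos_track(dase_by_snp: pd.Series | pd.DataFrame,
                       annotation: pd.DataFrame, path: str | Path) -> None:
    """Write per-SNP DASE values as a Circos 2D-value data track.

    One line per SNP, ``hsN start end value`` with 1-based inclusive
    coordinates (start = end = SNP position), sorted by chromosome then
    position.  Every SNP must be annotated.
    """
    if isinstance(dase_by_snp, pd.DataFrame):
        dase_by_snp = dase_by_snp.set_index("snp_id")["dase"]
    ann = annotation.set_index("snp_id")
    missing = dase_by_snp.index.difference(ann.index)
    if len(missing):
        raise KeyError(
            "SNP(s) without annotation: " + ", ".join(map(str, missing[:10])))
    tbl = pd.DataFrame({
        "chromosome": ann.loc[dase_by_snp.index, "chromosome"],
        "position": ann.loc[dase_by_snp.index, "position"],
        "value": dase_by_snp.to_numpy(),
    })
    tbl["rank"] = tbl["chromosome"].map(_CHROM_ORDER)
    tbl = tbl.sort_values(["rank", "position"], kind="mergesort")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom, p, v in zip(tbl["chromosome"], tbl["position"], tbl["value"]):
            fh.write(f"hs{chrom} {p} {p} {v:g}\n")


def dase_histogram(dase_values, bin_width: float = 0.25) -> tuple[pd.DataFrame, float]:
    """Histogram DASE values and report the fraction at or above 2.

    Returns ``(table, fraction_ge_2)`` where the table has columns
    ``bin_left``, ``bin_right``, ``count`` and counts sum to the input
    length.  For empty input the table is empty and the fraction is NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(dase_values, dtype=float)
    if (values < 0).any():
        raise ValueError("DASE values must be non-negative")
    if values.size == 0:
        empty = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
        return empty, float("nan")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    table = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts.astype(np.int64),
    })
    fraction_ge_2 = float((values >= 2.0).sum() / values.size)
    return table, fraction_ge_2
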