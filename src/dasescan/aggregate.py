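"""SNP-based and gene-based candidate calling and their intersection.

Two parallel summaries of the SNP x sample DASE matrix:

* SNP-based — a SNP qualifies when heterozygous in at least ``min_het``
  samples (3 of 8 by default); its statistic is the mean of its per-sample
  DASE values.
* Gene-based — per sample, a gene's DASE is the mean over its heterozygous
  SNPs in that sample; genes with such a value in at least ``min_samples``
  samples qualify, and the statistic is the mean across those samples.

The SNP-based view can capture isoform-restricted imbalance at a single
UTR SNP; the gene-based view damps single-SNP outliers.  A candidate gene
must pass the thresholds (mean DASE >= 2.00, P <= 0.01, FDR <= 0.05, all
boundaries inclusive) in BOTH views, which trades sensitivity for a lower
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dase import n_het as _n_het
from .significance import GammaParams, attach_significance


def snp_based(matrix: pd.DataFrame, min_het: int = 3,
              null_params: GammaParams | None = None,
              method: str = "tail", two_sided: bool = False) -> pd.DataFrame:
    """Per-SNP mean DASE over heterozygous samples, with support filter.

    Returns columns locus_id, approach ('snp'), mean_dase, n_het and —
    when ``null_params`` is given — p_value and fdr (FDR within this
    table).
    """
    counts = _n_het(matrix)
    keep = counts[counts >= min_het].index
    table = pd.DataFrame({
        "locus_id": keep,
        "approach": "snp",
        "mean_dase": matrix.loc[keep].mean(axis=1, skipna=True).to_numpy(),
        "n_het": counts.loc[keep].to_numpy(),
    }).reset_index(drop=True)
    if null_params is not None and len(table):
        values = {s: matrix.loc[s].dropna().to_numpy() for s in keep} \
            if method == "glm" else None
        table = attach_significance(table, null_params, method=method,
                                    two_sided=two_sided,
                                    values_by_locus=values)
    return table


def gene_based(matrix: pd.DataFrame, annotation: pd.DataFrame,
               min_samples: int = 3,
               null_params: GammaParams | None = None,
               method: str = "tail", two_sided: bool = False
               ) -> tuple[pd.DataFrame, int]:
    """Per-gene mean DASE (per-sample gene means, then across samples).

    SNPs mapped to no gene are ignored and counted in the returned warning
    tally.  Returns ``(table, n_unmapped_snps)`` with the same columns as
    :func:`snp_based` (approach 'gene'; ``n_het`` = qualifying samples).
    """
    gene_of = annotation.set_index("snp_id")["gene_id"]
    mapped = matrix.index.intersection(gene_of.index[gene_of != ""])
    n_unmapped = len(matrix.index) - len(mapped)
    sub = matrix.loc[mapped]
    genes = gene_of.loc[mapped]

    # per-sample gene DASE: mean over that gene's het SNPs in that sample
    per_sample = sub.groupby(genes.to_numpy()).mean()
    support = per_sample.notna().sum(axis=1)
    keep = support[support >= min_samples].index
    table = pd.DataFrame({
        "locus_id": keep,
        "approach": "gene",
        "mean_dase": per_sample.loc[keep].mean(axis=1, skipna=True).to_numpy(),
        "n_het": support.loc[keep].to_numpy(),
    }).reset_index(drop=True)
    if null_params is not None and len(table):
        values = {
            g: per_sample.loc[g].dropna().to_numpy() for g in keep
        } if method == "glm" else None
        table = attach_significance(table, null_params, method=method,
                                    two_sided=two_sided,
                                    values_by_locus=values)
    return table, int(n_unmapped)


@dataclass
class CandidateSet:
    """Genes passing all thresholds in both views, with supporting rows."""

    genes: list[str]
    snp_support: pd.DataFrame
    gene_support: pd.DataFrame

    def __len__(self) -> int:
        return len(self.genes)

    def to_table(self) -> pd.DataFrame:
        """One row per (gene, passing SNP), both views' statistics attached."""
        snp = self.snp_support.rename(columns={
            "locus_id": "snp_id", "mean_dase": "snp_dase",
            "p_value": "snp_p", "fdr": "snp_fdr"})
        gene = self.gene_support.rename(columns={
            "locus_id": "gene_id", "mean_dase": "gene_dase",
            "p_value": "gene_p", "fdr": "gene_fdr"})
        merged = snp.merge(gene, on="gene_id", how="inner",
                           suffixes=("_snp", "_gene"))
        cols = ["gene_id", "snp_id", "snp_dase", "snp_p", "snp_fdr",
                "gene_dase", "gene_p", "gene_fdr"]
        return merged[cols].sort_values(["gene_id", "snp_id"]).reset_index(
            drop=True)


def _passes(table: pd.DataFrame, dase_min: float, p_max: float,
            fdr_max: float) -> pd.DataFrame:
    return table[
        (table["mean_dase"] >= dase_min)
        & (table["p_value"] <= p_max)
        & (table["fdr"] <= fdr_max)
    ]


def intersect_candidates(snp_tbl: pd.DataFrame, gene_tbl: pd.DataFrame,
                         annotation: pd.DataFrame, dase_min: float = 2.0,
                         p_max: float = 0.01, fdr_max: float = 0.05
                         ) -> CandidateSet:
    """Genes significant by both the SNP-based and gene-based views.

    A gene is a candidate iff at least one of its SNPs passes mean DASE,
    p-value and FDR thresholds in the SNP table AND the gene itself passes
    all three in the gene table.  Boundary values pass (>=, <=, <=
    inclusive).  Raising any threshold's stringency can only shrink the
    set.
    """
    gene_of = annotation.set_index("snp_id")["gene_id"]
    snp_pass = _passes(snp_tbl, dase_min, p_max, fdr_max).copy()
    snp_pass["gene_id"] = gene_of.reindex(snp_pass["locus_id"]).to_numpy()
    gene_pass = _passes(gene_tbl, dase_min, p_max, fdr_max)

    genes = sorted(
        set(snp_pass["gene_id"].dropna()) & set(gene_pass["locus_id"]))
    return CandidateSet(
        genes=genes,
        snp_support=snp_pass[snp_pass["gene_id"].isin(genes)].reset_index(
            drop=True),
        gene_support=gene_pass[gene_pass["locus_id"].isin(genes)].reset_index(
            drop=True),
    )


def results_long(snp_tbl: pd.DataFrame, gene_tbl: pd.DataFrame,
                 annotation: pd.DataFrame) -> pd.DataFrame:
    """Stack both views into the writable result layout.

    Columns: gene_id, snp_id (empty on gene rows), approach, mean_dase,
    n_het, p_value, fdr.
    """
    gene_of = annotation.set_index("snp_id")["gene_id"]
    snp = snp_tbl.copy()
    snp["snp_id"] = snp["locus_id"]
    snp["gene_id"] = gene_of.reindex(snp["locus_id"]).fillna("").to_numpy()
    gene = gene_tbl.copy()
    gene["gene_id"] = gene["locus_id"]
    gene["snp_id"] = ""
    cols = ["gene_id", "snp_id", "approach", "mean_dase", "n_het",
            "p_value", "fdr"]
    return pd.concat([snp[cols], gene[cols]], ignore_index=True)
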