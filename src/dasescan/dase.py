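"""The differential allele-specific expression (DASE) statistic.

For a heterozygous SNP in one sample, with cDNA channel intensities
(DX, DY) and gDNA channel intensities (GX, GY),

    DASE = | log2( (DX/GX) / (DY/GY) ) |

The gDNA ratio normalizes away probe-specific affinity differences between
the two allele channels (gDNA is 1:1 allelic by construction in a
heterozygote), so DASE measures the magnitude of allelic imbalance in the
transcript pool: 0 means balanced expression, 2 means one allele is
expressed four-fold over the other.  The absolute value makes the statistic
direction-free; no reference allele is assumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_dase(dx, dy, gx, gy, pseudocount: float = 1.0):
    """|log2((DX/GX)/(DY/GY))| with a pseudocount guarding zero channels.

    Accepts scalars or aligned arrays.  Any channel equal to zero is
    replaced by ``pseudocount`` (> 0), which keeps the statistic finite;
    on 16-bit count data a pseudocount of 1 is negligible for expressed
    loci.  Result is non-negative and finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    arrs = [np.asarray(a, dtype=float) for a in (dx, dy, gx, gy)]
    if any((a < 0).any() for a in arrs):
        raise ValueError("intensities must be non-negative")
    dx, dy, gx, gy = (np.where(a == 0, pseudocount, a) for a in arrs)
    out = np.abs(np.log2((dx / gx) / (dy / gy)))
    return float(out) if out.ndim == 0 else out


def compute_dase_column(paired: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """DASE for every paired observation row (columns DX, DY, GX, GY)."""
    return pd.Series(
        compute_dase(paired["DX"], paired["DY"], paired["GX"], paired["GY"],
                     pseudocount=pseudocount),
        index=paired.index, name="dase")


def build_dase_matrix(paired: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Assemble the SNP x sample DASE matrix from heterozygous observations.

    Returns a pivoted DataFrame (rows = SNPs, columns = samples) with NaN
    where no heterozygous observation exists; rows with no defined entry
    are dropped.  Duplicate (snp, sample) observations are an error.
    """
    if paired.duplicated(["snp_id", "sample_id"]).any():
        dup = paired[paired.duplicated(["snp_id", "sample_id"])].iloc[0]
        raise ValueError(
            f"duplicate observation for ({dup['snp_id']}, {dup['sample_id']})")
    values = paired.assign(dase=compute_dase_column(paired, pseudocount))
    matrix = values.pivot(index="snp_id", columns="sample_id", values="dase")
    return matrix.dropna(how="all")


def n_het(matrix: pd.DataFrame) -> pd.Series:
    """Per-SNP count of samples with a defined DASE entry."""
    return matrix.notna().sum(axis=1).rename("n_het")


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy (snp_id, sample_id, dase) rows for the defined entries."""
    long = matrix.stack().rename("dase").reset_index()
    long.columns = ["snp_id", "sample_id", "dase"]
    return long
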