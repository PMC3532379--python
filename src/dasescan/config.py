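"""Configuration objects for the simulator and the analysis pipeline.

Both configs are plain dataclasses with validation in ``__post_init__`` and a
``from_yaml`` constructor so a single YAML file can drive a reproducible run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Tuple

import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic paired gDNA/ds-cDNA array cohort.

    The defaults describe the study design being emulated: 8 cell-line
    samples assayed on a two-channel genotyping array with 16-bit intensity
    range, a minority of transcribed loci carrying a planted allelic
    fold-change, probe-to-probe affinity variation, additive optical
    background, multiplicative intensity noise and a small X/Y channel
    crosstalk.
    """

    n_samples: int = 8
    n_snps: int = 20_000
    n_genes: int = 4_000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    fraction_dase: float = 0.05
    effect_log2fc_range: Tuple[float, float] = (2.5, 4.0)
    probe_affinity_sdlog: float = 0.3
    noise_sdlog: float = 0.15
    crosstalk: float = 0.01
    background_mean: float = 100.0
    expression_mean: float = 8_000.0
    expression_sdlog: float = 0.5
    intensity_cap: int = 65_535
    fraction_transcribed: float = 0.7
    fraction_cnv: float = 0.02
    low_quality_fraction: float = 0.05
    sanger_peak_height: float = 60.0
    sanger_sdlog: float = 0.1
    sanger_peak_cap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_samples >= 1, "n_samples must be >= 1")
        _check(self.n_snps >= 1, "n_snps must be >= 1")
        _check(self.n_genes >= 1, "n_genes must be >= 1")
        _check(self.n_snps >= self.n_genes, "n_snps must be >= n_genes")
        lo, hi = self.maf_range
        _check(0 < lo <= hi < 1 or (lo == hi and 0 <= lo < 1),
               "maf_range must lie in [0, 1) with lo <= hi")
        _check(lo <= hi, "maf_range must be ordered")
        _check(0 <= self.fraction_dase <= 1, "fraction_dase must be in [0, 1]")
        elo, ehi = self.effect_log2fc_range
        _check(elo >= 0 and ehi >= elo,
               "effect_log2fc_range must be non-negative and ordered")
        _check(self.probe_affinity_sdlog >= 0, "probe_affinity_sdlog must be >= 0")
        _check(self.noise_sdlog >= 0, "noise_sdlog must be >= 0")
        _check(0 <= self.crosstalk < 0.5, "crosstalk must be in [0, 0.5)")
        _check(self.background_mean >= 0, "background_mean must be >= 0")
        _check(self.expression_mean > 0, "expression_mean must be > 0")
        _check(self.intensity_cap >= 1, "intensity_cap must be >= 1")
        _check(0 <= self.fraction_transcribed <= 1,
               "fraction_transcribed must be in [0, 1]")
        _check(0 <= self.fraction_cnv <= 1, "fraction_cnv must be in [0, 1]")
        _check(0 <= self.low_quality_fraction <= 1,
               "low_quality_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("maf_range", "effect_log2fc_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """Thresholds and switches of the filtering/testing pipeline.

    Defaults are the published analysis constants: combined cDNA intensity
    cut-off 500, candidate thresholds DASE >= 2.00 / P <= 0.01 / FDR <= 0.05,
    heterozygote support >= 3 of 8 samples, sequencing event threshold
    DASE > 1.
    """

    intensity_min: float = 500.0
    dase_min: float = 2.0
    p_max: float = 0.01
    fdr_max: float = 0.05
    min_het: int = 3
    seq_threshold: float = 1.0
    array_event_threshold: float = 2.0
    pseudocount: float = 1.0
    genotype_quality_min: float = 0.15
    background_method: str = "percentile"
    pvalue_method: str = "tail"
    two_sided: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.intensity_min >= 0, "intensity_min must be >= 0")
        _check(self.dase_min >= 0, "dase_min must be >= 0")
        _check(0 < self.p_max <= 1, "p_max must be in (0, 1]")
        _check(0 < self.fdr_max <= 1, "fdr_max must be in (0, 1]")
        _check(self.min_het >= 1, "min_het must be >= 1")
        _check(self.pseudocount > 0, "pseudocount must be > 0")
        _check(0 <= self.genotype_quality_min <= 1,
               "genotype_quality_min must be in [0, 1]")
        _check(self.background_method in ("percentile", "none"),
               "background_method must be 'percentile' or 'none'")
        _check(self.pvalue_method in ("tail", "glm"),
               "pvalue_method must be 'tail' or 'glm'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return asdict(self)
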