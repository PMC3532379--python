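import pytest

from dasescan import PipelineConfig, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort with planted effects, shared across tests."""
    cfg = SimConfig(n_snps=2000, n_genes=400, seed=3)
    return cfg, simulate_cohort(cfg)


def zero_noise_config(**overrides) -> SimConfig:
    """A configuration in which every stochastic intensity term is off.

    Probe affinities, channel noise, expression spread, background and
    crosstalk are all zero and the planted effect is exactly 2 (a 4-fold
    allelic imbalance), so intensities are exact integers and the
    downstream DASE must equal the planted effect to machine precision.
    """
    base = dict(n_snps=2000, n_genes=400, fraction_dase=0.3,
                effect_log2fc_range=(2.0, 2.0), probe_affinity_sdlog=0.0,
                noise_sdlog=0.0, expression_sdlog=0.0, crosstalk=0.0,
                background_mean=0.0, expression_mean=10_000.0,
                low_quality_fraction=0.0, seed=9)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    cfg = zero_noise_config()
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def default_pipeline_config():
    return PipelineConfig()
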