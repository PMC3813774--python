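import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from fgrtools.synthetic import (
    CellMeans,
    GeneratorConfig,
    attach_tracer_data,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-calibration cohort with tracer data attached."""
    cfg = GeneratorConfig(seed=11)
    litters, fetuses = generate_cohort(cfg)
    plasma = attach_tracer_data(litters, fetuses, cfg)
    return cfg, litters, fetuses, plasma


@pytest.fixture()
def null_group_means():
    """Identical cell means everywhere: no genotype or treatment effect."""
    m = CellMeans(1.0, 0.08, 28.0, 25.0, 24.0)
    return {(g, t): m for g in ("WT", "P0") for t in ("water", "SC")}


@pytest.fixture()
def zero_noise_config():
    return GeneratorConfig(
        seed=5,
        plasma_noise_cv=0.0,
        accumulation_noise_cv=0.0,
        trace_noise_sd=0.0,
        true_kmf=100.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
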