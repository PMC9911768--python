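import numpy as np
import pytest

from bivatlas.synthetic import (
    CohortConfig,
    GroupConfig,
    PlantedMode,
    Resolution,
    ShapeParams,
    generate_cohort,
    generate_template,
)


@pytest.fixture(scope="session")
def template():
    """Default reference template surface with its analytic volumes."""
    surf, truth = generate_template()
    return surf, truth


def small_cohort_config(seed=0, **overrides):
    """A fast cohort: fewer subjects, default geometry and noise."""
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.pvr.n = 10
    cfg.no_pvr.n = 8
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config(seed=0))


@pytest.fixture(scope="session")
def clean_pair():
    """One subject with no noise, no planted shape variation and no
    misalignment: measured strains should match the analytic truth up to
    mesh discretization."""
    cfg = CohortConfig(seed=4, vertex_noise_sd=0.0, misalign_rot_deg=0.0,
                       misalign_trans_mm=0.0, planted_modes=[])
    cfg.pvr.n = 2
    cfg.no_pvr.n = 1
    co = generate_cohort(cfg)
    return co


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
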