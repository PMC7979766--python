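import numpy as np
import pytest

from metasurv.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Eight desk-scale patients (32 voxels at 2 mm) with a volume-driven hazard."""
    cfg = GeneratorConfig(
        n_patients=8, volume_shape=32, voxel_spacing=2.0,
        event_prevalence_target=0.3, hazard_coefficients=(2.0, 0.0, 0.0),
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """200 desk-scale patients for workflow-level tests."""
    cfg = GeneratorConfig(
        n_patients=200, volume_shape=32, voxel_spacing=2.0,
        event_prevalence_target=0.3, hazard_coefficients=(3.0, 0.0, 0.0),
        seed=7,
    )
    return cfg, generate_cohort(cfg)
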