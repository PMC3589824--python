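import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dcnsim import (
    GeneratorConfig,
    SomaCloud,
    calibrate_scale,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def calibrated_config(default_config) -> GeneratorConfig:
    """Generator config with scale calibrated to the 0.17-nad threshold."""
    return calibrate_scale(
        default_config, threshold=0.17, target_mean_neighbors=7.0, n_trials=24, seed=0
    )


@pytest.fixture(scope="session")
def small_cohort(calibrated_config):
    """Six calibrated clouds — enough for distribution-level checks."""
    return generate_cohort(calibrated_config, 6, seed=2024)


@pytest.fixture(scope="session")
def cohort16(calibrated_config):
    """The standard 16-cluster cohort used for prediction runs."""
    return generate_cohort(calibrated_config, 16, seed=2024)


def make_cloud(points, **kw) -> SomaCloud:
    return SomaCloud(cluster_id="test", points=np.asarray(points, float), **kw)


@pytest.fixture
def path_cloud() -> SomaCloud:
    """Three collinear soma forming a path graph a-b-c at threshold 0.17."""
    return make_cloud([[0.0, 0.0, 0.0], [0.0, 0.15, 0.0], [0.0, 0.30, 0.0]])
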