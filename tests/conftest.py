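import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    from ivcm_dryeye import default_config

    return default_config()


@pytest.fixture(scope="session")
def replicate_cohorts(default_config):
    """Twenty replicate default cohorts (fixed seeds), shared across tests."""
    from ivcm_dryeye.cohort import generate_cohort_frame

    return [generate_cohort_frame(default_config, seed=1000 + i) for i in range(20)]


@pytest.fixture(scope="session")
def single_cohort(replicate_cohorts):
    return replicate_cohorts[0]


@pytest.fixture(scope="session")
def small_config(default_config):
    """A fast-calibrating scaled-down config for structural tests."""
    import dataclasses

    groups = tuple(
        dataclasses.replace(g, n=6 if g.name == "AIDED" else 14)
        for g in default_config.groups
    )
    return dataclasses.replace(
        default_config,
        name="test_small",
        groups=groups,
        calibration=dataclasses.replace(default_config.calibration, n_calib=10_000),
    )
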