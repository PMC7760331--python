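import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupilarousal import CohortConfig, generate_cohort

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

logging.getLogger("pupilarousal").setLevel(logging.ERROR)


def clean_config(**kwargs) -> CohortConfig:
    """Artifact-free, noise-free config for exactness tests."""
    base = dict(n_control=2, n_depressed=3, noise_sd=0.0, blink_rate=0.0,
                gaze_excursion_prob=0.0, missing_run_prob=0.0,
                target_corr_dilation_symptoms=0.0, target_corr_dilation_rt=0.0,
                seed=0)
    base.update(kwargs)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully realistic cohort (artifacts, noise, effects)."""
    cfg = CohortConfig(n_control=6, n_depressed=9, seed=42)
    datasets, gt = generate_cohort(cfg)
    return cfg, datasets, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
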