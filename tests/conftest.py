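import numpy as np
import pandas as pd
import pytest

from eq5dsim.cohort import CohortConfig, generate_cohort, gr_like
from eq5dsim.scoring import score_dataset, synthetic_5l_value_set, toy_linear_value_set


@pytest.fixture(scope="session")
def toy_vs():
    return toy_linear_value_set()


@pytest.fixture(scope="session")
def default_vs():
    return synthetic_5l_value_set()


@pytest.fixture(scope="session")
def gr_cohort(default_vs):
    """One scored GR-like cohort (n=450, 2 timepoints), complete."""
    return score_dataset(generate_cohort(gr_like(seed=42)), default_vs)


@pytest.fixture(scope="session")
def big_cohort(default_vs):
    """Large cohort for Monte-Carlo checks of the generator's mechanisms."""
    return score_dataset(generate_cohort(gr_like(seed=7, n_subjects=10_000)), default_vs)


def make_degenerate_config(**overrides) -> CohortConfig:
    """All-noise-off configuration: every latent propensity is exactly 0."""
    base = dict(
        n_subjects=20,
        n_timepoints=2,
        latent_loadings={"age": 0, "gender": 0, "marital": 0, "academic": 0, "srh": 0},
        time_effect=(0.0, 0.0),
        random_intercept_sd=0.0,
        residual_sd=0.0,
        thresholds=(0.5, 1.0, 1.5, 2.0),
        seed=1,
    )
    base.update(overrides)
    return CohortConfig(**base)
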