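import pytest
from hypothesis import HealthCheck, settings

from pomarch.synthetic import (
    SyntheticConfig,
    generate_internode_dataset,
    generate_leaf_dataset,
)

settings.register_profile(
    "pomarch",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pomarch")


def zero_noise_config(**overrides) -> SyntheticConfig:
    """Zero-noise generator configuration used for closure checks.

    Leaf counts start at 3: at nl = 2 a bourse shoot with beta = 0.5 would
    need a zero-area second leaf for the allometry to hold exactly.
    """
    base = dict(
        leaf_area_noise_cv=0.0,
        beta_noise_cv=0.0,
        ecc_noise_sd=0.0,
        internode_noise_sd=0.0,
        nl_range={"BS": (3, 18), "RO": (3, 18), "VS": (3, 18)},
        n_bs={"AR": 25, "FU": 25, "RB": 25},
        n_ro={"AR": 25, "FU": 25, "RB": 25},
        n_vs={"AR": 8, "FU": 8},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_leaf_dataset():
    """One default-noise leaf dataset at the study's sample sizes."""
    return generate_leaf_dataset(SyntheticConfig(), seed=101)


@pytest.fixture(scope="session")
def default_internode_dataset():
    return generate_internode_dataset(SyntheticConfig(), seed=101)


@pytest.fixture(scope="session")
def slope_exact_dataset():
    """Zero-noise dataset satisfying TLA = beta * nl * Amax exactly."""
    return generate_leaf_dataset(zero_noise_config(), seed=7)


@pytest.fixture(scope="session")
def shape_exact_dataset():
    """Zero-noise dataset lying exactly on the Lorentz profile."""
    return generate_leaf_dataset(
        zero_noise_config(profile_mode="shape-exact", ro_peak_mode="continuous"),
        seed=8,
    )
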