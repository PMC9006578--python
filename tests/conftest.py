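import numpy as np
import pytest

from colonykin.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_population():
    """One full default-design simulation shared by read-only tests."""
    cfg = SimConfig(seed=101)
    table, meta, truth = simulate_population(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def clean_population():
    """Default design with all error rates zero (exact pedigree genotypes)."""
    cfg = SimConfig(seed=202, dropout_rate=0.0, missing_rate=0.0)
    table, meta, truth = simulate_population(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def single_region_colonies():
    """200 colonies, half monogyne half polygyne, one panmictic region."""
    cfg = SimConfig(
        seed=303,
        n_regions=1,
        region_coords=[(51.0, -115.0)],
        colonies_per_region=200,
        social_mix={
            "monogyne": 0.5,
            "polygynous": 0.5,
            "polyandrous": 0.0,
            "oligogynous": 0.0,
        },
    )
    table, meta, truth = simulate_population(cfg)
    return cfg, table, meta, truth
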