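import numpy as np
import pytest

from sldep.simulate import (
    PlantedGene,
    ProteinConfig,
    ScreenConfig,
    SimConfig,
    simulate_cohort,
    simulate_modifier_screen,
)


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A cohort sized for unit tests: every planted structure, tiny runtime."""
    defaults = dict(
        seed=seed,
        n_models=300,
        frac_deleted=0.15,
        frac_msih=0.25,
        n_genes=120,
        noise_sd=0.2,
        n_sites=50,
        n_expression_features=20,
        protein=ProteinConfig(n_noise_proteins=10),
        screen=ScreenConfig(
            n_target_genes=10,
            n_guides_per_gene=2,
            n_negative_controls=7,
            n_positive_controls=7,
        ),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def modifier_screen_data(cohort):
    return simulate_modifier_screen(cohort.config, cohort.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
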