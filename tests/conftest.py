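import numpy as np
import pytest

from pabaflux import SyntheticStudyConfig, TracerScheme

#: Published cohort means: excess ([1-13C], [2-13C], [1,2-13C2]) acetyl, %.
SOLUTION_1 = (0.4, 1.1, 2.0)
SOLUTION_2 = (1.1, 2.6, 5.3)


@pytest.fixture
def scheme() -> TracerScheme:
    return TracerScheme()


@pytest.fixture
def solution1_config() -> SyntheticStudyConfig:
    e1, e2, e12 = SOLUTION_1
    return SyntheticStudyConfig(excess_1_13c=e1, excess_2_13c=e2,
                                excess_12_13c2=e12, noise_sd=0.0)


@pytest.fixture
def solution2_config() -> SyntheticStudyConfig:
    e1, e2, e12 = SOLUTION_2
    return SyntheticStudyConfig(excess_1_13c=e1, excess_2_13c=e2,
                                excess_12_13c2=e12, noise_sd=0.0)


def random_flux_config(rng: np.random.Generator):
    """A random mass-balanced flux configuration for property tests."""
    from pabaflux import FluxConfig
    pdh = rng.uniform(0.05, 0.6)
    glc = rng.uniform(0.0, 1.0)
    fru = rng.uniform(0.0, 1.0)
    unl = rng.uniform(0.0, 1.0) + max(0.0, pdh - glc - fru)  # cover PDH demand
    return FluxConfig(
        pdh_flux=pdh,
        pyruvate_cycling_flux=rng.uniform(0.0, 4.0),
        anaplerotic_unlabeled_inflow=rng.uniform(0.0, 3.0),
        glycolytic_feed={"glucose": glc, "fructose": fru, "unlabeled": unl},
    )


def random_tracer_scheme(rng: np.random.Generator) -> TracerScheme:
    return TracerScheme(
        fructose_labeled_fraction=rng.uniform(0.1, 1.0),
        glucose_labeled_fraction=rng.uniform(0.1, 1.0),
        tracer_purity=rng.uniform(0.9, 1.0),
    )
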