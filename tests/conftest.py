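import numpy as np
import pytest

from latentdim.synthetic import (
    CohortSpec,
    PlantedDimension,
    default_family_blocks,
    generate_cohort,
)


def planted_cohort(
    seed: int,
    n: int = 400,
    rho: float = 0.6,
    families: str = "twins",
    h2: float = 0.5,
    brain_blocks=(("GMV", 50), ("CT", 10), ("SA", 10)),
    n_behaviour: int = 12,
    n_dims: int = 1,
) -> "Cohort":
    spec = CohortSpec(
        n_participants=n,
        family_blocks=default_family_blocks(n, families, seed),
        n_behaviour=n_behaviour,
        brain_blocks=list(brain_blocks),
        planted_dimensions=[PlantedDimension(rho=rho) for _ in range(n_dims)],
        h2_target=h2,
        seed=seed,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort shared across read-only tests."""
    return planted_cohort(seed=11, n=300)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
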