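import numpy as np
import pytest
from hypothesis import settings

from bsaseq.simulate import SimulationConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_loci_primers():
    from bsaseq.simulate import default_loci

    return default_loci()


@pytest.fixture(scope="session")
def small_config():
    """A read-level config small enough for per-test pipelines."""
    return SimulationConfig.default(
        seed=11,
        n_per_population=(2, 3),
        depth_per_locus={"ACTB": 40.0, "BDNF": 40.0, "CRF": 40.0, "NR3C1": 40.0},
        depth_log_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
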