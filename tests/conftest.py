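import numpy as np
import pytest

from enclavoc.segregation import AreaUnit, RegionCounts
from enclavoc.synthetic import GeneratorConfig, simulate


def make_region(counts, region_id="R"):
    """RegionCounts from (api, white, pop) triples."""
    units = [
        AreaUnit(f"u{i}", a, w, p) for i, (a, w, p) in enumerate(counts)
    ]
    return RegionCounts(region_id=region_id, units=tuple(units))


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured synthetic study shared across tests."""
    config = GeneratorConfig(
        n_regions=9,
        units_per_region=12,
        n_enclave_regions=3,
        n_mothers=2500,  # large enough that rare covariate strata have events
        vocs=("benzene", "toluene", "styrene"),
    )
    return simulate(config, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
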