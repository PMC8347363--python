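import warnings

import pytest

from scntkit.simulate import SimConfig, simulate_dataset

#: smaller-than-default study used where the test only needs structure,
#: not the full default gene universe
SMALL = SimConfig(
    seed=7,
    n_background_genes=300,
    n_planted_degs=60,
    pathway_deg_count=30,
    cells_per_group=8,
    n_regulon_targets=30,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_dataset(SMALL)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions at seed 42."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def ten_seed_bundles():
    """Default study conditions at seeds 0..9, shared across recovery tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [simulate_dataset(SimConfig(seed=s)) for s in range(10)]
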