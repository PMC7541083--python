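import numpy as np
import pytest

from aplocal import (
    SyntheticKCPopulation,
    ToyMushroomBodySpec,
    make_synthetic_synapses,
    make_toy_skeleton,
    map_synapses,
)


@pytest.fixture(scope="session")
def toy():
    """Y-shaped toy mushroom-body skeleton (two neurites per branch)."""
    return make_toy_skeleton(ToyMushroomBodySpec(seed=7))


@pytest.fixture(scope="session")
def clustered_population(toy):
    """Clustered synthetic synapses mapped onto the toy skeleton."""
    pop = SyntheticKCPopulation(n_kc=20, synapses_in=50, synapses_out=50,
                                cluster_sigma_um=15.0, seed=11)
    records, subtypes, truth = make_synthetic_synapses(toy, pop)
    mapped = map_synapses(toy.skeleton, records)
    return {"pop": pop, "records": records, "subtypes": subtypes,
            "truth": truth, "mapped": mapped}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
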