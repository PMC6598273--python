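import numpy as np
import pytest

from varguide.fixtures import (PlantSpec, SyntheticSpec, generate_genome,
                               plant_offtargets, random_guide)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(SyntheticSpec(genome_length=5000, rng_seed=11))


@pytest.fixture(scope="session")
def guide():
    return random_guide(np.random.default_rng(17))


@pytest.fixture(scope="session")
def planted(guide):
    """A 20 kb genome with sites planted at 0..4 mismatches, both strands."""
    genome = generate_genome(SyntheticSpec(genome_length=20_000, rng_seed=23))
    plant = PlantSpec(guide=guide, n_sites=5,
                      mismatch_counts=(0, 1, 2, 3, 4), strand_mix=0.4)
    return plant_offtargets(genome, plant, seed=29)
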