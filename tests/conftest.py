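import numpy as np
import pytest

import circulome as c


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb circular genome with short planted repeats, an AT-rich origin
    window and a few genes — shared read-only across tests."""
    spec = c.GenomeSpec(
        length=20_000,
        gc_background=0.45,
        repeats=[c.RepeatPlan("direct", 40), c.RepeatPlan("inverted", 35)],
        origin=(6_000, 200, 0.9),
        genes=[c.GenePlan("CDS", 6, (300, 600))],
        seed=7,
    )
    genome, features, truth = c.generate_genome(spec)
    return genome, features, truth


@pytest.fixture(scope="session")
def small_library(small_genome):
    """An error-free 63 bp paired-end library over the small genome, dense
    enough for single-contig assembly."""
    genome, _, _ = small_genome
    spec = c.LibrarySpec(read_length=63, insert_mean=350.0, n_pairs=17_000, seed=11)
    return c.simulate_read_library(genome, spec)


def random_seq(rng, n):
    return "".join(rng.choice(np.array(list("ACGT")), size=n))
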