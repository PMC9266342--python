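import numpy as np
import pytest

from clusterhop.core import GenomeSequence, Region
from clusterhop.sim import make_reference, plant_cluster_duplication, simulate_paired_reads


@pytest.fixture(scope="session")
def toy_reference() -> GenomeSequence:
    """Two small chromosomes, enough to exercise mapping and depth."""
    return make_reference(2, [20000, 15000], 0.40, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """A scaled-down planted-duplication sample: 3 x 60 kb chromosomes,
    4 kb donor at the end of chrIII, one interior insertion on chrI.
    The donor spans 4 windows: with fewer, the elevated windows dominate
    the CBS permutation null themselves and the segment is (correctly)
    not significant at this chromosome size."""
    ref = make_reference(3, [60000, 60000, 60000], 0.38, seed=5)
    donor = Region("chrIII", 56000, 60000)
    sample, truth = plant_cluster_duplication(ref, donor, [("chrI", 30000)], seed=5)
    reads = simulate_paired_reads(sample, 20.0, 151, 500, 12.5, 0.002, seed=6)
    return ref, sample, donor, truth, reads
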