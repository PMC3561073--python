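import numpy as np
import pytest

from bach3d.contact_data import ContactMatrix, GenomicBin, LocusFeatures
from bach3d.simulate import SimScenario, simulate_single_population


@pytest.fixture
def small_bins():
    return [GenomicBin("chr1", i * 40_000, (i + 1) * 40_000) for i in range(5)]


@pytest.fixture
def small_cm(small_bins):
    counts = np.array([
        [0, 5, 2, 1, 0],
        [5, 0, 7, 3, 1],
        [2, 7, 0, 6, 2],
        [1, 3, 6, 0, 4],
        [0, 1, 2, 4, 0],
    ])
    return ContactMatrix(small_bins, counts)


@pytest.fixture
def small_lf():
    return LocusFeatures(frag_ends=[10, 20, 15, 30, 12],
                         gc=[0.4, 0.5, 0.45, 0.55, 0.42],
                         mappability=[0.9, 0.95, 0.85, 0.99, 0.92])


@pytest.fixture
def sim_instance():
    """A 10-locus single-population simulation with its generating truth."""
    sc = SimScenario(n_loci=10, seed=7, mean_count=30)
    cm, truth = simulate_single_population(sc)
    return cm, truth
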