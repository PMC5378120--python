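import numpy as np
import pytest

from namkit.io import GenotypeMatrix, MarkerInfo
from namkit.linkage import GeneticMap, LinkageGroup
from namkit.simulate import (SimulationConfig, simulate_ssd_population,
                             uniform_genome)


def truth_map(truth) -> GeneticMap:
    """GeneticMap from a TruthRecord's rearranged marker layout."""
    lgs = []
    for i, (chrom, d) in enumerate(truth.true_map.items()):
        pos = np.asarray(d["positions"], float)
        if len(pos) == 0:
            continue
        lgs.append(LinkageGroup(f"LG{i + 1}", list(d["markers"]), pos - pos[0], chrom))
    return GeneticMap(truth.population_id, lgs)


@pytest.fixture(scope="session")
def small_genome():
    return uniform_genome(3, 10, 110.0)


@pytest.fixture(scope="session")
def small_population(small_genome):
    cfg = SimulationConfig(genome=small_genome, n_individuals=150,
                           generation=4, seed=42, population_id="pop42")
    return simulate_ssd_population(cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-written 4-marker x 6-individual matrix."""
    markers = [MarkerInfo(f"m{i}", "1A") for i in range(4)]
    calls = np.array(
        [
            [0, 0, 1, 2, 2, 0],
            [0, 0, 1, 2, 2, 0],
            [0, 1, 1, 2, 2, -1],
            [2, 2, 1, 0, 0, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix("tiny", markers, [f"i{j}" for j in range(6)], calls,
                          generation=4)
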