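import numpy as np
import pytest

from rdstreeboot.population_graph import PopulationGraph
from rdstreeboot.rds_simulator import ForestDesign, RecruitmentForest


@pytest.fixture
def triangle():
    return PopulationGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)], [1, 0, 1])


@pytest.fixture
def path3():
    # a - b - c
    return PopulationGraph.from_edges(3, [(0, 1), (1, 2)], [0, 1, 0])


@pytest.fixture
def star():
    # centre 0 with three leaves; degrees (3, 1, 1, 1)
    return PopulationGraph.from_edges(4, [(0, 1), (0, 2), (0, 3)], [1, 0, 0, 0])


def random_connected_graph(num_vertices: int, rng: np.random.Generator) -> PopulationGraph:
    """G(n, p) conditioned on connectivity, with random traits."""
    for _ in range(200):
        edges = [
            (i, j)
            for i in range(num_vertices)
            for j in range(i + 1, num_vertices)
            if rng.random() < 0.4
        ]
        trait = rng.integers(0, 2, size=num_vertices)
        g = PopulationGraph.from_edges(num_vertices, edges, trait)
        if g.is_connected() and (g.degrees > 0).all():
            return g
    raise RuntimeError("failed to draw a connected graph")


def random_forest(design: ForestDesign, rng: np.random.Generator) -> RecruitmentForest:
    """A forest with random binary traits and random positive degrees."""
    n = design.num_nodes
    return RecruitmentForest(
        design=design,
        trait=rng.integers(0, 2, size=n),
        degree=rng.integers(1, 8, size=n),
    )
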