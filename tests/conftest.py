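import numpy as np
import pytest

from commute_exposure.models import ConcentrationGrid, RoadNetwork, Segment
from commute_exposure.synthetic import ScenarioConfig, generate_network


def build_network(nodes: dict, edges: list) -> RoadNetwork:
    """Small hand-built network: edges as (u, v, road_class) tuples."""
    segments = []
    for sid, (u, v, cls) in enumerate(edges):
        segments.append(Segment(id=sid, u=u, v=v, points=[nodes[u], nodes[v]], road_class=cls))
    return RoadNetwork(nodes=dict(nodes), segments=segments)


@pytest.fixture
def small_config():
    return ScenarioConfig(
        domain_extent=(0.0, 0.0, 800.0, 800.0),
        street_spacing=200.0,
        n_subjects=30,
        seed=42,
    )


@pytest.fixture
def small_network(small_config):
    return generate_network(small_config)


@pytest.fixture
def uniform_grid():
    return ConcentrationGrid(
        x0=0.0, y0=0.0, cell_size=25.0, values=np.full((8, 8), 40.0), model_name="uniform"
    )


@pytest.fixture
def triangle_network():
    nodes = {0: (0.0, 0.0), 1: (3.0, 0.0), 2: (0.0, 4.0)}
    # edge lengths 3, 4 and 5
    return build_network(nodes, [(0, 1, "main"), (0, 2, "main"), (1, 2, "main")])
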