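import numpy as np
import pytest
from hypothesis import settings

from mask2skel import CameraView, RunConfig, SkeletonGraph, edges_to_logits

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def frontal_camera() -> CameraView:
    """Camera at the origin looking down +z, 32x32, f=100 px."""
    return CameraView(fx=100.0, fy=100.0, cx=16.0, cy=16.0, width=32, height=32,
                      rotation=np.eye(3), translation=np.zeros(3))


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def path_graph() -> SkeletonGraph:
    """Three collinear nodes a-b-c along x."""
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    return SkeletonGraph(positions=pos, radii=[0.1, 0.1, 0.1],
                         adjacency_logits=edges_to_logits(3, [(0, 1), (1, 2)]))


def random_tree_graph(k: int, seed: int = 0) -> SkeletonGraph:
    """Random tree: node i attaches to a uniformly chosen earlier node."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, (k, 3))
    edges = [(int(rng.integers(0, i)), i) for i in range(1, k)]
    return SkeletonGraph(positions=pos, radii=rng.uniform(0.01, 0.1, k),
                         adjacency_logits=edges_to_logits(k, edges))
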