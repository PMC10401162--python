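import numpy as np
import pytest

from otfrm import FeatureSpace, OTConfig, SyntheticSpaceSpec, TaskEmbeddingSet


@pytest.fixture
def exact_cfg() -> OTConfig:
    return OTConfig(solver="exact")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_space(rng) -> FeatureSpace:
    """Three well-behaved random tasks (m=6, d=4)."""
    tasks = [
        TaskEmbeddingSet(task_id=f"t{k}", embeddings=rng.standard_normal((6, 4)) + 1.0)
        for k in range(3)
    ]
    return FeatureSpace(tasks)


@pytest.fixture
def tri_space() -> FeatureSpace:
    """Singleton tasks at (1,0), (0,1) and the 45-degree unit vector."""
    s = np.sqrt(2) / 2
    return FeatureSpace(
        [
            TaskEmbeddingSet(task_id="task1", embeddings=[[1.0, 0.0]]),
            TaskEmbeddingSet(task_id="task2", embeddings=[[0.0, 1.0]]),
            TaskEmbeddingSet(task_id="task3", embeddings=[[s, s]]),
        ]
    )


@pytest.fixture
def default_spec() -> SyntheticSpaceSpec:
    return SyntheticSpaceSpec(K=4, m=20, d=8, delta=2.0, sigma=1.0, seed=7)
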