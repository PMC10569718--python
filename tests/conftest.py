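import numpy as np
import pytest

from mtlcox import (
    FeatureRegistry,
    MultiTaskDataset,
    SurvivalTask,
)


@pytest.fixture
def two_subject_task() -> SurvivalTask:
    """The smallest nontrivial Cox problem: 2 subjects, both events, 1 feature."""
    return SurvivalTask(
        "toy",
        features=np.array([[1.0], [0.0]]),
        time=np.array([1.0, 2.0]),
        event=np.array([1, 1]),
    )


def random_task(
    rng: np.random.Generator,
    n: int = 30,
    p: int = 4,
    censor_frac: float = 0.3,
    name: str = "rand",
    allow_ties: bool = False,
) -> SurvivalTask:
    """A random censored PH task for oracle comparisons."""
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 0.5, p)
    T = -np.log(rng.uniform(size=n)) / (0.2 * np.exp(X @ beta))
    if allow_ties:
        T = np.ceil(T * 4) / 4  # coarse grid induces tied times
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    time = np.where(event == 1, T, T * rng.uniform(0.2, 1.0, n))
    time = np.maximum(time, 1e-6)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    return SurvivalTask(name, X, time, event)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_dataset(tasks) -> MultiTaskDataset:
    p = tasks[0].n_features
    registry = FeatureRegistry(
        tuple(f"x{j}" for j in range(p)), tuple("continuous" for _ in range(p))
    )
    return MultiTaskDataset(list(tasks), registry)
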