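import numpy as np
import pytest

import pantop


@pytest.fixture(scope="session")
def small_spec() -> pantop.SyntheticSpec:
    """A scaled-down two-organ benchmark used across the unit suite."""
    return pantop.SyntheticSpec(
        organs={"kidney": 2, "heart": 1},
        n_genes=300,
        n_samples_range=(30, 30),
        organ_specific={"kidney": (5, 1.0), "heart": (5, 1.0)},
    )


@pytest.fixture(scope="session")
def small_collection(small_spec):
    return pantop.generate_collection(small_spec, seed=11)


@pytest.fixture(scope="session")
def fast_config() -> pantop.TOPConfig:
    return pantop.TOPConfig(n_features=10, loss="squared", n_lambda=15, seed=0)


def make_array_dataset(
    M: np.ndarray,
    y,
    dataset_id: str = "d1",
    organ: str = "kidney",
    genes=None,
    samples=None,
) -> pantop.ExpressionDataset:
    """Wrap a log2-scale matrix as an array dataset (2**M - 1 intensities)."""
    M = np.asarray(M, dtype=float)
    genes = genes or [f"g{i}" for i in range(M.shape[0])]
    samples = samples or [f"s{j}" for j in range(M.shape[1])]
    return pantop.ExpressionDataset(
        dataset_id=dataset_id,
        organ=organ,
        platform="array",
        tissue="biopsy",
        genes=genes,
        samples=samples,
        X=np.maximum(2.0**M - 1.0, 0.0),
        y=np.asarray(y, dtype=int),
    )


def dyadic(rng: np.random.Generator, shape, scale=16.0, grid=2.0**-12):
    """Random values on a dyadic grid: sums/differences are exact in floats."""
    return np.round(rng.uniform(0, scale, size=shape) / grid) * grid
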