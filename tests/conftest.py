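from __future__ import annotations

import numpy as np
import pytest

from coreclust.geometry import DistanceMatrix
from coreclust.synthetic import SyntheticSpec, make_dataset, make_fixture


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A 3-homolog, 2-cluster instance small enough for per-test reuse."""
    return SyntheticSpec(
        n_homologs=3,
        core_len=16,
        n_models_per_homolog=10,
        n_clusters=2,
        within_sigma=1.0,
        between_shift=12.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return make_dataset(small_spec)


@pytest.fixture(scope="session")
def small_fixture_dir(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths, truth = make_fixture(small_spec, out)
    return paths, truth


def random_metric_matrix(
    n: int, rng: np.random.Generator, scale: float = 8.0, prefix: str = "m"
) -> DistanceMatrix:
    """Euclidean distance matrix of random 3D points (a valid metric)."""
    pts = rng.uniform(0, scale, size=(n, 3))
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(values, 0.0)
    ids = tuple(f"{prefix}#{i:03d}" for i in range(n))
    return DistanceMatrix(ids=ids, values=values)
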