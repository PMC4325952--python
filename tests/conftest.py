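import numpy as np
import pandas as pd
import pytest

from spatmiss.datasets import SpatialDataset
from spatmiss.fields import SpdeFieldModel
from spatmiss.inference import GridSettings
from spatmiss.mesh import build_mesh
from spatmiss.synthetic import GeneratorConfig, generate_dataset

#: reduced-scale settings shared by the slower integration fixtures
SMALL_GRID = GridSettings(size=5, max_expansions=1, mode_search_budget=60)


@pytest.fixture(scope="session")
def small_dataset() -> SpatialDataset:
    """n=200 synthetic dataset at the study's default generative values."""
    return generate_dataset(GeneratorConfig(n=200, seed=42))


@pytest.fixture(scope="session")
def small_field_model(small_dataset):
    mesh = build_mesh(
        small_dataset.locations,
        max_edge_inner=8.0,
        max_edge_outer=50.0,
        min_vertex_dist=3.0,
        range_guess=12.7,
    )
    return SpdeFieldModel(mesh, small_dataset.locations)


@pytest.fixture()
def toy_dataset():
    """Deterministic 60-point dataset on a unit-ish square, no field needed."""
    rng = np.random.default_rng(314)
    locs = rng.uniform(0, 10, (60, 2))
    x = rng.normal(0, 1, 60)
    from scipy.special import expit

    y = (rng.random(60) < expit(-0.5 + 0.8 * x)).astype(np.int8)
    return SpatialDataset(locs, pd.DataFrame({"x": x}), y)
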