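import numpy as np
import pytest

from phenocloud.core import PointCloud, SegmentedPlant
from phenocloud.synthetic import StemSpec, SyntheticPlantSpec, default_spec, generate_plant


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_plant():
    """A two-organ plant small enough for exhaustive checks: a 6-point stem
    column and a 4-point square leaf."""
    stem = np.array([[0, 0, z] for z in np.linspace(0, 0.5, 6)], dtype=float)
    leaf = np.array([[0.05, 0.0, 0.30], [0.15, 0.0, 0.30],
                     [0.05, 0.05, 0.30], [0.15, 0.05, 0.30]])
    cloud = PointCloud(points=np.vstack([stem, leaf]))
    return SegmentedPlant(cloud=cloud, stem=np.arange(6),
                          leaves=[np.arange(6, 10)])


@pytest.fixture(scope="session")
def tomato():
    """One moderately dense synthetic tomato-like plant plus ground truth."""
    spec = default_spec("tomato_like", seed=7)
    return generate_plant(spec, density=150.0)


@pytest.fixture(scope="session")
def bare_cylinder():
    """An untapered bare-stem plant: the reference object for diameter and
    view-culling checks."""
    spec = SyntheticPlantSpec("maize_like", StemSpec(0.30, 12.0, 12.0, 12.0), seed=3)
    return generate_plant(spec, density=300.0)
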