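import numpy as np
import pytest

from flocfrac.stack_io import RunConfig, VoxelGeometry


@pytest.fixture
def paper_geometry() -> VoxelGeometry:
    """Wide-field acquisition pitch: 0.092 µm/px, 0.198 µm z step."""
    return VoxelGeometry(0.092, 0.092, 0.198)


@pytest.fixture
def iso_geometry() -> VoxelGeometry:
    return VoxelGeometry(1.0, 1.0, 1.0)


@pytest.fixture
def config(paper_geometry) -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_particle(mask: np.ndarray, geometry: VoxelGeometry, label: int = 1,
                  condition: str = ""):
    """Build a Particle directly from a boolean mask (origin at 0)."""
    from flocfrac.reconstruction import Particle

    idx = np.argwhere(mask)
    box = tuple(slice(0, s) for s in mask.shape)
    return Particle(label=label, voxel_indices=idx, bounding_box=box,
                    geometry=geometry, condition=condition)


@pytest.fixture
def particle_factory():
    return make_particle
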