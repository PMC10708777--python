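import numpy as np
import pytest

from tartes import AngioVolume, StructuralVolume, VoxelGrid, default_phantom_spec, simulate


def make_grid(n_z=8, n_y=4, n_x=4, pitch_z=8.1, pitch_x=2.3, pitch_y=2.2) -> VoxelGrid:
    return VoxelGrid(pitch_z_um=pitch_z, pitch_x_um=pitch_x, pitch_y_um=pitch_y,
                     shape=(n_z, n_y, n_x))


def column_angio(values, pitch_z=8.1) -> AngioVolume:
    """Single-A-scan AngioVolume from a 1-D sequence of layer values."""
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return AngioVolume(grid=make_grid(values.shape[0], 1, 1, pitch_z=pitch_z), values=values)


def column_structural(values, pitch_z=8.1) -> StructuralVolume:
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return StructuralVolume(grid=make_grid(values.shape[0], 1, 1, pitch_z=pitch_z),
                            values=values)


def random_angio(rng, shape=(16, 8, 8), scale=10.0) -> AngioVolume:
    return AngioVolume(grid=make_grid(*shape), values=rng.uniform(0, scale, size=shape))


def random_structural(rng, shape=(16, 8, 8), scale=10.0) -> StructuralVolume:
    return StructuralVolume(grid=make_grid(*shape), values=rng.uniform(0, scale, size=shape))


@pytest.fixture(scope="session")
def default_phantom():
    """The reference vessel phantom (noise-free, unit transmittance)."""
    spec = default_phantom_spec()
    return simulate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20231121)
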