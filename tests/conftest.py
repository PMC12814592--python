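import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanoburden.stack import ImageGrid, PsfModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def psf() -> PsfModel:
    return PsfModel()


@pytest.fixture()
def small_grid() -> ImageGrid:
    """A compact stack geometry at the reference voxel sizes."""
    return ImageGrid(nx=96, ny=96, nz=32)


def constant_blob_stack(grid: ImageGrid, voxel_indices, value: float = 100.0,
                        background: float = 0.0):
    """Hand-built stack + label field: one labelled blob of constant
    intensity at the given (z, y, x) indices."""
    from nanoburden.stack import ImageStack

    data = np.full(grid.shape, background, dtype=float)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for (z, y, x) in voxel_indices:
        data[z, y, x] = value
        labels[z, y, x] = 1
    return ImageStack(data=data, grid=grid), labels
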