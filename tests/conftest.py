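import numpy as np
import pytest

from icaseed import BrainMask, FMRIRun, Geometry


@pytest.fixture
def small_geometry() -> Geometry:
    return Geometry.isotropic((4, 4, 2), voxel_mm=3.0, tr=2.0)


@pytest.fixture
def small_run(small_geometry) -> FMRIRun:
    """A 10-volume random run on a full 4x4x2 grid (32 voxels)."""
    rng = np.random.default_rng(7)
    mask = BrainMask.full(small_geometry)
    data = rng.standard_normal((10, mask.v)) + 100.0
    return FMRIRun(data, mask, small_geometry)


def make_run(data: np.ndarray, tr: float = 2.0) -> FMRIRun:
    """Wrap a (t, v) matrix as a run on a flat 1xvx1 grid."""
    t, v = data.shape
    geom = Geometry.isotropic((v, 1, 1), voxel_mm=3.0, tr=tr)
    return FMRIRun(data, BrainMask.full(geom), geom)
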