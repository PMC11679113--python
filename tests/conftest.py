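import numpy as np
import pytest

from augseg.synthetic_data import PhantomSpec, generate_phantom
from augseg.volume_io import LabelMap, ROICatalog, Volume


def make_sphere_mask(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                     radius_mm=10.0, label=1, center=None):
    """A smooth single-ROI sphere mask on an axis-aligned grid."""
    spacing = np.asarray(spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    idx = np.indices(shape, dtype=float)
    mm = idx * spacing.reshape(3, 1, 1, 1)
    if center is None:
        center = (np.asarray(shape) - 1) * spacing / 2.0
    dist2 = sum((mm[k] - center[k]) ** 2 for k in range(3))
    data = np.where(dist2 <= radius_mm ** 2, label, 0).astype(np.int64)
    return LabelMap(data=data, affine=affine, catalog=ROICatalog.generic(label))


@pytest.fixture(scope="session")
def small_phantom():
    """A noise-free 32^3 phantom (volume, truth mask) used across tests."""
    spec = PhantomSpec(shape=(32, 32, 32), spacing=(1.5, 1.5, 1.0),
                       n_rois=2, radius_range_mm=(5.0, 9.0), noise_sd=0.0,
                       seed=42)
    return generate_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the study's default geometry."""
    spec = PhantomSpec(seed=11)
    return generate_phantom(spec) + (spec,)


@pytest.fixture
def sphere_mask():
    return make_sphere_mask()


@pytest.fixture
def box_volume():
    """A 21^3 unit-spacing volume holding a bright off-center box."""
    data = np.full((21, 21, 21), -1000.0, dtype=np.float32)
    data[5:9, 10:14, 8:12] = 100.0
    return Volume(data=data, affine=np.eye(4))
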