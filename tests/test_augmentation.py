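import numpy as np
import pytest
from scipy.stats import chisquare

from augseg import augmentation_engine as aug
from augseg.errors import GridMismatchError
from augseg.metrics import dice_per_class
from augseg.volume_io import Volume

from conftest import make_sphere_mask

SHAPE = (32, 32, 32)
SPACING = (1.5, 1.5, 1.0)
CP = (5, 5, 7)


def _transform(level, seed):
    return aug.sample_augmentation(level, seed, SPACING, SHAPE,
                                   control_points=CP)


def _probe_points(t, n=2000, seed=0):
    rng = np.random.default_rng(seed)
    lo = np.zeros(3)
    hi = (np.asarray(t.shape) - 1) * np.asarray(SPACING)
    return rng.uniform(lo, hi, size=(n, 3))


# ---------------------------------------------------------------------------
# sampling

def test_sampling_is_deterministic():
    for level in (1, 2, 3):
        a = _transform(level, 7)
        b = _transform(level, 7)
        pts = _probe_points(a)
        np.testing.assert_array_equal(a.sampling_map(pts), b.sampling_map(pts))
    r1, r2 = _transform(1, 7).stages[0], _transform(1, 7).stages[0]
    assert r1.angles == r2.angles


@pytest.mark.parametrize("seed", range(25))
def test_rotation_angles_within_range(seed):
    rot = _transform(1, seed).stages[0]
    assert all(-45.0 <= a <= 45.0 for a in rot.angles)


def test_level3_is_elastic_then_rotation():
    t = _transform(3, 5)
    assert len(t.stages) == 2
    assert isinstance(t.stages[0], aug.ElasticDeformation)
    assert isinstance(t.stages[1], aug.RigidRotation)


def test_invalid_level_rejected():
    with pytest.raises(ValueError):
        aug.sample_augmentation(4, 0, SPACING, SHAPE)


def test_sample_level_uniformity():
    levels = np.array([aug.sample_level(s) for s in range(30000)])
    freq = np.bincount(levels, minlength=4)[1:] / levels.size
    assert np.all(freq >= 0.323) and np.all(freq <= 0.343)
    assert aug.sample_level(123) == aug.sample_level(123)


def test_reported_level_proportions_consistent_with_uniform():
    # an observed 309/346/355 split over 1010 draws is compatible with
    # equal likelihood of the three levels
    assert chisquare([309, 346, 355]).pvalue > 0.05


def test_seed_derivation_stable_and_bounded():
    s = aug.derive_seed(17, "scan-003", 4)
    assert s == aug.derive_seed(17, "scan-003", 4)
    assert 0 <= s < 2 ** 31
    assert s != aug.derive_seed(17, "scan-003", 5)


# ---------------------------------------------------------------------------
# application

def test_identity_rotation_preserves_volume(box_volume):
    t = aug.RigidRotation((0, 0, 0), (10, 10, 10), box_volume.shape,
                          box_volume.affine)
    out = aug.apply_to_volume(t, box_volume)
    np.testing.assert_allclose(out.data, box_volume.data, atol=1e-4)


def test_90_degree_rotation_matches_coordinate_oracle(box_volume):
    """A 90-degree z rotation equals a brute-force integer coordinate map."""
    t = aug.RigidRotation((0, 0, 90), (10, 10, 10), box_volume.shape,
                          box_volume.affine)
    out = aug.apply_to_volume(t, box_volume)
    # independent oracle: for each output voxel, source = R^T (x - c) + c
    # computed with exact integer arithmetic for the 90-degree case
    expected = np.full_like(box_volume.data, -1000.0)
    c = 10
    for i in range(21):
        for j in range(21):
            # inverse of 90 deg about z: (x, y) <- (c + (y - c), c - (x - c))
            si = c + (j - c)
            sj = c - (i - c)
            expected[i, j, :] = box_volume.data[si, sj, :]
    np.testing.assert_allclose(out.data, expected, atol=1e-3)


def test_zero_displacement_elastic_is_identity(box_volume):
    cd = np.zeros((3, 4, 4, 4))
    t = aug.ElasticDeformation(cd, box_volume.shape, box_volume.affine)
    out = aug.apply_to_volume(t, box_volume)
    np.testing.assert_allclose(out.data, box_volume.data, atol=1e-4)
    pts = np.random.default_rng(0).uniform(0, 20, (100, 3))
    np.testing.assert_allclose(t.inverse().sampling_map(pts), pts, atol=1e-9)


def test_labels_never_invented(sphere_mask):
    for level, seed in [(1, 3), (2, 4), (3, 5)]:
        t = aug.sample_augmentation(level, seed, sphere_mask.spacing,
                                    sphere_mask.shape, sphere_mask.affine,
                                    control_points=CP)
        out = aug.apply_to_labels(t, sphere_mask)
        assert set(np.unique(out.data)) <= set(np.unique(sphere_mask.data)) | {0}


def test_180_degree_rotation_of_centered_sphere():
    mask = make_sphere_mask()
    center = (np.asarray(mask.shape) - 1) / 2.0  # unit spacing
    t = aug.RigidRotation((0, 0, 180), center, mask.shape, mask.affine)
    out = aug.apply_to_labels(t, mask)
    assert dice_per_class(mask, out).average >= 0.99


def test_nonidentity_transforms_alter_volume(sphere_mask):
    """Augmented volumes visibly differ from the original: > 1% of the
    foreground intensities change.  (Label maps need not change under a
    level-2 deformation — quarter-voxel displacements are sub-voxel.)"""
    vol = Volume(data=np.where(sphere_mask.data > 0, 100.0, -1000.0),
                 affine=sphere_mask.affine)
    fg = sphere_mask.data > 0
    for level, seed in [(1, 1), (2, 2), (3, 3)]:
        t = aug.sample_augmentation(level, seed, vol.spacing, vol.shape,
                                    vol.affine, control_points=CP)
        out = aug.apply_to_volume(t, vol)
        changed = np.abs(out.data - vol.data) > 1.0  # HU
        assert changed[fg].mean() > 0.01


def test_grid_mismatch_rejected(sphere_mask):
    t = aug.sample_augmentation(1, 0, (1, 1, 1), (8, 8, 8))
    with pytest.raises(GridMismatchError):
        aug.apply_to_labels(t, sphere_mask)


# ---------------------------------------------------------------------------
# inversion

def test_rotation_inverse_is_analytic():
    t = aug.sample_augmentation(1, 9, SPACING, SHAPE)
    pts = _probe_points(t)
    back = t.inverse().sampling_map(t.sampling_map(pts))
    assert np.abs(back - pts).max() < 1e-6  # mm


@pytest.mark.parametrize("level,seed", [(1, 10), (2, 11), (3, 12),
                                        (1, 13), (2, 14), (3, 15)])
def test_coordinate_roundtrip_below_quarter_voxel(level, seed):
    t = _transform(level, seed)
    pts = _probe_points(t)
    back = t.inverse().sampling_map(t.sampling_map(pts))
    err_vox = np.abs(back - pts) / np.asarray(SPACING)
    assert err_vox.max() < 0.25


def test_double_inverse_acts_like_original():
    t = _transform(3, 21)
    pts = _probe_points(t)
    np.testing.assert_allclose(t.inverse().inverse().sampling_map(pts),
                               t.sampling_map(pts), atol=1e-3)


@pytest.mark.parametrize("level,seed", [(1, 30), (2, 31), (3, 32)])
def test_mask_roundtrip_dice(level, seed):
    mask = make_sphere_mask(spacing=SPACING)
    t = aug.sample_augmentation(level, seed, SPACING, mask.shape, mask.affine,
                                control_points=CP)
    out = aug.apply_to_labels(t.inverse(), aug.apply_to_labels(t, mask))
    assert dice_per_class(mask, out).average >= 0.95


def test_elastic_control_point_displacements_bounded():
    t = _transform(2, 40).stages[0]
    maxd = t.max_displacement.reshape(3, 1, 1, 1)
    assert np.all(np.abs(t.control_displacements) <= maxd + 1e-12)
    np.testing.assert_allclose(t.max_displacement,
                               np.asarray(SPACING) / 4.0)


def test_transform_serialization_roundtrip(tmp_path):
    t = _transform(3, 50)
    path = tmp_path / "t.json"
    aug.save_transform(t, path)
    back = aug.load_transform(path)
    pts = _probe_points(t)
    np.testing.assert_allclose(back.sampling_map(pts), t.sampling_map(pts),
                               atol=1e-9)
    np.testing.assert_allclose(back.inverse().sampling_map(pts),
                               t.inverse().sampling_map(pts), atol=1e-6)


def test_fill_value_used_outside_grid():
    data = np.full((16, 16, 16), 500.0, dtype=np.float32)
    v = Volume(data=data, affine=np.eye(4))
    t = aug.RigidRotation((0, 0, 45), (7.5, 7.5, 7.5), v.shape, v.affine,
                          fill_value=-1024.0)
    out = aug.apply_to_volume(t, v)
    assert out.data.min() == pytest.approx(-1024.0)
    assert np.count_nonzero(out.data == -1024.0) > 0
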