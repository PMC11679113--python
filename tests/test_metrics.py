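import numpy as np
import pytest

from augseg.errors import GridMismatchError
from augseg.metrics import (BinaryMask, ErrorTally, assd, augmentation_loss,
                            binary_mask, coefficient_of_variance, count_errors,
                            cv_category, dice_per_class, error_rate,
                            surface_voxels)
from augseg.volume_io import LabelMap, ROICatalog


def _lm(data, spacing=(1.0, 1.0, 1.0), catalog=None):
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    return LabelMap(data=np.asarray(data, dtype=np.int64), affine=affine,
                    catalog=catalog)


def _brute_force_dice(a, b, c):
    sa = {tuple(i) for i in np.argwhere(np.asarray(a) == c)}
    sb = {tuple(i) for i in np.argwhere(np.asarray(b) == c)}
    if not sa and not sb:
        return None
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def _brute_force_assd(m1, m2, spacing):
    """All-pairs surface distance oracle (independent of scipy EDT)."""
    def surf(m):
        m = np.asarray(m, dtype=bool)
        out = []
        for idx in np.argwhere(m):
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    if (nb < 0).any() or (nb >= np.asarray(m.shape)).any() \
                            or not m[tuple(nb)]:
                        out.append(idx)
                        break
                else:
                    continue
                break
        return np.asarray(out, dtype=float)

    s1 = surf(m1) * spacing
    s2 = surf(m2) * spacing
    d12 = np.sqrt(((s1[:, None, :] - s2[None, :, :]) ** 2).sum(-1))
    return (d12.min(axis=1).sum() + d12.min(axis=0).sum()) / (len(s1) + len(s2))


# ---------------------------------------------------------------------------
# DICE

def test_dice_identical_masks():
    m = _lm(np.random.default_rng(0).integers(0, 3, (6, 6, 6)))
    res = dice_per_class(m, m)
    assert all(v == 1.0 for v in res.per_class.values())
    assert res.average == 1.0


def test_dice_counting_example():
    a = np.zeros((4, 4, 4), dtype=int)
    b = np.zeros((4, 4, 4), dtype=int)
    a[0, 0, :3] = 1               # |A| = 3
    b[0, 0, 1:4] = 1              # |B| = 3 ... adjust to 5
    b[0, 1, :2] = 1               # |B| = 5, overlap = 2
    res = dice_per_class(_lm(a), _lm(b))
    assert res.per_class[1] == pytest.approx(2 * 2 / (3 + 5))  # 0.5


def test_dice_disjoint_masks_zero():
    a = np.zeros((4, 4, 4), dtype=int)
    b = np.zeros((4, 4, 4), dtype=int)
    a[:2] = 1
    b[2:] = 1
    assert dice_per_class(_lm(a), _lm(b)).per_class[1] == 0.0


def test_dice_bothempty_excluded_oneempty_zero():
    a = np.zeros((3, 3, 3), dtype=int)
    a[0, 0, 0] = 1
    res = dice_per_class(_lm(a), _lm(np.zeros((3, 3, 3), dtype=int)),
                         classes=(1, 2))
    assert res.per_class[1] == 0.0
    assert 2 in res.missing and 2 not in res.per_class
    assert res.n_classes_evaluated == 1


def test_dice_grid_mismatch():
    with pytest.raises(GridMismatchError):
        dice_per_class(_lm(np.zeros((3, 3, 3), int)),
                       _lm(np.zeros((3, 3, 3), int), spacing=(2, 2, 2)))


@pytest.mark.parametrize("seed", range(10))
def test_dice_matches_set_cardinality_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, (8, 8, 8))
    b = rng.integers(0, 4, (8, 8, 8))
    res = dice_per_class(_lm(a), _lm(b), classes=(1, 2, 3))
    for c in (1, 2, 3):
        oracle = _brute_force_dice(a, b, c)
        if oracle is None:
            assert c in res.missing
        else:
            assert res.per_class[c] == oracle  # exact


def test_dice_symmetry():
    rng = np.random.default_rng(3)
    a, b = rng.integers(0, 3, (6, 6, 6)), rng.integers(0, 3, (6, 6, 6))
    r1 = dice_per_class(_lm(a), _lm(b))
    r2 = dice_per_class(_lm(b), _lm(a))
    assert r1.per_class == r2.per_class


# ---------------------------------------------------------------------------
# ASSD

def test_assd_identical_masks_zero():
    m = np.zeros((6, 6, 6), dtype=bool)
    m[2:4, 2:4, 2:4] = True
    bm = BinaryMask(m, (1.0, 1.0, 1.0))
    assert assd(bm, bm) == 0.0


def test_assd_single_voxel_distance_scales_with_spacing():
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[2, 2, 2] = True
    b[2, 2, 5] = True  # 3 voxels apart along the last axis
    assert assd(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) == \
        pytest.approx(3.0)
    assert assd(BinaryMask(a, (1, 1, 2)), BinaryMask(b, (1, 1, 2))) == \
        pytest.approx(6.0)


def test_assd_empty_mask_is_missing():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = a.copy()
    b[1, 1, 1] = True
    assert assd(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) is None


@pytest.mark.parametrize("seed", range(8))
def test_assd_matches_all_pairs_oracle(seed):
    rng = np.random.default_rng(seed)
    spacing = np.array([1.0, 1.5, 2.0])
    a = rng.random((9, 9, 9)) < 0.2
    b = rng.random((9, 9, 9)) < 0.2
    if not (a.any() and b.any()):
        pytest.skip("degenerate draw")
    got = assd(BinaryMask(a, spacing), BinaryMask(b, spacing))
    assert got == pytest.approx(_brute_force_assd(a, b, spacing), abs=1e-9)


def test_assd_symmetric_and_translation_monotone():
    base = np.zeros((16, 8, 8), dtype=bool)
    base[2:5, 2:5, 2:5] = True
    sp = (1.0, 1.0, 1.0)
    vals = []
    for k in range(0, 8):
        shifted = np.roll(base, k, axis=0)
        d1 = assd(BinaryMask(base, sp), BinaryMask(shifted, sp))
        d2 = assd(BinaryMask(shifted, sp), BinaryMask(base, sp))
        assert d1 == pytest.approx(d2)
        vals.append(d1)
    assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
    assert vals[0] == 0.0


def test_surface_uses_face_adjacency():
    m = np.zeros((5, 5, 5), dtype=bool)
    m[1:4, 1:4, 1:4] = True
    s = surface_voxels(m)
    assert s.sum() == 27 - 1  # only the single interior voxel is excluded


# ---------------------------------------------------------------------------
# CV

def test_cv_constant_scores_low():
    res = coefficient_of_variance([0.9, 0.9, 0.9])
    assert res.cv == 0.0 and res.category == "low"


def test_cv_sample_sd_example():
    res = coefficient_of_variance([0.8, 1.2])
    assert res.cv == pytest.approx(0.2828, abs=1e-3)
    assert res.category == "medium"


def test_cv_boundaries():
    assert cv_category(0.3) == "high"     # inclusive upper threshold
    assert cv_category(0.1) == "medium"
    assert cv_category(0.0999) == "low"


def test_cv_degenerate_inputs():
    assert coefficient_of_variance([0.0, 0.0]) is None  # zero mean
    assert coefficient_of_variance([0.7]).cv == 0.0     # single score
    with pytest.raises(ValueError):
        coefficient_of_variance([])


# ---------------------------------------------------------------------------
# augmentation loss

def test_loss_dice_duality():
    rng = np.random.default_rng(5)
    a = _lm(rng.integers(0, 3, (6, 6, 6)))
    b = _lm(rng.integers(0, 3, (6, 6, 6)))
    loss = augmentation_loss(a, b)
    assert loss + dice_per_class(a, b).average == pytest.approx(1.0, abs=1e-15)


def test_loss_identity_zero_and_total_one():
    m = _lm(np.random.default_rng(6).integers(0, 3, (5, 5, 5)))
    assert augmentation_loss(m, m) == 0.0
    empty = _lm(np.zeros((5, 5, 5), dtype=int))
    assert augmentation_loss(m, empty) == 1.0


# ---------------------------------------------------------------------------
# error tallies

def test_count_errors_set_difference():
    cat = ROICatalog.generic(5)
    first = np.zeros((4, 4, 4), dtype=int)
    second = np.zeros((4, 4, 4), dtype=int)
    first[0, 0, :3] = (1, 2, 3)
    second[0, 0, :3] = (2, 3, 4)
    tally = count_errors(_lm(first, catalog=cat), _lm(second, catalog=cat), cat)
    assert (tally.type1, tally.type2) == (1, 1)
    assert tally.total == 2


def test_count_errors_empty_second():
    cat = ROICatalog.generic(4)
    first = np.zeros((4, 4, 4), dtype=int)
    first[0, 0, :3] = (1, 2, 3)
    tally = count_errors(_lm(first, catalog=cat),
                         _lm(np.zeros((4, 4, 4), int), catalog=cat), cat)
    assert (tally.type1, tally.type2) == (3, 0)
    identical = count_errors(_lm(first, catalog=cat), _lm(first, catalog=cat),
                             cat)
    assert identical.total == 0


def test_error_rate_worked_examples():
    assert error_rate([ErrorTally(57, 127)], 117, 101) == pytest.approx(
        100 * 184 / 11817)
    assert error_rate([ErrorTally(554, 172)], 117, 1010) == pytest.approx(
        100 * 726 / 118170)
    assert error_rate([ErrorTally(0, 0)], 117, 101) == 0.0
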