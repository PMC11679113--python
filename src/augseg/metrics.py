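"""Mask-agreement metrics: DICE, ASSD, CV, augmentation loss, error tallies.

Conventions (documented because a 100+-class catalog makes them matter):

* A class absent from BOTH masks is *missing*, excluded from the average
  DICE rather than scored 1 — otherwise averages over a catalog where most
  scans contain few classes would be inflated toward 1.  Presence/absence
  disagreements are captured separately as Type 1/Type 2 errors.
* A class present in exactly one mask scores DICE 0.
* Surfaces use 6-connectivity face adjacency (grid edges count as
  background); surface distances are Euclidean in world mm via spacing.
* The coefficient of variance uses the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, require_same_grid

__all__ = [
    "BinaryMask",
    "DiceResult",
    "CVResult",
    "ErrorTally",
    "binary_mask",
    "surface_voxels",
    "dice_per_class",
    "assd",
    "coefficient_of_variance",
    "cv_category",
    "augmentation_loss",
    "count_errors",
    "error_rate",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)

CV_LOW_THRESHOLD = 0.1
CV_HIGH_THRESHOLD = 0.3


@dataclass(frozen=True)
class BinaryMask:
    """A single-class boolean mask with its voxel spacing in mm."""

    data: np.ndarray
    spacing: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))


def binary_mask(labelmap: LabelMap, class_id: int) -> BinaryMask:
    return BinaryMask(data=labelmap.data == int(class_id),
                      spacing=labelmap.spacing)


@dataclass(frozen=True)
class DiceResult:
    """Per-class DICE scores plus their mean over evaluable classes."""

    per_class: dict          # class id -> score in [0, 1]
    average: float           # mean of per_class values; NaN if none evaluable
    n_classes_evaluated: int
    missing: tuple = ()      # classes empty in both masks


@dataclass(frozen=True)
class CVResult:
    cv: float
    category: str  # "low" | "medium" | "high"


@dataclass(frozen=True)
class ErrorTally:
    """Presence/absence disagreements between an ordered pair of masks."""

    type1: int  # present in first, missing in second
    type2: int  # present in second, missing in first

    @property
    def total(self) -> int:
        return self.type1 + self.type2


def dice_per_class(m1: LabelMap, m2: LabelMap, classes=None) -> DiceResult:
    """DICE score per class: D_c = 2|A∩B| / (|A| + |B|).

    ``classes`` defaults to the union of classes present in either mask;
    pass the full catalog to also record both-empty classes as missing.
    """
    require_same_grid(m1, m2, "label maps")
    if classes is None:
        classes = sorted(set(m1.present_classes()) | set(m2.present_classes()))
    per_class, missing = {}, []
    for c in classes:
        a = m1.data == c
        b = m2.data == c
        na, nb = int(a.sum()), int(b.sum())
        if na + nb == 0:
            missing.append(int(c))
            continue
        inter = int(np.count_nonzero(a & b))
        per_class[int(c)] = 2.0 * inter / (na + nb)
    values = list(per_class.values())
    average = float(np.mean(values)) if values else float("nan")
    return DiceResult(per_class=per_class, average=average,
                      n_classes_evaluated=len(values), missing=tuple(missing))


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 face-adjacent background neighbor.

    Voxels on the grid edge count as adjacent to background.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, _STRUCT6, border_value=0)
    return mask & ~interior


def assd(m1: BinaryMask, m2: BinaryMask) -> float | None:
    """Average symmetric surface distance in mm.

    ASSD = (sum_{a in S1} d(a, S2) + sum_{b in S2} d(b, S1)) / (|S1|+|S2|)
    with Euclidean distances in world mm.  Returns None (missing) when
    either mask is empty — the distance is undefined.
    """
    if not np.allclose(m1.spacing, m2.spacing):
        raise ValueError("masks have different voxel spacings")
    if not m1.data.any() or not m2.data.any():
        return None
    s1 = surface_voxels(m1.data)
    s2 = surface_voxels(m2.data)
    # distance of every voxel to the nearest surface voxel of the other mask
    d_to_s2 = ndimage.distance_transform_edt(~s2, sampling=m1.spacing)
    d_to_s1 = ndimage.distance_transform_edt(~s1, sampling=m1.spacing)
    total = float(d_to_s2[s1].sum() + d_to_s1[s2].sum())
    return total / (int(s1.sum()) + int(s2.sum()))


def cv_category(cv: float) -> str:
    if cv < CV_LOW_THRESHOLD:
        return "low"
    if cv < CV_HIGH_THRESHOLD:
        return "medium"
    return "high"


def coefficient_of_variance(scores) -> CVResult | None:
    """Sample std / mean of a score collection, with variance category.

    A single score yields cv 0; a zero mean is undefined (returns None,
    recorded as missing by callers).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    mean = scores.mean()
    if mean == 0:
        return None
    cv = 0.0 if scores.size == 1 else float(scores.std(ddof=1) / mean)
    return CVResult(cv=cv, category=cv_category(cv))


def augmentation_loss(gtsm: LabelMap, iasm: LabelMap, classes=None) -> float:
    """Resampling degradation: 1 - AverageDice(ground truth, round-tripped
    ground truth).  0 means the forward+inverse augmentation lost nothing.
    """
    return 1.0 - dice_per_class(gtsm, iasm, classes=classes).average


def count_errors(first: LabelMap, second: LabelMap, catalog=None) -> ErrorTally:
    """Presence/absence disagreements for one ordered mask pair.

    A class is present when it covers >= 1 voxel.  Type 1: present in the
    first mask, missing in the second; Type 2: the reverse.
    """
    p1 = set(first.present_classes())
    p2 = set(second.present_classes())
    if catalog is not None:
        ids = set(catalog.ids)
        p1 &= ids
        p2 &= ids
    return ErrorTally(type1=len(p1 - p2), type2=len(p2 - p1))


def error_rate(tallies, catalog_size: int, n_files: int) -> float:
    """Total errors as a percentage of all possible classifications
    (catalog size x number of files)."""
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    total = sum(t.total for t in tallies)
    return 100.0 * total / (catalog_size * n_files)
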