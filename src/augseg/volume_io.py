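"""NIfTI input/output and the in-memory grid containers.

The two central containers are :class:`Volume` (a scalar intensity grid,
e.g. Hounsfield units) and :class:`LabelMap` (an integer multi-ROI mask on
the same kind of grid).  Both carry a 4x4 voxel-to-world affine in mm;
voxel spacing is always *derived* from the affine column norms so the two
can never drift apart.  Voxel indices are 0-based and world coordinates
are ``affine @ (i, j, k, 1)``.  No reorientation to a canonical axis order
is performed on load — spatial transforms operate in world space, so they
are agnostic to the stored orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, GridMismatchError

__all__ = [
    "ROICatalog",
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
]

_SPACING_ATOL = 1e-6  # mm; affine column norms vs stored spacing


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass(frozen=True)
class ROICatalog:
    """An ordered catalog of valid ROI ids and their names.

    Label 0 is always background and is never part of the catalog.
    """

    ids: tuple[int, ...]
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.names):
            raise ValueError("ids and names must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ROI ids in catalog")
        if any(i <= 0 for i in self.ids):
            raise ValueError("ROI ids must be positive (0 is background)")

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, roi_id: int) -> bool:
        return int(roi_id) in self._idset

    @property
    def _idset(self) -> frozenset:
        return frozenset(self.ids)

    def name_of(self, roi_id: int) -> str:
        return self.names[self.ids.index(int(roi_id))]

    @classmethod
    def generic(cls, n: int, prefix: str = "roi") -> "ROICatalog":
        """A catalog of ``n`` ROIs with ids 1..n and generated names."""
        ids = tuple(range(1, n + 1))
        return cls(ids=ids, names=tuple(f"{prefix}_{i:03d}" for i in ids))


def _validate_grid(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got {data.ndim}-D data")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be a 4x4 matrix")
    spacing = _spacing_from_affine(affine)
    if np.any(spacing <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return data, affine


@dataclass(frozen=True)
class Volume:
    """A 3-D scalar intensity grid with world geometry in mm."""

    data: np.ndarray
    affine: np.ndarray
    spacing: np.ndarray = field(init=False)

    def __post_init__(self):
        data, affine = _validate_grid(self.data, self.affine)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "spacing", _spacing_from_affine(affine))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grid_matches(self, other, atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass(frozen=True)
class LabelMap:
    """A 3-D integer ROI mask; 0 is background.

    When a catalog is attached, every nonzero label must be a catalog
    member (the catalog may contain ids absent from the data).
    """

    data: np.ndarray
    affine: np.ndarray
    catalog: ROICatalog | None = None
    spacing: np.ndarray = field(init=False)

    def __post_init__(self):
        data, affine = _validate_grid(self.data, self.affine)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=_SPACING_ATOL):
                raise FormatError("label map contains non-integer voxel values")
            data = rounded.astype(np.int64)
        if data.min() < 0:
            raise ValueError("label values must be non-negative")
        if self.catalog is not None:
            present = set(np.unique(data).tolist()) - {0}
            unknown = present - set(self.catalog.ids)
            if unknown:
                raise ValueError(f"labels outside catalog: {sorted(unknown)}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "spacing", _spacing_from_affine(affine))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def grid_matches(self, other, atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def present_classes(self) -> tuple[int, ...]:
        """Sorted nonzero labels that occur in the data."""
        u = np.unique(self.data)
        return tuple(int(c) for c in u if c != 0)


def _label_dtype(max_label: int):
    # 8-bit holds catalogs up to 255 classes; larger catalogs need 16-bit.
    if max_label <= np.iinfo(np.uint8).max:
        return np.uint8
    if max_label <= np.iinfo(np.uint16).max:
        return np.uint16
    return np.uint32


def read_volume(path) -> Volume:
    """Read a NIfTI-1/-2 intensity volume.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    a non-3-D image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    return Volume(data=data, affine=img.affine)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as float32 NIfTI."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    nib.save(img, str(path))


def read_labelmap(path, catalog: ROICatalog | None = None,
                  on_unknown: str = "error") -> LabelMap:
    """Read a NIfTI label map.

    Voxel values must be integers (floats within 1e-6 of an integer are
    accepted and cast).  Labels outside ``catalog`` ∪ {0} raise by default;
    with ``on_unknown="zero"`` they are remapped to background.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=_SPACING_ATOL):
        raise FormatError(f"{path}: non-integer voxel values in label map")
    idata = rounded.astype(np.int64)
    if catalog is not None and on_unknown == "zero":
        valid = np.isin(idata, np.asarray((0,) + catalog.ids))
        idata = np.where(valid, idata, 0)
    return LabelMap(data=idata, affine=img.affine, catalog=catalog)


def write_labelmap(labelmap: LabelMap, path) -> None:
    """Write a label map; integer dtype is chosen from the max label."""
    max_label = int(labelmap.data.max(initial=0))
    out = np.asarray(labelmap.data, dtype=_label_dtype(max_label))
    img = nib.Nifti1Image(out, labelmap.affine)
    nib.save(img, str(path))


def require_same_grid(a, b, what: str = "inputs") -> None:
    """Raise :class:`GridMismatchError` unless a and b share shape+affine."""
    if not a.grid_matches(b):
        raise GridMismatchError(f"{what} are not on the same grid")
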