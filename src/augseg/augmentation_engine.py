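"""Invertible spatial augmentations for 3-D volumes and label maps.

Three augmentation levels are supported:

* level 1 — a rigid rotation about the grid's world-space center, with
  per-axis angles drawn uniformly from ``[-45, 45]`` degrees;
* level 2 — a random elastic deformation realized from a control-point
  grid, with the displacement at each control point bounded per axis by a
  quarter of the voxel spacing (in mm);
* level 3 — an elastic deformation followed by a rotation.

Every transform is defined through its *sampling map*: the function that,
for each output-grid world coordinate, returns the world coordinate at
which the input image is sampled.  Applying a transform to an image is a
single interpolation pass (linear for intensities, nearest-neighbor for
labels) — so forward application is always cheap.  The inverse of a
rotation is analytic; the inverse of an elastic deformation is computed by
fixed-point iteration on the displacement field, which converges rapidly
because displacements are far below one voxel.

All sampling is a pure function of ``(level, seed, spacing, shape)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, InversionError
from .volume_io import LabelMap, Volume

__all__ = [
    "InvertibleTransform",
    "RigidRotation",
    "ElasticDeformation",
    "CompositeTransform",
    "sample_level",
    "sample_augmentation",
    "apply_to_volume",
    "apply_to_labels",
    "invert",
    "derive_seed",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]

DEFAULT_ROTATION_RANGE = 45.0  # degrees, per axis
DEFAULT_CONTROL_POINTS = (50, 50, 70)
DEFAULT_FILL_VALUE = -1024.0  # HU of air
_FIXED_POINT_TOL = 0.1  # voxels
_FIXED_POINT_MAX_ITER = 20


def derive_seed(master_seed: int, scan_id: str, aug_index: int) -> int:
    """Stable per-(scan, augmentation) substream seed below 2**31."""
    key = f"{master_seed}:{scan_id}:{aug_index}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _euler_matrix(angles_deg) -> np.ndarray:
    """Extrinsic x-y-z rotation matrix: R = Rz @ Ry @ Rx."""
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _grid_center_world(shape, affine) -> np.ndarray:
    idx = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return affine[:3, :3] @ idx + affine[:3, 3]


class InvertibleTransform:
    """Abstract contract: a world-space spatial map with an exact or
    numerically controlled inverse.

    Subclasses implement :meth:`sampling_map` — output world coordinate →
    input world coordinate — and :meth:`inverse`.
    """

    level: int | None = None
    seed: int | None = None
    shape: tuple | None = None
    affine: np.ndarray | None = None
    spacing: np.ndarray | None = None

    def sampling_map(self, points: np.ndarray) -> np.ndarray:  # (N, 3) mm
        raise NotImplementedError

    def inverse(self) -> "InvertibleTransform":
        raise NotImplementedError


class RigidRotation(InvertibleTransform):
    """Rotation about a world-space center; exactly invertible.

    Parameters
    ----------
    angles : 3-sequence or None
        Per-axis angles in degrees (extrinsic x-y-z order).  ``None`` for
        transforms constructed directly from a matrix (e.g. inverses).
    center : 3-vector, mm
        World-space rotation center; defaults to the grid center.
    """

    def __init__(self, angles, center, shape, affine, *, fill_value=DEFAULT_FILL_VALUE,
                 matrix=None, seed=None):
        self.angles = None if angles is None else tuple(float(a) for a in angles)
        self.center = np.asarray(center, dtype=float)
        self.shape = tuple(int(s) for s in shape)
        self.affine = np.asarray(affine, dtype=float)
        self.spacing = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.fill_value = fill_value
        self.seed = seed
        self.level = 1
        if matrix is not None:
            self.matrix = np.asarray(matrix, dtype=float)
        else:
            self.matrix = _euler_matrix(self.angles)

    def sampling_map(self, points: np.ndarray) -> np.ndarray:
        # content moves by R about center => sample input at R^T (x - c) + c
        return (points - self.center) @ self.matrix + self.center

    def inverse(self) -> "RigidRotation":
        inv = RigidRotation(None, self.center, self.shape, self.affine,
                            fill_value=self.fill_value, matrix=self.matrix.T,
                            seed=self.seed)
        if self.angles is not None:
            inv._forward_angles = self.angles
        return inv


class ElasticDeformation(InvertibleTransform):
    """Smooth random deformation from a bounded control-point grid.

    The displacement (mm, world axes) at each control point is drawn
    uniformly within ``±max_displacement`` per axis, where
    ``max_displacement = spacing / 4`` by default.  The canonical dense
    per-voxel field is the cubic-spline interpolation of the control grid
    onto the voxel grid; off-grid queries interpolate that dense field
    trilinearly.  The forward image operation samples the input at
    ``x + d(x)``; the inverse solves ``x + d(x) = y`` by fixed-point
    iteration (tolerance 0.1 voxel, at most 20 iterations).
    """

    def __init__(self, control_displacements, shape, affine, *, seed=None,
                 max_displacement=None):
        cd = np.asarray(control_displacements, dtype=float)
        if cd.ndim != 4 or cd.shape[0] != 3:
            raise ValueError("control_displacements must have shape (3, cx, cy, cz)")
        self.control_displacements = cd
        self.control_points = cd.shape[1:]
        self.shape = tuple(int(s) for s in shape)
        self.affine = np.asarray(affine, dtype=float)
        self.spacing = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.max_displacement = (
            self.spacing / 4.0 if max_displacement is None
            else np.asarray(max_displacement, dtype=float)
        )
        self.seed = seed
        self.level = 2
        self._inv_affine = np.linalg.inv(self.affine)
        self._dense = None  # lazy (3, *shape) float32 field, mm

    @classmethod
    def sample(cls, rng: np.random.Generator, shape, affine,
               control_points=DEFAULT_CONTROL_POINTS, max_displacement=None,
               seed=None) -> "ElasticDeformation":
        spacing = np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)
        maxd = spacing / 4.0 if max_displacement is None else np.asarray(max_displacement)
        cd = rng.uniform(-1.0, 1.0, size=(3,) + tuple(control_points))
        cd *= maxd.reshape(3, 1, 1, 1)
        return cls(cd, shape, affine, seed=seed, max_displacement=maxd)

    @property
    def displacement_field(self) -> np.ndarray:
        """Dense per-voxel displacement field, shape (3, *grid), mm."""
        if self._dense is None:
            shape = np.asarray(self.shape, dtype=float)
            cp = np.asarray(self.control_points, dtype=float)
            idx = np.indices(self.shape, dtype=np.float32)
            # voxel index -> control-grid coordinate (endpoints pinned)
            scale = (cp - 1) / np.maximum(shape - 1, 1)
            coords = idx * scale.reshape(3, 1, 1, 1)
            field = np.empty((3,) + self.shape, dtype=np.float32)
            for k in range(3):
                field[k] = ndimage.map_coordinates(
                    self.control_displacements[k], coords, order=3, mode="nearest"
                )
            self._dense = field
        return self._dense

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Displacement (mm) at arbitrary world points, via the dense field."""
        idx = (points - self.affine[:3, 3]) @ self._inv_affine[:3, :3].T
        field = self.displacement_field
        out = np.empty_like(points, dtype=np.float64)
        coords = np.ascontiguousarray(idx.T)
        for k in range(3):
            out[:, k] = ndimage.map_coordinates(field[k], coords, order=1,
                                                mode="nearest")
        return out

    def sampling_map(self, points: np.ndarray) -> np.ndarray:
        return points + self.displacement_at(points)

    def inverse(self) -> "_InverseElasticDeformation":
        return _InverseElasticDeformation(self)


class _InverseElasticDeformation(InvertibleTransform):
    """Numerical inverse of an elastic deformation (fixed-point solve)."""

    def __init__(self, forward: ElasticDeformation):
        self.forward_transform = forward
        self.shape = forward.shape
        self.affine = forward.affine
        self.spacing = forward.spacing
        self.seed = forward.seed
        self.level = 2

    def sampling_map(self, points: np.ndarray) -> np.ndarray:
        # solve x + d(x) = y  by  x <- y - d(x)
        fwd = self.forward_transform
        y = points
        x = y - fwd.displacement_at(y)
        tol_mm = _FIXED_POINT_TOL * float(self.spacing.min())
        residual = np.inf
        for _ in range(_FIXED_POINT_MAX_ITER):
            x_new = y - fwd.displacement_at(x)
            residual = float(np.abs(x_new - x).max())
            x = x_new
            if residual < tol_mm:
                return x
        raise InversionError(
            f"elastic inversion did not converge: residual {residual:.4g} mm "
            f"exceeds {tol_mm:.4g} mm",
            residual=residual / float(self.spacing.min()),
        )

    def inverse(self) -> ElasticDeformation:
        return self.forward_transform


class CompositeTransform(InvertibleTransform):
    """An ordered chain of invertible transforms.

    ``stages`` are listed in application order; the composite sampling map
    is therefore ``s_1 ∘ s_2 ∘ ... ∘ s_k`` applied innermost-last, and the
    inverse is the reversed chain of stage inverses.
    """

    def __init__(self, stages, level, seed=None):
        if not stages:
            raise ValueError("composite transform needs at least one stage")
        self.stages = list(stages)
        self.level = int(level)
        self.seed = seed
        self.shape = self.stages[0].shape
        self.affine = self.stages[0].affine
        self.spacing = self.stages[0].spacing

    def sampling_map(self, points: np.ndarray) -> np.ndarray:
        for stage in reversed(self.stages):
            points = stage.sampling_map(points)
        return points

    def inverse(self) -> "CompositeTransform":
        inv = CompositeTransform([s.inverse() for s in reversed(self.stages)],
                                 level=self.level, seed=self.seed)
        return inv


def sample_level(seed: int) -> int:
    """Draw an augmentation level uniformly from {1, 2, 3}."""
    return int(np.random.default_rng(seed).integers(1, 4))


def _default_affine(spacing) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    return affine


def sample_augmentation(level: int, seed: int, spacing, shape, affine=None, *,
                        rotation_range: float = DEFAULT_ROTATION_RANGE,
                        control_points=DEFAULT_CONTROL_POINTS,
                        fill_value: float = DEFAULT_FILL_VALUE) -> CompositeTransform:
    """Sample one augmentation of the given level for a specific grid.

    Deterministic: identical ``(level, seed, spacing, shape)`` always
    yields an identical transform.  When no affine is given, an axis-
    aligned affine built from the spacing is assumed.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"augmentation level must be 1, 2 or 3, got {level!r}")
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    affine = _default_affine(spacing) if affine is None else np.asarray(affine, float)
    rng = np.random.default_rng(seed)
    center = _grid_center_world(shape, affine)
    stages = []
    if level in (2, 3):
        stages.append(ElasticDeformation.sample(
            rng, shape, affine, control_points=control_points, seed=seed))
    if level in (1, 3):
        angles = rng.uniform(-rotation_range, rotation_range, size=3)
        stages.append(RigidRotation(angles, center, shape, affine,
                                    fill_value=fill_value, seed=seed))
    return CompositeTransform(stages, level=level, seed=seed)


def _check_grid(t: InvertibleTransform, obj) -> None:
    if t.shape is not None and tuple(t.shape) != tuple(obj.shape):
        raise GridMismatchError(
            f"transform sampled for shape {t.shape}, image has {obj.shape}")
    if t.affine is not None and not np.allclose(t.affine, obj.affine, atol=1e-5):
        raise GridMismatchError("transform and image affines differ")


def sampling_grid(t: InvertibleTransform, shape, affine) -> np.ndarray:
    """Source voxel coordinates for resampling a grid through ``t``.

    Returns a ``(3, N)`` array of fractional input-grid indices, one
    column per output voxel in C order.  Computing this once and reusing
    it lets many images be resampled through the same transform without
    re-solving the (possibly iterative) sampling map.
    """
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1).T
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    src = t.sampling_map(pts)
    inv = np.linalg.inv(affine)
    src_idx = (src - affine[:3, 3]) @ inv[:3, :3].T
    return np.ascontiguousarray(src_idx.T)


def resample_with_grid(data: np.ndarray, grid: np.ndarray, order: int,
                       cval: float) -> np.ndarray:
    """Resample through precomputed :func:`sampling_grid` coordinates."""
    out = ndimage.map_coordinates(data, grid, order=order, mode="constant",
                                  cval=cval)
    return out.reshape(data.shape)


def _resample(data: np.ndarray, affine: np.ndarray, t: InvertibleTransform,
              order: int, cval: float) -> np.ndarray:
    return resample_with_grid(data, sampling_grid(t, data.shape, affine),
                              order, cval)


def apply_to_volume(t: InvertibleTransform, v: Volume,
                    fill_value: float | None = None) -> Volume:
    """Resample an intensity volume through the transform (linear interp).

    The output grid equals the input grid; voxels mapped from outside the
    grid take the fill value (air, -1024 HU, by default).
    """
    _check_grid(t, v)
    if fill_value is None:
        fill_value = getattr(t, "fill_value", DEFAULT_FILL_VALUE)
        if fill_value is None:
            fill_value = DEFAULT_FILL_VALUE
    out = _resample(np.asarray(v.data, dtype=np.float32), v.affine, t,
                    order=1, cval=float(fill_value))
    return Volume(data=out.astype(np.float32), affine=v.affine)


def apply_to_labels(t: InvertibleTransform, m: LabelMap) -> LabelMap:
    """Resample a label map through the transform (nearest neighbor).

    Never invents labels: output labels are a subset of input labels ∪ {0}.
    """
    _check_grid(t, m)
    out = _resample(np.asarray(m.data), m.affine, t, order=0, cval=0)
    return LabelMap(data=out.astype(m.data.dtype), affine=m.affine,
                    catalog=m.catalog)


def invert(t: InvertibleTransform) -> InvertibleTransform:
    """The inverse transform (rotations analytic, elastic numeric)."""
    return t.inverse()


# ---------------------------------------------------------------------------
# Sidecar serialization — enough state to re-invert any mask later.

def transform_to_dict(t: InvertibleTransform) -> dict:
    if isinstance(t, CompositeTransform):
        return {"kind": "composite", "level": t.level, "seed": t.seed,
                "stages": [transform_to_dict(s) for s in t.stages]}
    if isinstance(t, RigidRotation):
        return {"kind": "rotation", "angles": t.angles,
                "matrix": t.matrix.tolist(), "center": t.center.tolist(),
                "shape": list(t.shape), "affine": t.affine.tolist(),
                "fill_value": t.fill_value, "seed": t.seed}
    if isinstance(t, ElasticDeformation):
        return {"kind": "elastic", "seed": t.seed,
                "control_points": list(t.control_points),
                "max_displacement": t.max_displacement.tolist(),
                "control_displacements": t.control_displacements.tolist(),
                "shape": list(t.shape), "affine": t.affine.tolist()}
    if isinstance(t, _InverseElasticDeformation):
        return {"kind": "inverse_elastic",
                "forward": transform_to_dict(t.forward_transform)}
    raise TypeError(f"cannot serialize transform of type {type(t).__name__}")


def transform_from_dict(d: dict) -> InvertibleTransform:
    kind = d["kind"]
    if kind == "composite":
        return CompositeTransform([transform_from_dict(s) for s in d["stages"]],
                                  level=d["level"], seed=d.get("seed"))
    if kind == "rotation":
        return RigidRotation(d.get("angles"), d["center"], d["shape"], d["affine"],
                             fill_value=d.get("fill_value", DEFAULT_FILL_VALUE),
                             matrix=np.asarray(d["matrix"]), seed=d.get("seed"))
    if kind == "elastic":
        return ElasticDeformation(np.asarray(d["control_displacements"]),
                                  d["shape"], d["affine"], seed=d.get("seed"),
                                  max_displacement=d["max_displacement"])
    if kind == "inverse_elastic":
        fwd = transform_from_dict(d["forward"])
        return fwd.inverse()
    raise ValueError(f"unknown transform kind {kind!r}")


def save_transform(t: InvertibleTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(transform_to_dict(t), fh)


def load_transform(path) -> InvertibleTransform:
    with open(path) as fh:
        return transform_from_dict(json.load(fh))
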