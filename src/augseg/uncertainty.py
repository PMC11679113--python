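"""Voxelwise label-agreement uncertainty from pooled inverted masks.

Given the *n* labels assigned to a voxel by *n* segmentation masks (each
an augmented-scan mask mapped back to the original frame), the agreement
fraction is the multiplicity of the most common label divided by *n*, and

    uncertainty = 1 - agreement_fraction = 1 - count(mode) / n.

Values therefore live on the lattice {0, 1/n, ..., 1 - 1/n}: 0 means all
masks agree (including unanimous background) and 1 - 1/n means every mask
assigned a different label.  Background (label 0) participates as an
ordinary label, both voxelwise and in the filewise average.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError
from .volume_io import LabelMap

__all__ = [
    "UncertaintyMap",
    "uncertainty_at_voxel",
    "compute_uncertainty_map",
    "filewise_uncertainty",
    "roiwise_uncertainty",
    "write_uncertainty_map",
]


@dataclass(frozen=True)
class UncertaintyMap:
    """Per-voxel disagreement score in [0, 1 - 1/n] on the original grid."""

    data: np.ndarray
    n: int
    affine: np.ndarray

    @property
    def shape(self):
        return self.data.shape

    def grid_matches(self, other, atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol)


def uncertainty_at_voxel(labels) -> float:
    """Uncertainty of a single voxel from its n pooled labels."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one label")
    _, counts = np.unique(labels, return_counts=True)
    return 1.0 - counts.max() / labels.size


def _max_multiplicity(stack: np.ndarray) -> np.ndarray:
    """Per-voxel multiplicity of the most common label along axis 0.

    O(n^2) pairwise comparison — exact and fully vectorized, cheap for the
    small n (~10) used when pooling augmentations.
    """
    n = stack.shape[0]
    best = np.zeros(stack.shape[1:], dtype=np.int32)
    for i in range(n):
        counts = np.zeros(stack.shape[1:], dtype=np.int32)
        for j in range(n):
            counts += stack[i] == stack[j]
        np.maximum(best, counts, out=best)
    return best


def compute_uncertainty_map(masks) -> UncertaintyMap:
    """Pool n label maps on a common grid into an uncertainty heatmap."""
    masks = list(masks)
    if len(masks) < 1:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if not first.grid_matches(m):
            raise GridMismatchError("masks are not on a common grid")
    stack = np.stack([np.asarray(m.data) for m in masks])
    n = len(masks)
    agreement = _max_multiplicity(stack).astype(np.float32) / n
    return UncertaintyMap(data=1.0 - agreement, n=n, affine=first.affine)


def filewise_uncertainty(umap: UncertaintyMap) -> float:
    """Mean uncertainty over ALL voxels, background included."""
    return float(np.mean(umap.data))


def roiwise_uncertainty(umap: UncertaintyMap, reference: LabelMap,
                        rois=None) -> pd.Series:
    """Mean uncertainty over each ROI's voxels in the reference mask.

    ``rois`` defaults to the reference's catalog (or its present classes
    when no catalog is attached).  ROIs absent from the reference are
    returned as NaN — explicitly missing, never zero.
    """
    if not umap.grid_matches(reference):
        raise GridMismatchError("uncertainty map and reference grids differ")
    if rois is None:
        rois = (reference.catalog.ids if reference.catalog is not None
                else reference.present_classes())
    out = {}
    for roi in rois:
        sel = reference.data == roi
        out[int(roi)] = float(umap.data[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="uncertainty")


def write_uncertainty_map(umap: UncertaintyMap, path) -> None:
    """Write the heatmap as float32 NIfTI on the original grid."""
    img = nib.Nifti1Image(np.asarray(umap.data, dtype=np.float32), umap.affine)
    nib.save(img, str(path))
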