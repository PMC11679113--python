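"""The pluggable segmenter contract plus built-in mock segmenters.

Any segmentation model — including external tools such as TotalSegmentator
driven through a subprocess adapter — can be plugged into the pipeline by
implementing :class:`Segmenter`: a named callable from a :class:`Volume`
to a :class:`LabelMap` on the same grid whose labels stay inside the ROI
catalog.  Two built-in segmenters make the entire framework testable with
no external model:

* :func:`threshold_segmenter` — assigns classes by intensity intervals;
  exact on noise-free synthetic phantoms;
* :func:`corrupted_oracle` — ignores intensities and returns a known truth
  mask degraded by controlled corruption (boundary flips, whole-ROI
  dropout, dilation/erosion bias).  Because each call corrupts its truth
  independently, a pool of oracle outputs shows exactly the kind of
  inconsistency that consistency-based quality control is meant to detect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, ROICatalog, Volume

__all__ = [
    "Segmenter",
    "CorruptionSpec",
    "ThresholdSegmenter",
    "CorruptedOracleSegmenter",
    "threshold_segmenter",
    "corrupted_oracle",
    "segment_batch",
    "BatchResult",
    "check_segmenter",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class Segmenter:
    """Abstract segmenter contract.

    Attributes
    ----------
    name : str
    catalog : ROICatalog or None
    requires_truth : bool
        True for oracle-style segmenters that need the per-volume ground
        truth passed alongside the volume (used by the synthetic
        validation study, where truth is known by construction).
    """

    name: str = "segmenter"
    catalog: ROICatalog | None = None
    requires_truth: bool = False

    def segment(self, volume: Volume) -> LabelMap:
        raise NotImplementedError


class ThresholdSegmenter(Segmenter):
    """Assign each voxel the class whose intensity interval contains it."""

    def __init__(self, thresholds: dict, catalog: ROICatalog | None = None,
                 name: str = "threshold"):
        intervals = sorted(((float(lo), float(hi), int(c))
                            for c, (lo, hi) in thresholds.items()))
        for (lo1, hi1, c1), (lo2, hi2, c2) in zip(intervals, intervals[1:]):
            if lo2 <= hi1:
                raise ValueError(
                    f"intensity intervals for classes {c1} and {c2} overlap")
        self.thresholds = {int(c): (float(lo), float(hi))
                           for c, (lo, hi) in thresholds.items()}
        self.catalog = catalog
        self.name = name

    def segment(self, volume: Volume) -> LabelMap:
        out = np.zeros(volume.shape, dtype=np.int64)
        for c, (lo, hi) in self.thresholds.items():
            out[(volume.data >= lo) & (volume.data <= hi)] = c
        return LabelMap(data=out, affine=volume.affine, catalog=self.catalog)


@dataclass(frozen=True)
class CorruptionSpec:
    """Controlled degradation applied by the corrupted oracle.

    boundary_flip_rate : probability that a surface voxel of an ROI is
        relabeled to background (independent per voxel).
    dropout_rate : probability that an entire present ROI is deleted.
    dilation_bias : signed number of morphological steps; positive dilates
        each ROI into background (over-segmentation), negative erodes it.
    seed : base seed; the per-call stream also hashes the truth content so
        distinct augmented truths are corrupted independently.
    """

    boundary_flip_rate: float = 0.0
    dropout_rate: float = 0.0
    dilation_bias: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.boundary_flip_rate <= 1.0):
            raise ValueError("boundary_flip_rate must be in [0, 1]")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")


def _corrupt(data: np.ndarray, spec: CorruptionSpec,
             rng: np.random.Generator) -> np.ndarray:
    out = data.copy()
    present = [int(c) for c in np.unique(out) if c != 0]

    if spec.dilation_bias > 0:
        for c in present:
            m = out == c
            grown = ndimage.binary_dilation(m, _STRUCT6,
                                            iterations=spec.dilation_bias)
            out[grown & (out == 0)] = c
    elif spec.dilation_bias < 0:
        for c in present:
            m = out == c
            kept = ndimage.binary_erosion(m, _STRUCT6,
                                          iterations=-spec.dilation_bias,
                                          border_value=0)
            out[m & ~kept] = 0

    # dropout draws happen for every present ROI regardless of rate, so the
    # downstream surface-flip draws are aligned across corruption severities
    # sharing a seed (making severity sweeps monotone by construction).
    dropout_u = rng.random(len(present))
    for c, u in zip(present, dropout_u):
        if u < spec.dropout_rate:
            out[out == c] = 0

    for c in present:
        m = out == c
        if not m.any():
            continue
        surface = m & ~ndimage.binary_erosion(m, _STRUCT6, border_value=0)
        n_surf = int(surface.sum())
        u = rng.random(n_surf)
        flip = np.zeros_like(m)
        flip[surface] = u < spec.boundary_flip_rate
        out[flip] = 0
    return out


class CorruptedOracleSegmenter(Segmenter):
    """Returns a known truth mask degraded per a :class:`CorruptionSpec`.

    The volume's intensities are ignored.  A per-call random stream is
    derived from ``(spec.seed, crc32(truth bytes), crc32(affine bytes))``
    plus an optional integer ``salt``, so the same truth is always
    corrupted identically while distinct calls can be made independent.
    The salt matters because sub-voxel augmentations (e.g. quarter-voxel
    elastic displacements) can leave a nearest-neighbor-resampled truth
    bit-identical to the original: the pipeline salts each augmentation
    index so every augmented scan is still corrupted independently, the
    way a real model errs independently on each input.  With an all-zero
    spec the truth is reproduced exactly.
    """

    requires_truth = True

    def __init__(self, truth: LabelMap, spec: CorruptionSpec,
                 name: str = "corrupted-oracle"):
        self.truth = truth
        self.spec = spec
        self.catalog = truth.catalog
        self.name = name

    def _rng_for(self, truth: LabelMap, salt: int | None) -> np.random.Generator:
        content = zlib.crc32(np.ascontiguousarray(truth.data).tobytes())
        geom = zlib.crc32(np.ascontiguousarray(
            np.asarray(truth.affine, dtype=np.float64)).tobytes())
        key = [self.spec.seed, content, geom]
        if salt is not None:
            key.append(int(salt) & 0x7FFFFFFF)
        return np.random.default_rng(key)

    def segment(self, volume: Volume, truth: LabelMap | None = None,
                salt: int | None = None) -> LabelMap:
        truth = self.truth if truth is None else truth
        if tuple(volume.shape) != tuple(truth.shape):
            raise ValueError("oracle truth is not on the volume's grid")
        out = _corrupt(np.asarray(truth.data), self.spec,
                       self._rng_for(truth, salt))
        return LabelMap(data=out, affine=truth.affine, catalog=truth.catalog)


def threshold_segmenter(thresholds: dict, catalog: ROICatalog | None = None
                        ) -> ThresholdSegmenter:
    """Build a segmenter from per-class intensity intervals.

    ``thresholds`` maps class id → (low, high) inclusive HU bounds; the
    intervals must be pairwise disjoint.
    """
    return ThresholdSegmenter(thresholds, catalog=catalog)


def corrupted_oracle(truth: LabelMap, spec: CorruptionSpec
                     ) -> CorruptedOracleSegmenter:
    """Build a truth-degrading oracle segmenter (see class docstring)."""
    return CorruptedOracleSegmenter(truth, spec)


@dataclass
class BatchResult:
    """Masks (None where segmentation failed) plus failure records."""

    masks: list
    failures: list  # (index, exception) pairs

    @property
    def n_effective(self) -> int:
        return sum(m is not None for m in self.masks)


def segment_batch(segmenter: Segmenter, volumes, truths=None) -> BatchResult:
    """Segment a list of volumes, isolating per-volume failures.

    Order-preserving: output ``masks[i]`` corresponds to ``volumes[i]`` and
    is None when the segmenter raised for that item.  For truth-requiring
    segmenters, ``truths`` supplies the per-volume ground-truth masks.
    """
    masks, failures = [], []
    for i, v in enumerate(volumes):
        try:
            if segmenter.requires_truth and truths is not None:
                mask = segmenter.segment(v, truth=truths[i])
            else:
                mask = segmenter.segment(v)
            masks.append(mask)
        except Exception as exc:  # noqa: BLE001 - contract: isolate failures
            masks.append(None)
            failures.append((i, exc))
    return BatchResult(masks=masks, failures=failures)


def check_segmenter(segmenter: Segmenter, volume: Volume,
                    truth: LabelMap | None = None) -> list[str]:
    """Contract-conformance checks usable against any plugged segmenter.

    Returns a list of human-readable violations (empty = conformant):
    output grid must match the input grid, labels must stay inside the
    catalog ∪ {0}, and repeated calls must be deterministic.
    """
    issues = []
    kwargs = {"truth": truth} if segmenter.requires_truth else {}
    mask = segmenter.segment(volume, **kwargs)
    again = segmenter.segment(volume, **kwargs)
    if tuple(mask.shape) != tuple(volume.shape):
        issues.append(f"output shape {mask.shape} != input shape {volume.shape}")
    if not np.allclose(mask.affine, volume.affine, atol=1e-5):
        issues.append("output affine differs from input affine")
    if segmenter.catalog is not None:
        unknown = set(mask.present_classes()) - set(segmenter.catalog.ids)
        if unknown:
            issues.append(f"labels outside catalog: {sorted(unknown)}")
    if not np.array_equal(mask.data, again.data):
        issues.append("segmenter is not deterministic on identical input")
    return issues
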