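"""End-to-end orchestration: augment → segment → invert → uncertainty/metrics.

For each scan the pipeline produces the model's original-scan mask, n
augmented-scan masks, their inversions back to the original frame (ISMs),
a pooled uncertainty heatmap, and tidy metric records for the two core
comparisons: ground truth vs original-scan mask (true quality, when a
ground-truth mask is supplied) and original-scan mask vs ISM (the
consistency proxy, always available).  Cohort runs aggregate the records
ROI-wise and filewise and correlate the metric columns.

Reproducibility: one master seed; per-(scan, augmentation) substreams are
derived with a stated splitting rule, and transform sidecar JSONs allow
any mask to be re-inverted later.  Per-item failures are isolated and
logged; aggregate denominators always use the explicit ``n_effective``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augmentation_engine as aug
from . import statistics as stats
from .metrics import (ErrorTally, augmentation_loss, assd, binary_mask,
                      count_errors, dice_per_class, error_rate)
from .segmenter_interface import (CorruptionSpec, Segmenter, corrupted_oracle,
                                  threshold_segmenter)
from .uncertainty import (compute_uncertainty_map, filewise_uncertainty,
                          roiwise_uncertainty, write_uncertainty_map)
from .volume_io import (LabelMap, ROICatalog, Volume, read_labelmap,
                        read_volume, write_labelmap)

__all__ = [
    "ScanEntry",
    "RunConfig",
    "ScanResult",
    "RunReport",
    "run_scan",
    "run_cohort",
    "cohort_bookkeeping",
    "load_config",
    "build_segmenter",
]

log = logging.getLogger("augseg")

GTSM_VS_MODEL = "gtsm_vs_model"   # ground truth (first) vs original-scan mask
MODEL_VS_ISM = "model_vs_ism"     # original-scan mask (first) vs inverted mask


@dataclass
class ScanEntry:
    scan_id: str
    volume_path: str | None = None
    mask_path: str | None = None
    volume: Volume | None = None
    mask: LabelMap | None = None

    def load(self, catalog: ROICatalog | None):
        vol = self.volume if self.volume is not None else read_volume(self.volume_path)
        gt = self.mask
        if gt is None and self.mask_path:
            gt = read_labelmap(self.mask_path, catalog=catalog)
        return vol, gt


@dataclass
class RunConfig:
    manifest: list = field(default_factory=list)  # ScanEntry items
    segmenter: dict | Segmenter | None = None
    n_augmentations: int = 10
    levels: tuple = (1, 2, 3)
    seed: int = 0
    out_dir: str | None = None
    catalog: ROICatalog | None = None
    rotation_range: float = aug.DEFAULT_ROTATION_RANGE
    control_points: tuple = aug.DEFAULT_CONTROL_POINTS
    fill_value: float = aug.DEFAULT_FILL_VALUE
    keep_acts: bool = False  # augmented volumes are regenerable from seeds
    compute_assd: bool = True

    def __post_init__(self):
        if self.n_augmentations < 1:
            raise ValueError("n_augmentations must be >= 1")
        if not self.levels or not set(self.levels) <= {1, 2, 3}:
            raise ValueError("levels must be a nonempty subset of {1, 2, 3}")


@dataclass
class ScanResult:
    scan_id: str
    model_mask: LabelMap
    isms: list
    heatmap: object
    transforms: list
    levels: list
    roi_records: pd.DataFrame
    pair_records: pd.DataFrame
    tallies_original: ErrorTally | None
    tallies_augmented: list
    n_effective: int
    failures: list


@dataclass
class RunReport:
    results: list
    roi_records: pd.DataFrame
    pair_records: pd.DataFrame
    roiwise: pd.DataFrame
    filewise: pd.DataFrame
    correlations: object
    error_summary: dict
    bookkeeping: dict
    paths: dict
    seed: int


def cohort_bookkeeping(n_scans: int, n_augmentations: int,
                       catalog_size: int) -> dict:
    """Exact mask/classification counts for any cohort configuration."""
    return {
        "n_masks": n_scans * (1 + n_augmentations),
        "original_instances": catalog_size * n_scans,
        "augmented_instances": catalog_size * n_scans * n_augmentations,
    }


def _pick_level(levels, seed: int) -> int:
    if set(levels) == {1, 2, 3}:
        return aug.sample_level(seed)
    levels = sorted(levels)
    return int(levels[np.random.default_rng(seed).integers(len(levels))])


def _segment(segmenter: Segmenter, volume: Volume,
             truth: LabelMap | None) -> LabelMap:
    if getattr(segmenter, "requires_truth", False):
        return segmenter.segment(volume, truth=truth)
    return segmenter.segment(volume)


def _pair_rows(scan_id, comparison, aug_index, level, first: LabelMap,
               second: LabelMap, catalog, compute_assd: bool, loss=np.nan):
    """One roi-record row per evaluable class + one pair-level row."""
    classes = catalog.ids if catalog is not None else None
    dres = dice_per_class(first, second, classes=classes)
    tally = count_errors(first, second, catalog)
    roi_rows = []
    for roi, d in dres.per_class.items():
        a = np.nan
        if compute_assd:
            v = assd(binary_mask(first, roi), binary_mask(second, roi))
            a = np.nan if v is None else v
        roi_rows.append({"scan_id": scan_id, "comparison": comparison,
                         "aug_index": aug_index, "level": level,
                         "roi_id": roi, "dice": d, "assd_mm": a})
    pair_row = {"scan_id": scan_id, "comparison": comparison,
                "aug_index": aug_index, "level": level,
                "average_dice": dres.average,
                "n_classes": dres.n_classes_evaluated,
                "type1": tally.type1, "type2": tally.type2, "loss": loss}
    return roi_rows, pair_row, tally


def run_scan(volume: Volume, gt_mask: LabelMap | None, segmenter: Segmenter,
             cfg: RunConfig, scan_id: str = "scan") -> ScanResult:
    """Run the full per-scan pipeline.

    Produces the model's original-scan mask, ``n_augmentations`` inverted
    augmented-scan masks, the pooled uncertainty heatmap and metric
    records.  With a ground-truth mask, also the true-quality comparison,
    augmented-truth error tallies, and augmentation-loss records.
    Segmentation failures on individual augmentations are dropped with a
    warning and reflected in ``n_effective``.
    """
    catalog = cfg.catalog or getattr(segmenter, "catalog", None) or (
        gt_mask.catalog if gt_mask is not None else None)
    model_mask = _segment(segmenter, volume, gt_mask)

    roi_rows, pair_rows = [], []
    tallies_original = None
    if gt_mask is not None:
        rows, pair, tallies_original = _pair_rows(
            scan_id, GTSM_VS_MODEL, None, None, gt_mask, model_mask,
            catalog, cfg.compute_assd)
        roi_rows += rows
        pair_rows.append(pair)

    isms, transforms, levels, failures, tallies_aug = [], [], [], [], []
    for j in range(cfg.n_augmentations):
        sub_seed = aug.derive_seed(cfg.seed, scan_id, j)
        level = _pick_level(cfg.levels, sub_seed)
        t = aug.sample_augmentation(level, sub_seed, volume.spacing,
                                    volume.shape, volume.affine,
                                    rotation_range=cfg.rotation_range,
                                    control_points=cfg.control_points,
                                    fill_value=cfg.fill_value)
        asm = aug.apply_to_labels(t, gt_mask) if gt_mask is not None else None
        try:
            if getattr(segmenter, "requires_truth", False):
                ts_act = segmenter.segment(volume, truth=asm, salt=j)
            else:
                act = aug.apply_to_volume(t, volume)
                ts_act = segmenter.segment(act)
        except Exception as exc:  # noqa: BLE001 - isolate per-item failure
            log.warning("scan %s augmentation %d: segmentation failed (%s)",
                        scan_id, j, exc)
            failures.append((j, exc))
            continue
        t_inv = t.inverse()
        ism = aug.apply_to_labels(t_inv, ts_act)
        isms.append(ism)
        transforms.append(t)
        levels.append(level)

        loss = np.nan
        if asm is not None:
            iasm = aug.apply_to_labels(t_inv, asm)
            loss = augmentation_loss(gt_mask, iasm)
            tallies_aug.append(count_errors(asm, ts_act, catalog))
        rows, pair, _ = _pair_rows(scan_id, MODEL_VS_ISM, j, level,
                                   model_mask, ism, catalog, cfg.compute_assd,
                                   loss=loss)
        roi_rows += rows
        pair_rows.append(pair)

    heatmap = compute_uncertainty_map(isms) if len(isms) >= 2 else None
    return ScanResult(scan_id=scan_id, model_mask=model_mask, isms=isms,
                      heatmap=heatmap, transforms=transforms, levels=levels,
                      roi_records=pd.DataFrame(roi_rows),
                      pair_records=pd.DataFrame(pair_rows),
                      tallies_original=tallies_original,
                      tallies_augmented=tallies_aug,
                      n_effective=len(isms), failures=failures)


def _filewise_table(results, pair_records: pd.DataFrame) -> pd.DataFrame:
    base = stats.aggregate(pair_records, by="file")
    extra = []
    for res in results:
        row = {"scan_id": res.scan_id,
               "voxel_count": int(np.prod(res.model_mask.shape))}
        if res.heatmap is not None:
            row["uncertainty"] = filewise_uncertainty(res.heatmap)
        extra.append(row)
    extra = pd.DataFrame(extra).set_index("scan_id")
    return base.join(extra, how="outer")


def _roiwise_table(results, roi_records: pd.DataFrame) -> pd.DataFrame:
    proxy = roi_records[roi_records["comparison"] == MODEL_VS_ISM]
    table = stats.aggregate(proxy, by="roi")
    table = table.rename(columns={"dice": "dice_proxy", "assd_mm": "assd_proxy"})
    truth = roi_records[roi_records["comparison"] == GTSM_VS_MODEL]
    if not truth.empty:
        t2 = stats.aggregate(truth, by="roi").rename(
            columns={"dice": "dice_true", "assd_mm": "assd_true"})
        table = table.join(t2[["dice_true", "assd_true"]], how="outer")
    # ROI-wise uncertainty, averaged over scans, with the model's own
    # original-scan mask defining ROI membership (ground truth may be absent)
    unc = []
    for res in results:
        if res.heatmap is not None:
            unc.append(roiwise_uncertainty(res.heatmap, res.model_mask))
    if unc:
        table["uncertainty"] = pd.concat(unc, axis=1).mean(axis=1)
    return table


def run_cohort(cfg: RunConfig, segmenter: Segmenter | None = None) -> RunReport:
    """Run the pipeline over a manifest of scans and aggregate.

    Per-scan failures are isolated; bookkeeping identities (masks produced
    = n_scans x (1 + n_augmentations) etc.) are reported explicitly.
    """
    if not cfg.manifest:
        raise ValueError("manifest is empty")
    results = []
    for entry in cfg.manifest:
        volume, gt = entry.load(cfg.catalog)
        seg = segmenter
        if seg is None:
            seg = build_segmenter(cfg.segmenter, truth=gt, catalog=cfg.catalog)
        try:
            results.append(run_scan(volume, gt, seg, cfg,
                                    scan_id=entry.scan_id))
        except Exception as exc:  # noqa: BLE001 - isolate per-scan failure
            log.warning("scan %s failed entirely: %s", entry.scan_id, exc)
    if not results:
        raise RuntimeError("every scan failed")

    roi_records = pd.concat([r.roi_records for r in results],
                            ignore_index=True)
    pair_records = pd.concat([r.pair_records for r in results],
                             ignore_index=True)
    filewise = _filewise_table(results, pair_records)
    roiwise = _roiwise_table(results, roi_records)
    correlations = stats.correlation_matrix(filewise)

    catalog_size = len(cfg.catalog) if cfg.catalog is not None else None
    error_summary = {}
    if catalog_size:
        orig = [r.tallies_original for r in results
                if r.tallies_original is not None]
        if orig:
            error_summary["original"] = {
                "type1": sum(t.type1 for t in orig),
                "type2": sum(t.type2 for t in orig),
                "rate_percent": error_rate(orig, catalog_size, len(orig)),
            }
        augd = [t for r in results for t in r.tallies_augmented]
        if augd:
            error_summary["augmented"] = {
                "type1": sum(t.type1 for t in augd),
                "type2": sum(t.type2 for t in augd),
                "rate_percent": error_rate(augd, catalog_size, len(augd)),
            }

    bookkeeping = cohort_bookkeeping(len(results), cfg.n_augmentations,
                                     catalog_size or 0)
    bookkeeping["n_masks_produced"] = sum(1 + r.n_effective for r in results)
    bookkeeping["n_effective_per_scan"] = {r.scan_id: r.n_effective
                                           for r in results}

    paths = {}
    if cfg.out_dir:
        paths = _write_outputs(cfg, results, roi_records, pair_records,
                               roiwise, filewise, correlations,
                               error_summary, bookkeeping)
    return RunReport(results=results, roi_records=roi_records,
                     pair_records=pair_records, roiwise=roiwise,
                     filewise=filewise, correlations=correlations,
                     error_summary=error_summary, bookkeeping=bookkeeping,
                     paths=paths, seed=cfg.seed)


def _write_outputs(cfg, results, roi_records, pair_records, roiwise,
                   filewise, correlations, error_summary, bookkeeping) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    roi_records.to_csv(out / "roi_records.csv", index=False)
    pair_records.to_csv(out / "pair_records.csv", index=False)
    roiwise.to_csv(out / "roiwise.csv")
    filewise.to_csv(out / "filewise.csv")
    correlations.r.to_csv(out / "correlation_r.csv")
    correlations.p.to_csv(out / "correlation_p.csv")
    paths.update({k: str(out / f"{k}.csv") for k in
                  ("roi_records", "pair_records", "roiwise", "filewise")})
    try:
        stats.plot_correlation_heatmap(correlations.r,
                                       path=out / "correlation_heatmap.png")
        paths["correlation_heatmap"] = str(out / "correlation_heatmap.png")
    except Exception as exc:  # noqa: BLE001 - plotting is best-effort
        log.warning("heatmap rendering failed: %s", exc)
    for res in results:
        scan_dir = out / res.scan_id
        scan_dir.mkdir(exist_ok=True)
        write_labelmap(res.model_mask, scan_dir / "model_mask.nii.gz")
        for j, (ism, t) in enumerate(zip(res.isms, res.transforms)):
            write_labelmap(ism, scan_dir / f"ism_{j:02d}.nii.gz")
            aug.save_transform(t, scan_dir / f"transform_{j:02d}.json")
        if res.heatmap is not None:
            write_uncertainty_map(res.heatmap,
                                  scan_dir / "uncertainty_heatmap.nii.gz")
    provenance = {"seed": cfg.seed, "n_augmentations": cfg.n_augmentations,
                  "levels": list(cfg.levels),
                  "rotation_range": cfg.rotation_range,
                  "control_points": list(cfg.control_points),
                  "error_summary": error_summary,
                  "bookkeeping": {k: v for k, v in bookkeeping.items()
                                  if k != "n_effective_per_scan"}}
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    paths["provenance"] = str(out / "provenance.json")
    return paths


# ---------------------------------------------------------------------------
# Config / registry plumbing for the CLI.

def build_segmenter(spec, truth: LabelMap | None = None,
                    catalog: ROICatalog | None = None) -> Segmenter:
    """Resolve a segmenter from a config dict (or pass an instance through).

    Registry names: ``threshold`` (params: thresholds mapping class ->
    [low, high]) and ``corrupted-oracle`` (params: boundary_flip_rate,
    dropout_rate, dilation_bias, seed; the per-scan ground-truth mask
    supplies the truth).
    """
    if isinstance(spec, Segmenter):
        return spec
    if not spec:
        raise ValueError("no segmenter configured")
    name = spec.get("name")
    params = spec.get("params", {})
    if name == "threshold":
        thresholds = {int(c): tuple(v) for c, v in params["thresholds"].items()}
        return threshold_segmenter(thresholds, catalog=catalog)
    if name == "corrupted-oracle":
        if truth is None:
            raise ValueError("corrupted-oracle needs a ground-truth mask")
        cs = CorruptionSpec(
            boundary_flip_rate=params.get("boundary_flip_rate", 0.0),
            dropout_rate=params.get("dropout_rate", 0.0),
            dilation_bias=params.get("dilation_bias", 0),
            seed=params.get("seed", 0))
        return corrupted_oracle(truth, cs)
    raise ValueError(f"unknown segmenter {name!r}")


def load_config(path) -> RunConfig:
    """Load a YAML run config with a CSV/TSV manifest.

    Manifest columns: scan_id, volume_path, optional mask_path (paths
    relative to the manifest file).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    manifest_path = Path(raw["manifest"])
    if not manifest_path.is_absolute():
        manifest_path = path.parent / manifest_path
    sep = "\t" if manifest_path.suffix in (".tsv", ".txt") else ","
    mf = pd.read_csv(manifest_path, sep=sep)
    entries = []
    for _, row in mf.iterrows():
        mask_path = row.get("mask_path")
        if isinstance(mask_path, str):
            mask_path = str((manifest_path.parent / mask_path).resolve())
        else:
            mask_path = None
        entries.append(ScanEntry(
            scan_id=str(row["scan_id"]),
            volume_path=str((manifest_path.parent / row["volume_path"]).resolve()),
            mask_path=mask_path))
    catalog = None
    if "catalog_size" in raw:
        catalog = ROICatalog.generic(int(raw["catalog_size"]))
    return RunConfig(
        manifest=entries,
        segmenter=raw.get("segmenter"),
        n_augmentations=int(raw.get("n_augmentations", 10)),
        levels=tuple(raw.get("levels", (1, 2, 3))),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        catalog=catalog,
        rotation_range=float(raw.get("rotation_range",
                                     aug.DEFAULT_ROTATION_RANGE)),
        control_points=tuple(raw.get("control_points",
                                     aug.DEFAULT_CONTROL_POINTS)),
        fill_value=float(raw.get("fill_value", aug.DEFAULT_FILL_VALUE)),
        compute_assd=bool(raw.get("compute_assd", True)),
    )
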