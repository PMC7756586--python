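"""Orchestration of the cascade: training, checkpoints, and full inference.

Inference order is fixed by the stage dependencies: the bony multi-label
model runs first (the vessel search region is anchored on the L4 block), the
vessel model runs inside that region and yields the bifurcation slice, and
the nodal / para-aortic border rules run last.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import anatomy
from .config import PipelineConfig, StructurePlan
from .errors import DataError, DependencyError, EmptyExtentError
from .extent import (ClassifierConfig, ExtentInterval, PresenceClassifier,
                     extent_postprocess, pad_extent, train_presence_classifier)
from .optim import OptimizerConfig
from .segmentation import (AugmentSpec, CropSpec, SegPrediction, VoxelSegmenter,
                           coarse_segment, default_crop_box, fuse_2d3d,
                           refine_segment, train_refine_segmenter, train_segmenter)
from .volume_io import StructureSet, Volume, load_scan

__all__ = ["Checkpoints", "AuditRecord", "train_structure", "predict_scan",
           "load_cohort", "write_audit_csv", "oracle_train_fn"]

Cohort = List[Tuple[Volume, StructureSet]]


@dataclass
class AuditRecord:
    scan: str
    structure: str
    stage: str
    detail: str


@dataclass
class Checkpoints:
    """On-disk model store: one ``.npz`` per model plus a JSON sidecar."""

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, plan: str, kind: str) -> Path:
        return self.root / f"{plan}__{kind}.npz"

    def save(self, plan: str, kind: str, params: dict, meta: Optional[dict] = None) -> None:
        arrays = {k: np.asarray(v) for k, v in params.items() if v is not None}
        np.savez(self._path(plan, kind), **arrays)
        if meta:
            with open(self._path(plan, kind).with_suffix(".json"), "w") as fh:
                json.dump(meta, fh)

    def load(self, plan: str, kind: str) -> dict:
        path = self._path(plan, kind)
        if not path.exists():
            raise DependencyError(f"missing checkpoint {path.name} "
                                  f"(stage {kind!r} of {plan!r} not trained)")
        with np.load(path, allow_pickle=False) as data:
            params = {k: data[k] for k in data.files}
        meta_path = path.with_suffix(".json")
        if meta_path.exists():
            with open(meta_path) as fh:
                params["_meta"] = json.load(fh)
        return params

    def has(self, plan: str, kind: str) -> bool:
        return self._path(plan, kind).exists()


def _classifier_params(model: PresenceClassifier) -> dict:
    p = model.get_params()
    p["structure"] = np.array(p["structure"])
    return p


def _opt_from(cfg_section: dict, seed: int) -> OptimizerConfig:
    return OptimizerConfig(
        learning_rate=float(cfg_section.get("learning_rate", 0.1)),
        epochs=int(cfg_section.get("epochs", 30)),
        batch_size=int(cfg_section.get("batch_size", 4096)),
        seed=seed,
    )


def _aug_from(cfg_section: dict) -> AugmentSpec:
    return AugmentSpec(
        hflip=bool(cfg_section.get("hflip", True)),
        rotation_range=tuple(cfg_section.get("rotation_range", (-30.0, 30.0))),
        crop_center_jitter=bool(cfg_section.get("crop_center_jitter", True)),
    )


def _union_presence_mask(sset: StructureSet, structures: Sequence[str]) -> np.ndarray:
    union = np.zeros(sset.grid_shape, dtype=np.uint8)
    for name in structures:
        if name in sset.masks:
            union |= sset.masks[name]
    return union


def train_structure(cohort: Cohort, plan: StructurePlan, cfg: PipelineConfig,
                    checkpoints: Checkpoints) -> None:
    """Train every model the plan's routing requires and store checkpoints."""
    seed = cfg.seed
    clf_section = cfg.section("classifier")
    opt = _opt_from(cfg.section("optimizer"), seed)
    aug = _aug_from(cfg.section("augment"))

    # extent classifier on the (union) presence labels
    clf_cohort = []
    for vol, sset in cohort:
        if all(s in sset.masks for s in plan.structures):
            s2 = sset.copy()
            s2.add_mask("__presence__", _union_presence_mask(sset, plan.structures))
            clf_cohort.append((vol, s2))
    if len(clf_cohort) < 2:
        raise DataError(f"plan {plan.name!r}: structures present in "
                        f"{len(clf_cohort)} scan(s); need >= 2")
    clf_cfg = ClassifierConfig(
        optimizer=OptimizerConfig(learning_rate=float(clf_section["learning_rate"]),
                                  epochs=int(clf_section["epochs"])),
        seed=seed)
    classifier = train_presence_classifier(clf_cohort, "__presence__", clf_cfg)
    classifier.structure = plan.name
    checkpoints.save(plan.name, "classifier", _classifier_params(classifier),
                     meta={"class_weight": classifier.class_weight_,
                           "threshold": clf_section["threshold"],
                           "max_gap": clf_section["max_gap"],
                           "pad": clf_section["pad"]})

    if plan.crop_from:
        # field-of-view-restricted model (vessel): crops around the anchor mask
        anchor = plan.crop_from
        usable = [(v, s) for v, s in cohort
                  if plan.name in s.masks and anchor in s.masks and s.masks[anchor].any()]
        if len(usable) < 2:
            raise DataError(f"plan {plan.name!r}: need >= 2 scans with both "
                            f"{plan.name!r} and anchor {anchor!r}")

        def provider(rng):
            samples = []
            for vol, sset in usable:
                crop = anatomy.vessel_search_region(sset.masks[anchor])
                sl = tuple(slice(max(c - b // 2, 0), min(max(c - b // 2, 0) + b, g))
                           for c, b, g in zip(crop.center, crop.box_shape, sset.grid_shape))
                from .segmentation import _preprocessed
                samples.append((_preprocessed(vol.data, vol.intensity_kind)[sl],
                                sset.masks[plan.name][sl][None].astype(np.float64)))
            return samples

        # rotation interpolation blends bone-edge intensities into the thin
        # vessel's band; flip-only augmentation keeps the training stream sharp
        crop_aug = AugmentSpec(hflip=aug.hflip, rotation_range=(0.0, 0.0),
                               crop_center_jitter=False)
        model = VoxelSegmenter([plan.name], plan.seg_mode)
        model.fit(provider, opt, crop_aug)
        checkpoints.save(plan.name, "crop_model", model.get_params())
        return

    extents = _training_extents(cohort, plan, pad=int(clf_section["pad"]))
    coarse_shape = None
    if plan.seg_mode == "3d" and not plan.members:
        frac = float(cfg.raw.get("coarse_frac", 0.5))
        ny, nx = cohort[0][0].shape[1], cohort[0][0].shape[2]
        coarse_shape = (max(int(ny * frac), 8), max(int(nx * frac), 8))
    model = train_segmenter(cohort, plan.structures, plan.seg_mode, opt, aug,
                            extents=extents, coarse_shape=coarse_shape)
    checkpoints.save(plan.name, "coarse", model.get_params())

    if plan.use_refine:
        refine_model, box = train_refine_segmenter(cohort, plan.structures[0], opt, aug)
        checkpoints.save(plan.name, "refine", refine_model.get_params(),
                         meta={"box_shape": list(box)})
    if plan.use_fusion_2d:
        model2d = train_segmenter(cohort, plan.structures[0], "2d", opt, aug,
                                  extents=extents)
        checkpoints.save(plan.name, "model2d", model2d.get_params())


def _training_extents(cohort: Cohort, plan: StructurePlan, pad: int
                      ) -> Dict[str, ExtentInterval]:
    extents = {}
    for vol, sset in cohort:
        union = _union_presence_mask(sset, plan.structures)
        zs = np.flatnonzero(union.any(axis=(1, 2)))
        if zs.size:
            extents[sset.volume_id] = pad_extent(
                ExtentInterval(int(zs.min()), int(zs.max())), vol.n_slices, pad)
    return extents


def _plan_order(plans: Sequence[StructurePlan]) -> List[StructurePlan]:
    """Dependency-respecting stage order (bony → vessel → the rest → bordered)."""
    names = {p.name for p in plans}
    ordered: List[StructurePlan] = []
    placed: set = set()
    remaining = list(plans)
    while remaining:
        progress = False
        for p in list(remaining):
            deps = [d for d in ([p.crop_from and _owner(p.crop_from, plans)] +
                                list(p.requires)) if d]
            if all(d in placed or d not in names for d in deps):
                ordered.append(p)
                placed.add(p.name)
                remaining.remove(p)
                progress = True
        if not progress:
            raise DependencyError(f"circular stage dependencies among "
                                  f"{[p.name for p in remaining]}")
    return ordered


def _owner(structure: str, plans: Sequence[StructurePlan]) -> Optional[str]:
    for p in plans:
        if structure in p.structures:
            return p.name
    return None


def predict_scan(vol: Volume, plans: Sequence[StructurePlan], cfg: PipelineConfig,
                 checkpoints: Checkpoints
                 ) -> Tuple[StructureSet, List[AuditRecord]]:
    """Run the full cascade for the requested plans on one scan."""
    # verify dependencies before doing any work
    requested = {p.name for p in plans}
    for p in plans:
        for dep in p.requires:
            if dep not in requested and not (
                    checkpoints.has(dep, "coarse") or checkpoints.has(dep, "crop_model")):
                raise DependencyError(
                    f"plan {p.name!r} requires stage {dep!r}, which is neither "
                    f"requested nor trained")
        anchor_plan = _owner(p.crop_from, plans) if p.crop_from else None
        if p.crop_from and anchor_plan is None and not checkpoints.has(
                p.crop_from, "coarse"):
            raise DependencyError(f"plan {p.name!r} needs {p.crop_from!r} predictions")

    coarse_frac = float(cfg.raw.get("coarse_frac", 0.5))
    scan_id = "scan"
    out = StructureSet(volume_id=scan_id, grid_shape=vol.shape)
    audit: List[AuditRecord] = []
    bifurcation: Optional[int] = None

    for plan in _plan_order(list(plans)):
        clf_params = checkpoints.load(plan.name, "classifier")
        meta = clf_params.pop("_meta", {})
        classifier = PresenceClassifier.from_params(clf_params)
        series = classifier.predict(vol)
        try:
            extent = extent_postprocess(series, float(meta.get("threshold", 0.5)),
                                        int(meta.get("max_gap", 2)))
            extent = pad_extent(extent, vol.n_slices, int(meta.get("pad", 1)))
        except EmptyExtentError:
            extent = ExtentInterval(0, vol.n_slices - 1)
            audit.append(AuditRecord(scan_id, plan.name, "extent",
                                     "empty-extent fallback to full volume"))
        audit.append(AuditRecord(scan_id, plan.name, "extent",
                                 f"lo={extent.lo} hi={extent.hi}"))

        if plan.crop_from:
            bifurcation = _predict_crop_plan(vol, plan, cfg, checkpoints, out,
                                             audit, extent)
            continue

        coarse_params = checkpoints.load(plan.name, "coarse")
        coarse_params.pop("_meta", None)
        model = VoxelSegmenter.from_params(coarse_params)

        if plan.members:
            masks = model.predict_multilabel(vol.data, vol.intensity_kind, extent)
            for name, mask in masks.items():
                out.add_mask(name, mask, "predicted")
            continue

        ny, nx = vol.shape[1], vol.shape[2]
        coarse_shape = ((ny, nx) if plan.seg_mode == "2d"
                        else (max(int(ny * coarse_frac), 8), max(int(nx * coarse_frac), 8)))
        pred = coarse_segment(model, vol, extent, coarse_shape)

        if plan.use_refine and checkpoints.has(plan.name, "refine"):
            refine_params = checkpoints.load(plan.name, "refine")
            box = tuple(refine_params.pop("_meta")["box_shape"])
            refine_model = VoxelSegmenter.from_params(refine_params)
            refined = refine_segment(pred, vol, refine_model,
                                     CropSpec(center=None, box_shape=box))
            if pred.mask.any():
                from .segmentation import center_of_mass
                audit.append(AuditRecord(scan_id, plan.name, "crop",
                                         f"center={center_of_mass(pred.mask)} box={box}"))
            pred = refined

        if plan.use_fusion_2d and checkpoints.has(plan.name, "model2d"):
            params2d = checkpoints.load(plan.name, "model2d")
            params2d.pop("_meta", None)
            model2d = VoxelSegmenter.from_params(params2d)
            pred2d = SegPrediction(plan.name,
                                   model2d.predict_mask(vol.data, vol.intensity_kind,
                                                        extent),
                                   "coarse")
            pred = fuse_2d3d(pred2d, pred)
            audit.append(AuditRecord(scan_id, plan.name, "fusion", "2d∪3d union"))

        mask = pred.mask
        if plan.border:
            if bifurcation is None:
                raise DependencyError(f"plan {plan.name!r} needs the bifurcation "
                                      "slice but no vessel stage ran")
            if plan.border == "nodal_superior":
                mask, res = anatomy.apply_nodal_superior_border(mask, bifurcation,
                                                                plan.name)
            else:
                mask, res = anatomy.apply_pan_inferior_border(mask, bifurcation,
                                                              plan.name)
            audit.append(AuditRecord(scan_id, plan.name, "border",
                                     f"{res.rule} anchor={res.anchor_slice} "
                                     f"removed={res.voxels_removed}"))
        out.add_mask(plan.name, mask, "predicted")
    return out, audit


def _predict_crop_plan(vol: Volume, plan: StructurePlan, cfg: PipelineConfig,
                       checkpoints: Checkpoints, out: StructureSet,
                       audit: List[AuditRecord], extent: ExtentInterval
                       ) -> Optional[int]:
    """Predict a field-of-view-restricted structure (vessel); return bifurcation."""
    anchor = plan.crop_from
    if anchor not in out.masks or not out.masks[anchor].any():
        raise DependencyError(f"plan {plan.name!r}: anchor mask {anchor!r} "
                              "not predicted or empty")
    crop = anatomy.vessel_search_region(out.masks[anchor])
    params = checkpoints.load(plan.name, "crop_model")
    params.pop("_meta", None)
    model = VoxelSegmenter.from_params(params)
    sl = tuple(slice(max(c - b // 2, 0), min(max(c - b // 2, 0) + b, g))
               for c, b, g in zip(crop.center, crop.box_shape, vol.shape))
    from .segmentation import _preprocessed
    sub = _preprocessed(vol.data, vol.intensity_kind)[sl]
    sub_mask = model.predict_mask(sub, "preprocessed", structure=plan.name)
    if sub_mask.any():
        # a Y-shaped vessel is one 3D component; drop stray blobs
        from scipy import ndimage as ndi
        labels, n = ndi.label(sub_mask)
        if n > 1:
            sizes = ndi.sum_labels(sub_mask, labels, index=np.arange(1, n + 1))
            sub_mask = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    mask = np.zeros(vol.shape, dtype=np.uint8)
    mask[sl] = sub_mask
    out.add_mask(plan.name, mask, "predicted")
    audit.append(AuditRecord(out.volume_id, plan.name, "crop",
                             f"center={crop.center} box={crop.box_shape}"))
    try:
        b = anatomy.detect_bifurcation_slice(mask)
        audit.append(AuditRecord(out.volume_id, plan.name, "bifurcation", f"slice={b}"))
        return b
    except Exception as exc:
        audit.append(AuditRecord(out.volume_id, plan.name, "bifurcation",
                                 f"failed: {exc}"))
        return None


def load_cohort(cohort_dir: Path) -> Cohort:
    """Load every ``scan_*/manifest.yaml`` under a cohort directory."""
    cohort_dir = Path(cohort_dir)
    scan_dirs = sorted(d for d in cohort_dir.iterdir()
                       if d.is_dir() and (d / "manifest.yaml").exists())
    if not scan_dirs:
        raise DataError(f"no scan directories under {cohort_dir}")
    return [load_scan(d) for d in scan_dirs]


def write_audit_csv(audit: Sequence[AuditRecord], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan", "structure", "stage", "detail"])
        for rec in audit:
            writer.writerow([rec.scan, rec.structure, rec.stage, rec.detail])


def oracle_train_fn(truth: Dict[str, StructureSet]):
    """Curation train function whose predictor returns the clean ground truth.

    Used in corruption experiments where the uncorrupted masks are known;
    real runs pass a closure over :func:`train_segmenter` instead.
    """

    def train(half: Cohort, structure: str):
        def predict(vol: Volume, scan_id: str) -> np.ndarray:
            if scan_id not in truth or structure not in truth[scan_id].masks:
                raise DataError(f"oracle has no clean label for "
                                f"({scan_id!r}, {structure!r})")
            return truth[scan_id].masks[structure]

        return predict

    return train


def segmenter_train_fn(cfg: PipelineConfig, mode: str = "3d"):
    """Curation train function backed by the real segmenter."""
    opt = _opt_from(cfg.section("optimizer"), cfg.seed)
    aug = _aug_from(cfg.section("augment"))

    def train(half: Cohort, structure: str):
        model = train_segmenter(half, structure, mode, opt, aug)

        def predict(vol: Volume, scan_id: str) -> np.ndarray:
            return model.predict_mask(vol.data, vol.intensity_kind)

        return predict

    return train
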