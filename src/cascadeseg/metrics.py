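"""Overlap and surface-distance metrics with evaluation-time border trimming.

Distances are Euclidean between surface-voxel centers in physical mm and
reported in cm.  Surface voxels are foreground voxels with at least one
six-connected background neighbour (the volume border counts as background).
Empty masks make the surface distances undefined; they are reported as
missing rather than zero, while DSC stays defined (1.0 for two empty masks,
0.0 when exactly one is empty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ContractError, EmptyMaskError, UndefinedMetricError
from .volume_io import StructureSet

__all__ = [
    "MetricsReport",
    "EvalConfig",
    "dice",
    "extract_surface",
    "mean_surface_distance",
    "hausdorff_distance",
    "trim_to_reference_extent",
    "evaluate_pair",
    "evaluate_cohort",
]

MM_PER_CM = 10.0


@dataclass
class MetricsReport:
    structure: str
    dsc: float
    msd_cm: Optional[float]
    hd_cm: Optional[float]
    n_pred_voxels: int
    n_ref_voxels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ContractError(f"DSC out of range: {self.dsc}")
        if self.msd_cm is not None and self.msd_cm < 0:
            raise ContractError("MSD must be non-negative")
        if (self.msd_cm is not None and self.hd_cm is not None
                and self.hd_cm < self.msd_cm - 1e-12):
            raise ContractError("HD must be >= MSD")


@dataclass
class EvalConfig:
    """Trim rules and outlier policy applied by :func:`evaluate_cohort`."""

    # structure -> which ends of the prediction are trimmed to the reference
    trim_rules: Dict[str, Tuple[str, ...]] = field(default_factory=lambda: {
        "pan": ("superior",),
        "rectum": ("inferior",),
        "cord": ("inferior",),
    })
    hd_percentile: float = 100.0
    outlier_whisker: float = 1.5  # boxplot whisker multiplier on DSC


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ContractError(f"{name} must be a 3D mask")
    return mask.astype(bool)


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """``2|P∩R| / (|P| + |R|)``; 1.0 when both empty, 0.0 when exactly one is."""
    pred = _as_binary(pred, "pred")
    ref = _as_binary(ref, "ref")
    if pred.shape != ref.shape:
        raise ContractError(f"grid mismatch {pred.shape} vs {ref.shape}")
    n_pred = int(pred.sum())
    n_ref = int(ref.sum())
    if n_pred == 0 and n_ref == 0:
        return 1.0
    if n_pred == 0 or n_ref == 0:
        return 0.0
    inter = int((pred & ref).sum())
    return 2.0 * inter / (n_pred + n_ref)


_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def extract_surface(mask: np.ndarray,
                    spacing: Optional[Tuple[float, float, float]] = None) -> np.ndarray:
    """(n, 3) coordinates of surface voxels, in mm when ``spacing`` is given.

    A surface voxel has >= 1 six-connected background neighbour; the volume
    border counts as background.
    """
    mask = _as_binary(mask, "mask")
    if not mask.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_SIX_CONN, border_value=0)
    surf = mask & ~interior
    coords = np.stack(np.nonzero(surf), axis=1).astype(np.float64)
    if spacing is not None:
        coords *= np.asarray(spacing, dtype=np.float64)
    return coords


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return d


def _surface_pair(pred: np.ndarray, ref: np.ndarray,
                  spacing: Tuple[float, float, float]) -> Tuple[np.ndarray, np.ndarray]:
    pred = _as_binary(pred, "pred")
    ref = _as_binary(ref, "ref")
    if pred.shape != ref.shape:
        raise ContractError(f"grid mismatch {pred.shape} vs {ref.shape}")
    if not pred.any() or not ref.any():
        raise UndefinedMetricError("surface distances undefined for an empty mask")
    sp = extract_surface(pred, spacing)
    sr = extract_surface(ref, spacing)
    return _directed_distances(sp, sr), _directed_distances(sr, sp)


def mean_surface_distance(pred: np.ndarray, ref: np.ndarray,
                          spacing: Tuple[float, float, float]) -> float:
    """Symmetric mean of nearest-surface distances, in cm."""
    d_pr, d_rp = _surface_pair(pred, ref, spacing)
    return 0.5 * (float(d_pr.mean()) + float(d_rp.mean())) / MM_PER_CM


def hausdorff_distance(pred: np.ndarray, ref: np.ndarray,
                       spacing: Tuple[float, float, float],
                       percentile: float = 100.0) -> float:
    """Max (or percentile) of the two directed nearest-surface maxima, in cm."""
    d_pr, d_rp = _surface_pair(pred, ref, spacing)
    if percentile >= 100.0:
        return max(float(d_pr.max()), float(d_rp.max())) / MM_PER_CM
    return max(float(np.percentile(d_pr, percentile)),
               float(np.percentile(d_rp, percentile))) / MM_PER_CM


def trim_to_reference_extent(pred: np.ndarray, ref: np.ndarray, end: str) -> np.ndarray:
    """Remove prediction voxels beyond the reference's axial extent at one end.

    ``end="superior"`` removes slices above the reference's top occupied
    slice; ``end="inferior"`` removes slices below its bottom occupied slice.
    """
    pred = np.asarray(pred)
    ref = _as_binary(ref, "ref")
    if pred.shape != ref.shape:
        raise ContractError(f"grid mismatch {pred.shape} vs {ref.shape}")
    if end not in ("superior", "inferior"):
        raise ContractError(f"end must be 'superior' or 'inferior', got {end!r}")
    zs = np.flatnonzero(ref.any(axis=(1, 2)))
    if zs.size == 0:
        raise ContractError("reference mask is empty")
    out = pred.copy()
    if end == "superior":
        out[int(zs.max()) + 1:] = 0
    else:
        out[: int(zs.min())] = 0
    return out.astype(np.uint8)


def evaluate_pair(pred: np.ndarray, ref: np.ndarray, structure: str,
                  spacing: Tuple[float, float, float],
                  cfg: Optional[EvalConfig] = None) -> MetricsReport:
    """Metrics for one predicted-vs-reference pair, applying trim rules first."""
    cfg = cfg or EvalConfig()
    for end in cfg.trim_rules.get(structure, ()):
        if _as_binary(ref, "ref").any():
            pred = trim_to_reference_extent(pred, ref, end)
    d = dice(pred, ref)
    try:
        msd = mean_surface_distance(pred, ref, spacing)
        hd = hausdorff_distance(pred, ref, spacing, cfg.hd_percentile)
    except UndefinedMetricError:
        msd = hd = None
    return MetricsReport(structure=structure, dsc=d, msd_cm=msd, hd_cm=hd,
                         n_pred_voxels=int(np.asarray(pred).astype(bool).sum()),
                         n_ref_voxels=int(np.asarray(ref).astype(bool).sum()))


def evaluate_cohort(predictions: Dict[str, StructureSet],
                    references: Dict[str, StructureSet],
                    spacing: Tuple[float, float, float],
                    cfg: Optional[EvalConfig] = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame, List[dict]]:
    """Per-scan metric rows, per-structure aggregates, and DSC outliers.

    Predictions without a matching reference are recorded as skipped rows;
    empty masks yield missing MSD/HD but a defined DSC.
    """
    cfg = cfg or EvalConfig()
    rows = []
    for scan_id, pred_set in sorted(predictions.items()):
        ref_set = references.get(scan_id)
        for structure, pred_mask in sorted(pred_set.masks.items()):
            if ref_set is None or structure not in ref_set.masks:
                rows.append({"scan": scan_id, "structure": structure, "status": "skipped",
                             "dsc": np.nan, "msd_cm": np.nan, "hd_cm": np.nan})
                continue
            rep = evaluate_pair(pred_mask, ref_set.masks[structure], structure,
                                spacing, cfg)
            rows.append({
                "scan": scan_id, "structure": structure,
                "status": "ok" if rep.msd_cm is not None else "missing_metric",
                "dsc": rep.dsc,
                "msd_cm": np.nan if rep.msd_cm is None else rep.msd_cm,
                "hd_cm": np.nan if rep.hd_cm is None else rep.hd_cm,
            })
    table = pd.DataFrame(rows)
    valid = table[table["status"] != "skipped"]
    summary = (valid.groupby("structure")
               .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", "std"),
                    msd_mean=("msd_cm", "mean"), msd_sd=("msd_cm", "std"),
                    hd_mean=("hd_cm", "mean"), hd_sd=("hd_cm", "std"),
                    n=("dsc", "size"))
               .reset_index()) if len(valid) else pd.DataFrame()
    outliers: List[dict] = []
    for structure, grp in valid.groupby("structure"):
        dscs = grp["dsc"].dropna()
        if len(dscs) < 4:
            continue
        q1, q3 = dscs.quantile([0.25, 0.75])
        lo = q1 - cfg.outlier_whisker * (q3 - q1)
        for _, row in grp[grp["dsc"] < lo].iterrows():
            outliers.append({"scan": row["scan"], "structure": structure,
                             "dsc": float(row["dsc"])})
    return table, summary, outliers
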