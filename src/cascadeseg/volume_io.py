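"""Volume and mask I/O, grid resampling, and intensity preprocessing.

Arrays are ordered ``(slice/z, row/y, col/x)`` with z increasing toward the
head; all superior/inferior border logic elsewhere in the package relies on
this convention.  On disk, volumes are NIfTI files whose affine encodes the
``(dx, dy, dz)`` spacing and the origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Tuple

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .errors import ContractError, FormatError, StateError

__all__ = [
    "Volume",
    "StructureSet",
    "PreprocessSpec",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_grid",
    "resample_mask_to_grid",
    "clip_shift_intensity",
    "clip_shift_array",
    "save_scan",
    "load_scan",
]

RAW_HU = "raw_hu"
PREPROCESSED = "preprocessed"

#: Valid provenance tags for structure masks.
PROVENANCES = ("ground_truth", "predicted", "curated")


@dataclass
class Volume:
    """A 3D scalar image with spacing/origin metadata.

    Parameters
    ----------
    data
        3D array ordered (slices, rows, cols).
    spacing
        Voxel size ``(dz, dy, dx)`` in mm; strictly positive.
    origin
        Physical position of voxel (0, 0, 0) as ``(z, y, x)`` in mm.
    intensity_kind
        Either ``"raw_hu"`` or ``"preprocessed"``.  Preprocessed volumes must
        hold values in [0, 4000].
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = RAW_HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be strictly positive, got {self.spacing}")
        if self.intensity_kind not in (RAW_HU, PREPROCESSED):
            raise ContractError(f"unknown intensity_kind {self.intensity_kind!r}")
        if self.intensity_kind == PREPROCESSED:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0.0 or hi > 4000.0:
                raise ContractError(
                    f"preprocessed volume values must lie in [0, 4000], got [{lo}, {hi}]"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class StructureSet:
    """Named binary masks aligned to one :class:`Volume` grid."""

    volume_id: str
    grid_shape: Tuple[int, int, int]
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        for name in list(self.masks):
            self.masks[name] = self._validate(name, self.masks[name])
            self.provenance.setdefault(name, "ground_truth")

    def _validate(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.grid_shape:
            raise ContractError(
                f"mask {name!r} shape {mask.shape} != grid shape {self.grid_shape}"
            )
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ContractError(f"mask {name!r} is not strictly binary")
        return mask.astype(np.uint8)

    def add_mask(self, name: str, mask: np.ndarray, provenance: str = "ground_truth") -> None:
        if provenance not in PROVENANCES:
            raise ContractError(f"unknown provenance {provenance!r}")
        self.masks[name] = self._validate(name, mask)
        self.provenance[name] = provenance

    def remove_mask(self, name: str) -> None:
        self.masks.pop(name, None)
        self.provenance.pop(name, None)

    def structures(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    def copy(self) -> "StructureSet":
        return StructureSet(
            volume_id=self.volume_id,
            grid_shape=self.grid_shape,
            masks={k: v.copy() for k, v in self.masks.items()},
            provenance=dict(self.provenance),
        )


@dataclass(frozen=True)
class PreprocessSpec:
    """Clipping bounds, shift, and target grid for preprocessing.

    The defaults clip CT numbers to [-1000, 3000] HU and shift by +1000 so the
    working intensity range is [0, 4000], on a 2.5 x 1.17 x 1.17 mm grid.
    """

    hu_low: float = -1000.0
    hu_high: float = 3000.0
    shift: float = 1000.0
    target_spacing: Tuple[float, float, float] = (2.5, 1.17, 1.17)

    def __post_init__(self) -> None:
        if self.hu_high <= self.hu_low:
            raise ContractError("hu_high must exceed hu_low")
        if self.hu_low + self.shift != 0:
            raise ContractError("shift must map hu_low to 0 (hu_low + shift == 0)")
        if any(s <= 0 for s in self.target_spacing):
            raise ContractError("target_spacing must be strictly positive")


def _affine_from(spacing: Tuple[float, float, float], origin: Tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    oz, oy, ox = origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    return affine


def read_volume(path: os.PathLike | str, intensity_kind: str = RAW_HU) -> Volume:
    """Read a NIfTI file into a :class:`Volume` (array order z, y, x)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    affine = img.affine
    spacing = (abs(float(affine[2, 2])), abs(float(affine[1, 1])), abs(float(affine[0, 0])))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return Volume(data=np.transpose(data, (2, 1, 0)), spacing=spacing, origin=origin,
                  intensity_kind=intensity_kind)


def write_volume(vol: Volume, path: os.PathLike | str) -> None:
    """Write a :class:`Volume` to NIfTI; re-reading reproduces data/spacing/origin."""
    path = Path(path)
    if not path.parent.exists():
        raise FormatError(f"parent directory does not exist: {path.parent}")
    data = np.transpose(vol.data, (2, 1, 0))
    img = nib.Nifti1Image(data, _affine_from(vol.spacing, vol.origin))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def read_mask(path: os.PathLike | str) -> np.ndarray:
    """Read a binary mask (z, y, x) from NIfTI."""
    vol = read_volume(path)
    mask = vol.data
    uniq = np.unique(mask)
    if not np.isin(uniq, (0, 1)).all():
        raise FormatError(f"{path}: mask is not strictly binary")
    return mask.astype(np.uint8)


def write_mask(mask: np.ndarray, spacing: Tuple[float, float, float],
               path: os.PathLike | str, origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    write_volume(Volume(np.asarray(mask, dtype=np.uint8), spacing, origin), path)


def _zoom_factors(spacing, target_spacing) -> Tuple[float, ...]:
    return tuple(s / t for s, t in zip(spacing, target_spacing))


def resample_to_grid(vol: Volume, spec: PreprocessSpec) -> Volume:
    """Resample an image volume to ``spec.target_spacing`` with linear interpolation.

    Physical extent is preserved to within one voxel.  Use
    :func:`resample_mask_to_grid` for masks (nearest-neighbour).
    """
    if min(vol.shape) < 2:
        raise ContractError(f"cannot resample degenerate volume of shape {vol.shape}")
    factors = _zoom_factors(vol.spacing, spec.target_spacing)
    if np.allclose(factors, 1.0):
        return replace(vol, data=vol.data.copy(), spacing=tuple(spec.target_spacing))
    out = ndimage.zoom(vol.data.astype(np.float64), factors, order=1,
                       mode="nearest", grid_mode=True)
    return Volume(out, tuple(spec.target_spacing), vol.origin, vol.intensity_kind)


def resample_mask_to_grid(mask: np.ndarray, spacing: Tuple[float, float, float],
                          spec: PreprocessSpec) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask; binarity is preserved."""
    mask = np.asarray(mask)
    if min(mask.shape) < 2:
        raise ContractError(f"cannot resample degenerate mask of shape {mask.shape}")
    factors = _zoom_factors(spacing, spec.target_spacing)
    if np.allclose(factors, 1.0):
        return mask.astype(np.uint8).copy()
    out = ndimage.zoom(mask.astype(np.uint8), factors, order=0,
                       mode="nearest", grid_mode=True)
    return out.astype(np.uint8)


def clip_shift_array(arr: np.ndarray, spec: PreprocessSpec | None = None) -> np.ndarray:
    """``clamp(arr, hu_low, hu_high) + shift`` on a bare array."""
    spec = spec or PreprocessSpec()
    return np.clip(arr, spec.hu_low, spec.hu_high) + spec.shift


def clip_shift_intensity(vol: Volume, spec: PreprocessSpec | None = None) -> Volume:
    """Clip raw HU to ``[hu_low, hu_high]`` and shift into the working range.

    Raises :class:`StateError` on already-preprocessed input to prevent double
    shifting.
    """
    spec = spec or PreprocessSpec()
    if vol.intensity_kind == PREPROCESSED:
        raise StateError("volume is already preprocessed; refusing to shift twice")
    out = clip_shift_array(vol.data.astype(np.float64), spec)
    return Volume(out, vol.spacing, vol.origin, intensity_kind=PREPROCESSED)


# ---------------------------------------------------------------------------
# Per-scan manifest: volume + named masks + provenance in one directory.

def save_scan(scan_dir: os.PathLike | str, vol: Volume, sset: StructureSet) -> Path:
    """Write ``volume.nii`` plus one mask NIfTI per structure and a YAML manifest."""
    scan_dir = Path(scan_dir)
    scan_dir.mkdir(parents=True, exist_ok=True)
    write_volume(vol, scan_dir / "volume.nii")
    manifest: Dict[str, object] = {
        "volume_id": sset.volume_id,
        "volume": "volume.nii",
        "spacing": list(vol.spacing),
        "intensity_kind": vol.intensity_kind,
        "structures": {},
    }
    for name, mask in sset.masks.items():
        fname = f"mask_{name}.nii"
        write_mask(mask, vol.spacing, scan_dir / fname, vol.origin)
        manifest["structures"][name] = {  # type: ignore[index]
            "mask": fname,
            "provenance": sset.provenance[name],
        }
    with open(scan_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return scan_dir / "manifest.yaml"


def load_scan(scan_dir: os.PathLike | str) -> Tuple[Volume, StructureSet]:
    """Load a scan directory written by :func:`save_scan`."""
    scan_dir = Path(scan_dir)
    manifest_path = scan_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.yaml in {scan_dir}")
    with open(manifest_path) as fh:
        manifest: Mapping = yaml.safe_load(fh)
    vol = read_volume(scan_dir / manifest["volume"],
                      intensity_kind=manifest.get("intensity_kind", RAW_HU))
    sset = StructureSet(volume_id=manifest["volume_id"], grid_shape=vol.shape)
    for name, entry in manifest.get("structures", {}).items():
        sset.add_mask(name, read_mask(scan_dir / entry["mask"]), entry["provenance"])
    return vol, sset
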