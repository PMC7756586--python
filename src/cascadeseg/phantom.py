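"""Synthetic pelvic phantoms with exact ground-truth masks.

Each phantom contains several soft-tissue structures (ellipsoidal bladder,
bent rectal tube, thin spinal-cord cylinder, two kidneys), high-intensity
bone (a pelvic ring plus two vertebral blocks), and a Y-shaped vessel whose
bifurcation slice is known by construction: the vessel is a single in-plane
component for every slice ``z >= b`` and exactly two components for
``z < b`` within its axial extent.

Geometry is specified as fractions of the grid so phantoms scale to any
grid shape; ``organ_params`` overrides individual resolved values.
Generation is a pure function of ``(spec, spec.seed)``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .errors import SpecError
from .volume_io import RAW_HU, StructureSet, Volume

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "default_intensity_map",
    "resolve_geometry",
    "generate_phantom",
    "generate_cohort",
    "corrupt_labels",
    "STRUCTURE_ORDER",
]

#: Mask construction order; later structures are carved against earlier ones
#: so ground-truth masks are pairwise non-overlapping.
STRUCTURE_ORDER = (
    "pelvic_bone",
    "vertebra_l4",
    "vertebra_l5",
    "cord",
    "vessel",
    "kidney_l",
    "kidney_r",
    "bladder",
    "rectum",
)

BONE_STRUCTURES = ("pelvic_bone", "vertebra_l4", "vertebra_l5")

#: Fraction of a soft structure allowed to collide with bone before the
#: spec is rejected.
BONE_OVERLAP_TOLERANCE = 0.05


def default_intensity_map() -> Dict[str, float]:
    """Plausible mean HU per structure plus the background."""
    return {
        "background": -50.0,
        "bladder": 80.0,
        "rectum": 20.0,
        "cord": 60.0,
        "kidney_l": 45.0,
        "kidney_r": 45.0,
        "pelvic_bone": 700.0,
        "vertebra_l4": 700.0,
        "vertebra_l5": 700.0,
        "vessel": 150.0,
    }


@dataclass
class PhantomSpec:
    grid_shape: Tuple[int, int, int] = (64, 96, 96)
    spacing: Tuple[float, float, float] = (2.5, 1.17, 1.17)
    organ_params: Dict[str, Dict] = field(default_factory=dict)
    intensity_map: Dict[str, float] = field(default_factory=default_intensity_map)
    noise_sigma: float = 20.0
    contrast_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 8 for s in self.grid_shape):
            raise SpecError(f"grid too small: {self.grid_shape}")
        if not (0.0 < self.contrast_scale <= 1.0):
            raise SpecError("contrast_scale must be in (0, 1]")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be non-negative")

    @property
    def bifurcation_slice(self) -> int:
        return int(resolve_geometry(self)["vessel"]["bifurcation_slice"])


@dataclass
class CorruptionSpec:
    """Covert label perturbations for curation experiments."""

    mode: str = "shift"  # dilate | erode | shift | wrong_level
    magnitude: int = 5
    fraction_corrupted: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("dilate", "erode", "shift", "wrong_level"):
            raise SpecError(f"unknown corruption mode {self.mode!r}")
        if self.magnitude < 1:
            raise SpecError("magnitude must be >= 1 voxel")
        if not (0.0 < self.fraction_corrupted < 1.0):
            raise SpecError("fraction_corrupted must be in (0, 1)")


def _deep_merge(base: Dict, override: Dict) -> Dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_geometry(spec: PhantomSpec) -> Dict[str, Dict]:
    """Resolve fractional defaults to absolute voxel geometry, then apply overrides."""
    nz, ny, nx = spec.grid_shape
    vessel_r = 0.035 * nx
    geo: Dict[str, Dict] = {
        "pelvic_bone": {
            "center_yx": (0.55 * ny, 0.50 * nx),
            "r_outer": 0.44 * min(ny, nx),
            "r_inner": 0.38 * min(ny, nx),
            "z_lo": 0, "z_hi": int(0.36 * nz),
        },
        "vertebra_l4": {
            "z_lo": int(0.56 * nz), "z_hi": int(0.68 * nz),
            "y_lo": int(0.40 * ny), "y_hi": int(0.50 * ny),
            "x_lo": int(0.42 * nx), "x_hi": int(0.58 * nx),
        },
        "vertebra_l5": {
            "z_lo": int(0.41 * nz), "z_hi": int(0.53 * nz),
            "y_lo": int(0.40 * ny), "y_hi": int(0.50 * ny),
            "x_lo": int(0.42 * nx), "x_hi": int(0.58 * nx),
        },
        "cord": {
            "center_yx": (0.53 * ny, 0.50 * nx),
            "radius": 0.030 * ny,
            "z_lo": int(0.25 * nz), "z_hi": int(0.95 * nz),
        },
        "vessel": {
            "center_yx": (0.33 * ny, 0.50 * nx),
            "radius": vessel_r,
            "z_lo": int(0.44 * nz), "z_hi": int(0.78 * nz),
            "bifurcation_slice": int(0.58 * nz),
            "branch_slope": 0.5,
            "branch_gap": vessel_r + 0.6,
        },
        "kidney_l": {
            "center": (0.72 * nz, 0.45 * ny, 0.28 * nx),
            "radii": (0.09 * nz, 0.08 * ny, 0.08 * nx),
        },
        "kidney_r": {
            "center": (0.72 * nz, 0.45 * ny, 0.72 * nx),
            "radii": (0.09 * nz, 0.08 * ny, 0.08 * nx),
        },
        "bladder": {
            "center": (0.28 * nz, 0.70 * ny, 0.50 * nx),
            "radii": (0.11 * nz, 0.14 * ny, 0.14 * nx),
        },
        "rectum": {
            "y_center": 0.82 * ny,
            "amplitude": 0.02 * ny,
            "x_center": 0.50 * nx,
            "radius": 0.042 * ny,
            "z_lo": int(0.08 * nz), "z_hi": int(0.47 * nz),
        },
    }
    geo = _deep_merge(geo, spec.organ_params)
    _validate_geometry(geo, spec.grid_shape)
    return geo


def _validate_geometry(geo: Dict[str, Dict], grid_shape: Tuple[int, int, int]) -> None:
    nz, ny, nx = grid_shape
    v = geo["vessel"]
    if not (v["z_lo"] < v["bifurcation_slice"] < v["z_hi"]):
        raise SpecError(
            f"bifurcation slice {v['bifurcation_slice']} not strictly inside "
            f"vessel extent [{v['z_lo']}, {v['z_hi']}]"
        )
    for name in ("bladder", "kidney_l", "kidney_r"):
        c, r = geo[name]["center"], geo[name]["radii"]
        for axis, n in enumerate((nz, ny, nx)):
            if c[axis] - r[axis] < 0 or c[axis] + r[axis] > n - 1:
                raise SpecError(f"{name} does not fit inside the grid along axis {axis}")
    for name in ("vertebra_l4", "vertebra_l5"):
        g = geo[name]
        if g["z_lo"] < 0 or g["z_hi"] > nz - 1 or g["y_hi"] > ny - 1 or g["x_hi"] > nx - 1:
            raise SpecError(f"{name} does not fit inside the grid")
    rec = geo["rectum"]
    if rec["y_center"] + rec["amplitude"] + rec["radius"] > ny - 1:
        raise SpecError("rectum does not fit inside the grid")


def _ellipsoid(grid_shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0


def _tube_slicewise(grid_shape, z_range, centers_yx, radius) -> np.ndarray:
    """Stack of in-plane discs; ``centers_yx[z]`` is a list of (y, x) centers."""
    nz, ny, nx = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)
    yy, xx = np.ogrid[:ny, :nx]
    for z in z_range:
        for (cy, cx) in centers_yx[z]:
            mask[z] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
    return mask


def _build_raw_shapes(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    geo = resolve_geometry(spec)
    gs = spec.grid_shape
    nz, ny, nx = gs
    shapes: Dict[str, np.ndarray] = {}

    ring = geo["pelvic_bone"]
    yy, xx = np.ogrid[:ny, :nx]
    cy, cx = ring["center_yx"]
    rr = (yy - cy) ** 2 + (xx - cx) ** 2
    annulus = (rr <= ring["r_outer"] ** 2) & (rr >= ring["r_inner"] ** 2)
    bone = np.zeros(gs, dtype=bool)
    bone[ring["z_lo"]: ring["z_hi"] + 1] = annulus
    shapes["pelvic_bone"] = bone

    for name in ("vertebra_l4", "vertebra_l5"):
        g = geo[name]
        block = np.zeros(gs, dtype=bool)
        block[g["z_lo"]: g["z_hi"] + 1, g["y_lo"]: g["y_hi"] + 1, g["x_lo"]: g["x_hi"] + 1] = True
        shapes[name] = block

    cord = geo["cord"]
    zr = range(cord["z_lo"], min(cord["z_hi"], nz - 1) + 1)
    centers = {z: [cord["center_yx"]] for z in zr}
    shapes["cord"] = _tube_slicewise(gs, zr, centers, cord["radius"])

    ves = geo["vessel"]
    b = int(ves["bifurcation_slice"])
    vcy, vcx = ves["center_yx"]
    vr = ves["radius"]
    zr = range(ves["z_lo"], min(ves["z_hi"], nz - 1) + 1)
    centers = {}
    for z in zr:
        if z >= b:
            centers[z] = [(vcy, vcx)]
        else:
            off = ves["branch_slope"] * (b - z) + ves["branch_gap"]
            centers[z] = [(vcy, vcx - off), (vcy, vcx + off)]
    vessel = _tube_slicewise(gs, zr, centers, vr)
    if b in zr:
        # the junction slice is a single laterally elongated lumen that
        # overlaps both branch roots, keeping the Y one 3D component
        a_x = ves["branch_slope"] + ves["branch_gap"] + vr
        yy, xx = np.ogrid[:ny, :nx]
        vessel[b] |= (((yy - vcy) / vr) ** 2 + ((xx - vcx) / a_x) ** 2) <= 1.0
    shapes["vessel"] = vessel

    for name in ("kidney_l", "kidney_r", "bladder"):
        g = geo[name]
        shapes[name] = _ellipsoid(gs, g["center"], g["radii"])

    rec = geo["rectum"]
    zr = range(rec["z_lo"], min(rec["z_hi"], nz - 1) + 1)
    span = max(rec["z_hi"] - rec["z_lo"], 1)
    centers = {
        z: [(rec["y_center"] + rec["amplitude"] * math.sin(2 * math.pi * (z - rec["z_lo"]) / span),
             rec["x_center"])]
        for z in zr
    }
    shapes["rectum"] = _tube_slicewise(gs, zr, centers, rec["radius"])
    return shapes


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, StructureSet]:
    """Build a raw-HU phantom volume and its exact ground-truth masks.

    Raises :class:`SpecError` if a soft structure overlaps bone beyond
    tolerance or geometry does not fit the grid.
    """
    shapes = _build_raw_shapes(spec)

    bone_union = np.zeros(spec.grid_shape, dtype=bool)
    for name in BONE_STRUCTURES:
        bone_union |= shapes[name]
    for name, shape in shapes.items():
        if name in BONE_STRUCTURES:
            continue
        n_vox = int(shape.sum())
        overlap = int((shape & bone_union).sum())
        if n_vox and overlap / n_vox > BONE_OVERLAP_TOLERANCE:
            raise SpecError(
                f"structure {name!r} overlaps bone by {overlap}/{n_vox} voxels "
                f"(> {BONE_OVERLAP_TOLERANCE:.0%} tolerance)"
            )

    # Carve in fixed order so masks are pairwise disjoint.
    occupied = np.zeros(spec.grid_shape, dtype=bool)
    masks: Dict[str, np.ndarray] = {}
    for name in STRUCTURE_ORDER:
        carved = shapes[name] & ~occupied
        occupied |= carved
        masks[name] = carved.astype(np.uint8)

    bg = spec.intensity_map.get("background", -50.0)
    data = np.full(spec.grid_shape, bg, dtype=np.float64)
    for name in STRUCTURE_ORDER:
        mean_hu = spec.intensity_map.get(name, bg)
        data[masks[name] > 0] = bg + spec.contrast_scale * (mean_hu - bg)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=spec.grid_shape)

    vol = Volume(data.astype(np.float32), spec.spacing, intensity_kind=RAW_HU)
    sset = StructureSet(volume_id=f"phantom_{spec.seed:05d}", grid_shape=spec.grid_shape,
                        masks=masks, provenance={n: "ground_truth" for n in masks})
    return vol, sset


def _jitter_spec(template: PhantomSpec, rng: np.random.Generator,
                 jitter: Dict[str, float]) -> Dict[str, Dict]:
    c = float(jitter.get("center", 2.0))
    rf = float(jitter.get("radii_frac", 0.08))
    bj = int(jitter.get("bifurcation", 2))
    base = resolve_geometry(template)
    over: Dict[str, Dict] = {}
    for name in ("bladder", "kidney_l", "kidney_r"):
        center = tuple(v + rng.uniform(-c, c) for v in base[name]["center"])
        radii = tuple(r * (1.0 + rng.uniform(-rf, rf)) for r in base[name]["radii"])
        over[name] = {"center": center, "radii": radii}
    over["rectum"] = {"y_center": base["rectum"]["y_center"] + rng.uniform(-c / 2, c / 2)}
    if bj > 0:
        over["vessel"] = {
            "bifurcation_slice": int(base["vessel"]["bifurcation_slice"]
                                     + rng.integers(-bj, bj + 1))
        }
    return over


def generate_cohort(spec_template: PhantomSpec, n: int,
                    jitter: Dict[str, float] | None = None,
                    seed: int = 0) -> List[Tuple[Volume, StructureSet]]:
    """Generate ``n`` phantoms with independently jittered organ geometry.

    ``jitter`` keys: ``center`` (voxels), ``radii_frac`` (fraction),
    ``bifurcation`` (slices).  Pass ``{"center": 0, "radii_frac": 0,
    "bifurcation": 0}`` for identical geometry.  Deterministic under ``seed``.
    """
    if n < 2:
        raise SpecError("cohort size must be >= 2")
    jitter = {"center": 2.0, "radii_frac": 0.08, "bifurcation": 2} if jitter is None else jitter
    cohort = []
    seeds = np.random.SeedSequence(seed).spawn(n)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        phantom_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            over = _jitter_spec(spec_template, rng, jitter)
            spec_i = PhantomSpec(
                grid_shape=spec_template.grid_shape,
                spacing=spec_template.spacing,
                organ_params=_deep_merge(spec_template.organ_params, over),
                intensity_map=dict(spec_template.intensity_map),
                noise_sigma=spec_template.noise_sigma,
                contrast_scale=spec_template.contrast_scale,
                seed=phantom_seed,
            )
            vol, sset = generate_phantom(spec_i)
        except SpecError as exc:
            raise SpecError(f"phantom {i}: {exc}") from exc
        sset.volume_id = f"phantom_{i:03d}"
        cohort.append((vol, sset))
    return cohort


def _shift_mask(mask: np.ndarray, shift: Sequence[int]) -> np.ndarray:
    """Translate with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        n = mask.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src[ax], dst[ax] = slice(0, n - s), slice(s, n)
        else:
            src[ax], dst[ax] = slice(-s, n), slice(0, n + s)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _corrupt_one(mask: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator) -> np.ndarray:
    m = spec.magnitude
    zs, ys, xs = np.nonzero(mask)
    if zs.size == 0:
        raise SpecError("cannot corrupt an empty mask")
    extent = (zs.max() - zs.min() + 1, ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    if spec.mode == "dilate":
        return ndimage.binary_dilation(mask, iterations=m).astype(np.uint8)
    if spec.mode == "erode":
        if min(extent[1], extent[2]) <= 2 * m:
            raise SpecError(f"erosion magnitude {m} exceeds structure extent {extent}")
        return ndimage.binary_erosion(mask, iterations=m).astype(np.uint8)
    if spec.mode == "shift":
        if m >= min(mask.shape):
            raise SpecError(f"shift magnitude {m} exceeds grid {mask.shape}")
        axis = int(rng.integers(1, 3))  # in-plane shift
        sign = 1 if rng.random() < 0.5 else -1
        shift = [0, 0, 0]
        shift[axis] = sign * m
        return _shift_mask(mask, shift)
    # wrong_level: move the structure up by one "level" (its own axial
    # thickness plus the magnitude), mimicking a vertebral mislabel.
    dz = int(extent[0]) + m
    if dz >= mask.shape[0]:
        raise SpecError(f"wrong_level shift {dz} exceeds axial grid {mask.shape[0]}")
    return _shift_mask(mask, [dz, 0, 0])


def corrupt_labels(cohort: Iterable[StructureSet], spec: CorruptionSpec
                   ) -> Tuple[List[StructureSet], Set[Tuple[str, str]]]:
    """Covertly perturb ``ceil(fraction * n)`` labels, one structure per scan.

    Provenance stays ``ground_truth`` (corruption is covert).  Returns the
    perturbed copies and the set of corrupted ``(volume_id, structure)`` pairs
    for test oracles.
    """
    sets = [s.copy() for s in cohort]
    if not sets:
        raise SpecError("cohort is empty")
    n_corrupt = math.ceil(spec.fraction_corrupted * len(sets))
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(len(sets), size=n_corrupt, replace=False)
    corrupted_ids: Set[Tuple[str, str]] = set()
    for idx in chosen:
        sset = sets[int(idx)]
        if spec.mode == "wrong_level":
            candidates = [s for s in sset.structures() if s.startswith("vertebra")]
        else:
            candidates = list(sset.structures())
        if not candidates:
            raise SpecError(f"scan {sset.volume_id} has no corruptible structure")
        structure = candidates[int(rng.integers(len(candidates)))]
        new_mask = _corrupt_one(sset.masks[structure], spec, rng)
        sset.masks[structure] = new_mask
        corrupted_ids.add((sset.volume_id, structure))
    return sets, corrupted_ids
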