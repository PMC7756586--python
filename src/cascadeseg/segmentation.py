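"""Trainable 2D/3D segmenters, soft Dice loss, coarse-to-fine refinement, fusion.

The published architectures are replaced by a compact pluggable model: a
per-voxel multi-channel logistic classifier over local image features
(multi-scale smoothed intensities, their squares, gradient magnitude, and
normalized coordinates), trained with the soft Dice loss and Adam.  Every
pipeline contract — per-voxel probabilities per structure channel, 2D vs 3D
mode, multi-label heads, augmentation, coarse→crop→refine, 2D∪3D fusion —
is honored by this model, so a heavier network can be swapped in unchanged.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ContractError, DataError, EmptyMaskError
from .extent import ExtentInterval
from .optim import Adam, OptimizerConfig
from .volume_io import RAW_HU, StructureSet, Volume, clip_shift_array

__all__ = [
    "OptimizerConfig",
    "AugmentSpec",
    "CropSpec",
    "SegPrediction",
    "soft_dice_loss",
    "VoxelSegmenter",
    "train_segmenter",
    "train_refine_segmenter",
    "default_crop_box",
    "coarse_segment",
    "center_of_mass",
    "refine_segment",
    "fuse_2d3d",
]

DICE_EPS = 1.0  # smoothing term in numerator and denominator


@dataclass
class AugmentSpec:
    hflip: bool = True
    rotation_range: Tuple[float, float] = (-30.0, 30.0)
    crop_center_jitter: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range
        if lo < -180 or hi > 180 or lo > hi:
            raise ContractError(f"invalid rotation range {self.rotation_range}")

    @property
    def enabled(self) -> bool:
        return self.hflip or self.rotation_range != (0.0, 0.0)


@dataclass
class CropSpec:
    center: Optional[Tuple[int, int, int]]
    box_shape: Tuple[int, int, int]
    coarse_shape: Optional[Tuple[int, int]] = None


@dataclass
class SegPrediction:
    structure: str
    mask: np.ndarray
    stage: str  # coarse | refined | fused_2d3d

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ContractError("prediction mask must be 3D")
        uniq = np.unique(self.mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ContractError("prediction mask must be binary")
        self.mask = self.mask.astype(np.uint8)


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = DICE_EPS) -> float:
    """``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

    Always in [0, 1]; equals ``1 - DSC`` on binary inputs up to ``eps``.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ContractError(f"shape mismatch {pred.shape} vs {target.shape}")
    if pred.size and (pred.min() < 0 or pred.max() > 1):
        raise ContractError("pred must lie in [0, 1]")
    num = 2.0 * float((pred * target).sum()) + eps
    den = float(pred.sum()) + float(target.sum()) + eps
    return 1.0 - num / den


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _preprocessed(data: np.ndarray, kind: str) -> np.ndarray:
    data = np.asarray(data, dtype=np.float64)
    return clip_shift_array(data) if kind == RAW_HU else data


# one sample = (image array, channel-stacked targets (C, z, y, x))
Sample = Tuple[np.ndarray, np.ndarray]
SampleProvider = Callable[[np.random.Generator], List[Sample]]


class VoxelSegmenter:
    """Per-voxel logistic model over local features; one sigmoid channel per structure."""

    #: Centers (in (intensity - 1000)/100 units) of the intensity basis bumps.
    INTENSITY_RBF_CENTERS = (-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0, 3.5, 5.0, 7.0)

    def __init__(self, structures: Sequence[str], mode: str = "3d"):
        if mode not in ("2d", "3d"):
            raise ContractError(f"mode must be '2d' or '3d', got {mode!r}")
        if not structures:
            raise ContractError("at least one structure channel required")
        self.structures = list(structures)
        self.mode = mode
        self.W: Optional[np.ndarray] = None  # (F, C)
        self.b: Optional[np.ndarray] = None  # (C,)
        self.feat_mean: Optional[np.ndarray] = None
        self.feat_std: Optional[np.ndarray] = None
        self.loss_history_: List[float] = []
        self.stream_digest_: str = ""

    # -- features ----------------------------------------------------------
    def features(self, data: np.ndarray) -> np.ndarray:
        """(n_voxels, F) feature matrix for a preprocessed (sub)volume."""
        if self.mode == "3d":
            s1 = ndimage.gaussian_filter(data, sigma=(0.6, 1.0, 1.0))
            s2 = ndimage.gaussian_filter(data, sigma=(1.5, 2.5, 2.5))
        else:
            s1 = ndimage.gaussian_filter(data, sigma=(0.0, 1.0, 1.0))
            s2 = ndimage.gaussian_filter(data, sigma=(0.0, 2.5, 2.5))
        n0 = (data - 1000.0) / 100.0
        n1 = (s1 - 1000.0) / 100.0
        n2 = (s2 - 1000.0) / 100.0
        gz, gy, gx = np.gradient(s1)
        grad = np.sqrt(gz ** 2 + gy ** 2 + gx ** 2) / 100.0
        nz, ny, nx = data.shape
        zc = np.linspace(-1, 1, nz)[:, None, None] * np.ones(data.shape)
        yc = np.linspace(-1, 1, ny)[None, :, None] * np.ones(data.shape)
        xc = np.linspace(-1, 1, nx)[None, None, :] * np.ones(data.shape)
        rad = yc ** 2 + xc ** 2
        feats = [n0, n0 ** 2, n1, n2, n1 ** 2, n2 ** 2, grad, yc, xc, rad]
        # radial-basis bumps over intensity give the linear head true band
        # selectivity (a monotone or quadratic response cannot single out a
        # narrow HU range without also firing on bone)
        for c in self.INTENSITY_RBF_CENTERS:
            feats.append(np.exp(-((n0 - c) ** 2) / (2 * 0.35 ** 2)))
            feats.append(np.exp(-((n1 - c) ** 2) / (2 * 0.5 ** 2)))
        if self.mode == "3d":
            # zc^2 and the intensity x zc interaction let a linear head carve
            # axial bands (adjacent same-intensity structures, e.g. vertebrae)
            feats.extend([zc, zc ** 2, n2 * zc])
        return np.stack([f.ravel() for f in feats], axis=1)

    # -- training ----------------------------------------------------------
    def fit(self, sample_provider: SampleProvider, opt_cfg: OptimizerConfig,
            aug: Optional[AugmentSpec] = None) -> "VoxelSegmenter":
        rng = np.random.default_rng(opt_cfg.seed)
        aug = aug or AugmentSpec(hflip=False, rotation_range=(0.0, 0.0),
                                 crop_center_jitter=False)
        digest = hashlib.md5()
        params: Optional[Dict[str, np.ndarray]] = None
        adam = Adam(opt_cfg)
        n_channels = len(self.structures)
        warmup = max(1, opt_cfg.epochs // 4) if opt_cfg.epochs > 4 else 0
        for epoch in range(opt_cfg.epochs):
            samples = sample_provider(rng)
            if not samples:
                raise DataError("sample provider returned no training samples")
            epoch_losses = []
            for s_idx, (data, targets) in enumerate(samples):
                data, targets = self._augment(data, targets, aug, rng)
                if s_idx == 0:
                    digest.update(np.ascontiguousarray(data, dtype=np.float32).tobytes())
                X = self.features(data)
                T = targets.reshape(n_channels, -1)
                sel = self._subsample(T, rng, opt_cfg.batch_size)
                Xb, Tb = X[sel], T[:, sel]
                if params is None:
                    self.feat_mean = X.mean(axis=0)
                    self.feat_std = X.std(axis=0) + 1e-9
                    params = {
                        "W": rng.normal(0, 0.01, size=(X.shape[1], n_channels)),
                        "b": np.zeros(n_channels),
                    }
                Xs = (Xb - self.feat_mean) / self.feat_std
                P = _sigmoid(Xs @ params["W"] + params["b"])
                if epoch < warmup:
                    # short cross-entropy warm-up: the Dice gradient carries a
                    # p(1-p) factor, so confidently-wrong voxels would start
                    # with vanishing gradients and never be corrected
                    loss, dZ = _ce_loss_and_grad(P, Tb.T)
                else:
                    loss, dZ = _dice_loss_and_grad(P, Tb.T)
                epoch_losses.append(loss)
                grads = {"W": Xs.T @ dZ, "b": dZ.sum(axis=0)}
                adam.step(params, grads)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        assert params is not None
        self.W, self.b = params["W"], params["b"]
        self.stream_digest_ = digest.hexdigest()
        return self

    def _augment(self, data: np.ndarray, targets: np.ndarray, aug: AugmentSpec,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        if aug.hflip and rng.random() < 0.5:
            data = data[:, :, ::-1].copy()
            targets = targets[:, :, :, ::-1].copy()
        lo, hi = aug.rotation_range
        if hi > lo:
            angle = float(rng.uniform(lo, hi))
            if abs(angle) > 1e-9:
                # in-plane rotation about the axial axis; linear for image,
                # nearest for masks
                data = ndimage.rotate(data, angle, axes=(1, 2), reshape=False,
                                      order=1, mode="nearest")
                targets = ndimage.rotate(targets, angle, axes=(2, 3), reshape=False,
                                         order=0, mode="constant", cval=0)
        return data, targets

    @staticmethod
    def _subsample(T: np.ndarray, rng: np.random.Generator, batch_size: int) -> np.ndarray:
        n_vox = T.shape[1]
        if n_vox <= 65536:
            return np.arange(n_vox)
        # large volumes: every foreground voxel (capped) plus a generous
        # background draw — thin structures need many hard negatives
        fg = np.flatnonzero(T.any(axis=0))
        bg = np.flatnonzero(~T.any(axis=0))
        n_fg = min(fg.size, batch_size)
        if n_fg and fg.size > n_fg:
            fg = rng.choice(fg, size=n_fg, replace=False)
        n_bg = min(bg.size, max(8 * max(n_fg, 1), 16384))
        if bg.size > n_bg:
            bg = rng.choice(bg, size=n_bg, replace=False)
        return np.concatenate([fg, bg])

    # -- inference ---------------------------------------------------------
    def predict_proba(self, data: np.ndarray, intensity_kind: str = "preprocessed",
                      extent: Optional[ExtentInterval] = None) -> np.ndarray:
        """(C, nz, ny, nx) probabilities; zero outside the extent slices."""
        if self.W is None:
            raise ContractError("segmenter is not fitted")
        data = _preprocessed(data, intensity_kind)
        out = np.zeros((len(self.structures),) + data.shape)
        sub = data if extent is None else data[extent.lo: extent.hi + 1]
        X = self.features(sub)
        Xs = (X - self.feat_mean) / self.feat_std
        P = _sigmoid(Xs @ self.W + self.b)
        probs = P.T.reshape((len(self.structures),) + sub.shape)
        if extent is None:
            out = probs
        else:
            out[:, extent.lo: extent.hi + 1] = probs
        return out

    def predict_mask(self, data: np.ndarray, intensity_kind: str = "preprocessed",
                     extent: Optional[ExtentInterval] = None,
                     structure: Optional[str] = None, threshold: float = 0.5) -> np.ndarray:
        probs = self.predict_proba(data, intensity_kind, extent)
        idx = 0 if structure is None else self.structures.index(structure)
        return (probs[idx] >= threshold).astype(np.uint8)

    def predict_multilabel(self, data: np.ndarray, intensity_kind: str = "preprocessed",
                           extent: Optional[ExtentInterval] = None,
                           threshold: float = 0.5) -> Dict[str, np.ndarray]:
        """Disjoint per-structure masks: argmax over channels where max prob > threshold."""
        probs = self.predict_proba(data, intensity_kind, extent)
        winner = probs.argmax(axis=0)
        confident = probs.max(axis=0) >= threshold
        return {
            name: ((winner == c) & confident).astype(np.uint8)
            for c, name in enumerate(self.structures)
        }

    # -- persistence -------------------------------------------------------
    def get_params(self) -> dict:
        return {"structures": self.structures, "mode": self.mode, "W": self.W,
                "b": self.b, "feat_mean": self.feat_mean, "feat_std": self.feat_std}

    @classmethod
    def from_params(cls, params: dict) -> "VoxelSegmenter":
        model = cls([str(s) for s in np.asarray(params["structures"]).ravel()],
                    str(params["mode"]))
        model.W = np.asarray(params["W"])
        model.b = np.asarray(params["b"])
        model.feat_mean = np.asarray(params["feat_mean"])
        model.feat_std = np.asarray(params["feat_std"])
        return model


def _ce_loss_and_grad(P: np.ndarray, T: np.ndarray) -> Tuple[float, np.ndarray]:
    """Class-balanced cross-entropy; gradient w.r.t. logits is bounded away
    from zero for confidently wrong voxels."""
    n, n_channels = P.shape
    Pc = np.clip(P, 1e-7, 1 - 1e-7)
    w_pos = np.maximum((T == 0).sum(axis=0), 1) / np.maximum(T.sum(axis=0), 1)
    loss = float(-np.mean(w_pos * T * np.log(Pc) + (1 - T) * np.log(1 - Pc)))
    dZ = (w_pos * T * (P - 1) + (1 - T) * P) / (n * n_channels)
    return loss, dZ


def _dice_loss_and_grad(P: np.ndarray, T: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean per-channel soft Dice loss and its gradient w.r.t. the logits.

    ``P`` and ``T`` are (n_voxels, C).
    """
    eps = DICE_EPS
    n_channels = P.shape[1]
    dZ = np.empty_like(P)
    losses = []
    for c in range(n_channels):
        p, t = P[:, c], T[:, c]
        num = 2.0 * float((p * t).sum()) + eps
        den = float(p.sum() + t.sum()) + eps
        losses.append(1.0 - num / den)
        dLdp = -(2.0 * t * den - num) / den ** 2
        dZ[:, c] = dLdp * p * (1.0 - p) / n_channels
    return float(np.mean(losses)), dZ


def _stack_targets(sset: StructureSet, structures: Sequence[str]) -> np.ndarray:
    return np.stack([sset.masks[s] for s in structures]).astype(np.float64)


def _downsample_inplane(data: np.ndarray, targets: np.ndarray,
                        coarse_shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    ny, nx = data.shape[1], data.shape[2]
    cy, cx = coarse_shape
    if (cy, cx) == (ny, nx):
        return data, targets
    factors = (1.0, cy / ny, cx / nx)
    small = ndimage.zoom(data, factors, order=1, mode="nearest")
    small_t = np.stack([ndimage.zoom(t, factors, order=0, mode="nearest")
                        for t in targets])
    return small, small_t


def train_segmenter(cohort: Sequence[Tuple[Volume, StructureSet]],
                    structures: str | Sequence[str], mode: str,
                    opt: OptimizerConfig, aug: Optional[AugmentSpec] = None,
                    extents: Optional[Dict[str, ExtentInterval]] = None,
                    coarse_shape: Optional[Tuple[int, int]] = None) -> VoxelSegmenter:
    """Train a (possibly multi-label) segmenter on full volumes.

    Training is restricted to the slices inside each scan's (padded) extent
    when ``extents`` maps volume ids to intervals.  When ``coarse_shape`` is
    given the model is trained on in-plane downsampled volumes and must be
    applied through :func:`coarse_segment` with the same shape.
    """
    names = [structures] if isinstance(structures, str) else list(structures)
    usable = [(v, s) for v, s in cohort if all(n in s.masks for n in names)]
    if len(usable) < 2:
        raise DataError(f"structures {names} present in {len(usable)} scan(s); need >= 2")
    samples: List[Sample] = []
    for vol, sset in usable:
        data = _preprocessed(vol.data, vol.intensity_kind)
        targets = _stack_targets(sset, names)
        if extents and sset.volume_id in extents:
            ext = extents[sset.volume_id]
            data = data[ext.lo: ext.hi + 1]
            targets = targets[:, ext.lo: ext.hi + 1]
        if coarse_shape is not None:
            data, targets = _downsample_inplane(data, targets, tuple(coarse_shape))
        if targets.any():
            samples.append((data, targets))
    if not samples:
        raise DataError("empty training set after extent restriction")
    model = VoxelSegmenter(names, mode)
    model.fit(lambda rng: samples, opt, aug)
    return model


def default_crop_box(cohort: Sequence[Tuple[Volume, StructureSet]], structure: str,
                     dilate_frac: float = 0.25) -> Tuple[int, int, int]:
    """Per-structure crop box: the cohort's tight bounding box dilated per axis."""
    sizes = []
    grid = None
    for _, sset in cohort:
        if structure not in sset.masks:
            continue
        mask = sset.masks[structure]
        grid = mask.shape
        idx = np.nonzero(mask)
        if idx[0].size == 0:
            continue
        sizes.append([int(ax.max() - ax.min() + 1) for ax in idx])
    if not sizes:
        raise DataError(f"no non-empty {structure!r} masks in cohort")
    box = np.ceil(np.max(sizes, axis=0) * (1.0 + dilate_frac)).astype(int)
    return tuple(int(min(b, g)) for b, g in zip(box, grid))


def _crop_slices(center: Sequence[int], box_shape: Sequence[int],
                 grid_shape: Sequence[int]) -> Tuple[slice, slice, slice]:
    out = []
    for c, b, g in zip(center, box_shape, grid_shape):
        start = int(np.clip(int(c) - b // 2, 0, max(g - b, 0)))
        out.append(slice(start, min(start + b, g)))
    return tuple(out)  # type: ignore[return-value]


def train_refine_segmenter(cohort: Sequence[Tuple[Volume, StructureSet]], structure: str,
                           opt: OptimizerConfig, aug: Optional[AugmentSpec] = None,
                           box_shape: Optional[Tuple[int, int, int]] = None,
                           mode: str = "3d") -> Tuple[VoxelSegmenter, Tuple[int, int, int]]:
    """Train the second-stage model on crops around the structure.

    The crop center is drawn uniformly over the ground-truth bounding box each
    epoch when ``aug.crop_center_jitter`` is on (otherwise the mask centroid).
    Returns the model together with the crop box it was trained with.
    """
    usable = [(v, s) for v, s in cohort if structure in s.masks and s.masks[structure].any()]
    if len(usable) < 2:
        raise DataError(f"structure {structure!r} present in {len(usable)} scan(s); need >= 2")
    box = box_shape or default_crop_box(usable, structure)
    aug = aug if aug is not None else AugmentSpec()
    prepped = [(_preprocessed(v.data, v.intensity_kind), s.masks[structure].astype(np.float64))
               for v, s in usable]

    def provider(rng: np.random.Generator) -> List[Sample]:
        samples = []
        for data, mask in prepped:
            idx = np.nonzero(mask)
            los = [int(ax.min()) for ax in idx]
            his = [int(ax.max()) for ax in idx]
            if aug.crop_center_jitter:
                center = [int(rng.integers(lo, hi + 1)) for lo, hi in zip(los, his)]
            else:
                center = [int(round((lo + hi) / 2)) for lo, hi in zip(los, his)]
            sl = _crop_slices(center, box, data.shape)
            samples.append((data[sl], mask[sl][None]))
        return samples

    model = VoxelSegmenter([structure], mode)
    model.fit(provider, opt, aug)
    return model, box


def coarse_segment(model: VoxelSegmenter, vol: Volume, extent: ExtentInterval,
                   coarse_shape: Optional[Tuple[int, int]] = None,
                   structure: Optional[str] = None) -> SegPrediction:
    """Segment on an in-plane downsampled grid, then upsample back (nearest)."""
    if extent is None:
        raise ContractError("coarse_segment requires a valid extent")
    if not isinstance(extent, ExtentInterval):
        raise ContractError("extent must be an ExtentInterval")
    if extent.hi >= vol.n_slices:
        raise ContractError(f"extent {extent} outside volume with {vol.n_slices} slices")
    name = structure or model.structures[0]
    data = _preprocessed(vol.data, vol.intensity_kind)
    nz, ny, nx = data.shape
    if coarse_shape is None or tuple(coarse_shape) == (ny, nx):
        mask = model.predict_mask(data, "preprocessed", extent, structure=name)
        return SegPrediction(structure=name, mask=mask, stage="coarse")
    cy, cx = coarse_shape
    factors = (1.0, cy / ny, cx / nx)
    small = ndimage.zoom(data, factors, order=1, mode="nearest")
    sub_extent = ExtentInterval(extent.lo, min(extent.hi, small.shape[0] - 1))
    small_mask = model.predict_mask(small, "preprocessed", sub_extent, structure=name)
    up = ndimage.zoom(small_mask, (1.0, ny / small_mask.shape[1], nx / small_mask.shape[2]),
                      order=0, mode="nearest")
    # rounding in zoom can leave an off-by-one; crop/pad to the native grid
    fixed = np.zeros((nz, ny, nx), dtype=np.uint8)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(up.shape, fixed.shape))
    fixed[sl] = up[sl]
    return SegPrediction(structure=name, mask=fixed, stage="coarse")


def center_of_mass(mask: np.ndarray) -> Tuple[int, int, int]:
    """Unweighted mean foreground coordinate, rounded to the nearest voxel."""
    idx = np.nonzero(np.asarray(mask))
    if idx[0].size == 0:
        raise EmptyMaskError("center_of_mass of an empty mask is undefined")
    return tuple(int(np.floor(ax.mean() + 0.5)) for ax in idx)  # type: ignore[return-value]


def refine_segment(coarse: SegPrediction, vol: Volume, refine_model: VoxelSegmenter,
                   crop: CropSpec) -> SegPrediction:
    """Resegment at native resolution inside a crop box centered on the coarse mask.

    An empty coarse prediction falls back to returning it unchanged with a
    warning; the scan is then recorded as a failure case by the caller.
    """
    if not coarse.mask.any():
        warnings.warn(f"empty coarse prediction for {coarse.structure!r}; "
                      "returning it unchanged", stacklevel=2)
        return coarse
    center = crop.center if crop.center is not None else center_of_mass(coarse.mask)
    data = _preprocessed(vol.data, vol.intensity_kind)
    sl = _crop_slices(center, crop.box_shape, data.shape)
    sub_mask = refine_model.predict_mask(data[sl], "preprocessed", structure=coarse.structure)
    full = np.zeros_like(coarse.mask)
    full[sl] = sub_mask
    return SegPrediction(structure=coarse.structure, mask=full, stage="refined")


def fuse_2d3d(pred2d: SegPrediction, pred3d: SegPrediction) -> SegPrediction:
    """Voxelwise union of the 2D and 3D predictions."""
    if pred2d.mask.shape != pred3d.mask.shape:
        raise ContractError("cannot fuse predictions on different grids")
    if pred2d.structure != pred3d.structure:
        raise ContractError("cannot fuse predictions of different structures")
    fused = (pred2d.mask | pred3d.mask).astype(np.uint8)
    return SegPrediction(structure=pred2d.structure, mask=fused, stage="fused_2d3d")
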