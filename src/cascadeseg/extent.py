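"""Per-slice organ presence classification and cranial-caudal extent postprocessing.

A small logistic model over per-slice intensity features stands in for the
large 2D classification network: the pipeline only depends on the contract
*fit on labeled slices, emit a per-slice presence probability*.  The loss is
weighted cross-entropy with the positive-class weight taken as the ratio of
absent to present slices in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ContractError, DataError, EmptyExtentError
from .optim import Adam, OptimizerConfig
from .volume_io import RAW_HU, StructureSet, Volume, clip_shift_array

__all__ = [
    "SlicePresenceSeries",
    "ExtentInterval",
    "ClassifierConfig",
    "weighted_ce_loss",
    "slice_features",
    "PresenceClassifier",
    "train_presence_classifier",
    "extent_postprocess",
    "pad_extent",
]

#: Clamp applied to probabilities inside the loss; never NaN.
PROB_EPS = 1e-7

#: Intensity band edges (working-range units) used as slice histogram features.
#: The fine bands around 1000-1150 resolve the narrow soft-tissue HU ranges.
BAND_EDGES = np.array(
    [0.0, 500.0, 900.0, 985.0, 1005.0, 1032.0, 1052.0, 1070.0,
     1092.0, 1115.0, 1250.0, 1500.0, 4001.0]
)


@dataclass
class SlicePresenceSeries:
    structure: str
    probs: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1:
            raise ContractError("probs must be a 1D per-slice array")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ContractError("probs must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.probs.shape:
                raise ContractError("labels must align with probs")


@dataclass(frozen=True)
class ExtentInterval:
    """Inclusive axial slice range [lo, hi]."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ContractError(f"invalid extent [{self.lo}, {self.hi}]")

    @property
    def n_slices(self) -> int:
        return self.hi - self.lo + 1

    def contains(self, z: int) -> bool:
        return self.lo <= z <= self.hi


@dataclass
class ClassifierConfig:
    model_factory: Optional[Callable[[], "PresenceClassifier"]] = None
    loss_weight_mode: str = "auto_ratio"  # auto_ratio | fixed
    fixed_weight: float = 1.0
    optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(learning_rate=0.3, epochs=200))
    threshold: float = 0.5
    max_gap: int = 2
    pad: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_weight_mode not in ("auto_ratio", "fixed"):
            raise ContractError(f"unknown loss_weight_mode {self.loss_weight_mode!r}")
        if self.optimizer.epochs < 1:
            raise ContractError("epochs must be >= 1")


def weighted_ce_loss(probs: np.ndarray, labels: np.ndarray, w: float) -> float:
    """``-mean[w*y*log p + (1-y)*log(1-p)]`` with probabilities clamped by eps.

    Reduces to standard cross-entropy at ``w = 1``.
    """
    if w <= 0:
        raise ContractError("positive-class weight must be > 0")
    probs = np.clip(np.asarray(probs, dtype=np.float64), PROB_EPS, 1.0 - PROB_EPS)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ContractError("probs and labels must have the same shape")
    return float(-np.mean(w * labels * np.log(probs) + (1 - labels) * np.log(1 - probs)))


def auto_class_weight(labels: np.ndarray) -> float:
    """Positive-class weight = number of absences / number of presences."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0:
        raise DataError("no presence slices in the training labels")
    return n_neg / n_pos if n_neg else 1.0


def slice_features(vol: Volume) -> np.ndarray:
    """Per-slice feature matrix: intensity-band fractions, moments, block means."""
    data = vol.data.astype(np.float64)
    if vol.intensity_kind == RAW_HU:
        data = clip_shift_array(data)
    nz, ny, nx = data.shape
    smooth = np.stack([ndimage.gaussian_filter(data[z], sigma=1.0) for z in range(nz)])
    flat = smooth.reshape(nz, -1)
    # fraction of slice pixels per intensity band
    idx = np.searchsorted(BAND_EDGES, flat, side="right") - 1
    idx = np.clip(idx, 0, len(BAND_EDGES) - 2)
    bands = np.stack([(idx == k).mean(axis=1) for k in range(len(BAND_EDGES) - 1)], axis=1)
    moments = np.stack([flat.mean(axis=1) / 1000.0, flat.std(axis=1) / 1000.0], axis=1)
    # 4x4 block means capture coarse in-plane layout
    by, bx = max(ny // 4, 1), max(nx // 4, 1)
    blocks = smooth[:, : by * 4, : bx * 4].reshape(nz, 4, by, 4, bx).mean(axis=(2, 4))
    blocks = blocks.reshape(nz, 16) / 1000.0
    return np.concatenate([bands, moments, blocks], axis=1)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PresenceClassifier:
    """Logistic slice-presence model trained with weighted cross-entropy + Adam."""

    def __init__(self, structure: str = ""):
        self.structure = structure
        self.w: Optional[np.ndarray] = None
        self.b: float = 0.0
        self.feat_mean: Optional[np.ndarray] = None
        self.feat_std: Optional[np.ndarray] = None
        self.class_weight_: float = 1.0
        self.loss_history_: List[float] = []

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_std

    def fit(self, X: np.ndarray, y: np.ndarray, class_weight: float,
            opt_cfg: OptimizerConfig) -> "PresenceClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.feat_mean = X.mean(axis=0)
        self.feat_std = X.std(axis=0) + 1e-9
        Xs = self._standardize(X)
        rng = np.random.default_rng(opt_cfg.seed)
        self.w = rng.normal(0, 0.01, size=X.shape[1])
        self.b = 0.0
        self.class_weight_ = float(class_weight)
        adam = Adam(opt_cfg)
        params = {"w": self.w, "b": np.array([self.b])}
        n = X.shape[0]
        for _ in range(opt_cfg.epochs):
            p = _sigmoid(Xs @ params["w"] + params["b"][0])
            self.loss_history_.append(weighted_ce_loss(p, y, class_weight))
            # d loss / d logit for the weighted CE
            dz = (class_weight * y * (p - 1) + (1 - y) * p) / n
            grads = {"w": Xs.T @ dz, "b": np.array([dz.sum()])}
            adam.step(params, grads)
        self.w = params["w"]
        self.b = float(params["b"][0])
        return self

    def predict_probs(self, X: np.ndarray) -> np.ndarray:
        if self.w is None:
            raise ContractError("classifier is not fitted")
        return _sigmoid(self._standardize(np.asarray(X, dtype=np.float64)) @ self.w + self.b)

    def predict(self, vol: Volume, labels: Optional[np.ndarray] = None) -> SlicePresenceSeries:
        probs = self.predict_probs(slice_features(vol))
        return SlicePresenceSeries(structure=self.structure, probs=probs, labels=labels)

    def get_params(self) -> dict:
        return {"structure": self.structure, "w": self.w, "b": self.b,
                "feat_mean": self.feat_mean, "feat_std": self.feat_std,
                "class_weight": self.class_weight_}

    @classmethod
    def from_params(cls, params: dict) -> "PresenceClassifier":
        model = cls(structure=str(params["structure"]))
        model.w = np.asarray(params["w"])
        model.b = float(params["b"])
        model.feat_mean = np.asarray(params["feat_mean"])
        model.feat_std = np.asarray(params["feat_std"])
        model.class_weight_ = float(params["class_weight"])
        return model


def train_presence_classifier(cohort: Sequence[Tuple[Volume, StructureSet]],
                              structure: str, cfg: ClassifierConfig) -> PresenceClassifier:
    """Train a per-slice presence model for one structure.

    The per-slice label is "mask non-empty on that slice"; the class weight is
    absences/presences of the pooled training slices under ``auto_ratio``.
    """
    scans = [(v, s) for v, s in cohort if structure in s.masks]
    if len(scans) < 2:
        raise DataError(
            f"structure {structure!r} present in {len(scans)} scan(s); need >= 2")
    feats, labels = [], []
    for vol, sset in scans:
        feats.append(slice_features(vol))
        labels.append((sset.masks[structure].sum(axis=(1, 2)) > 0).astype(np.float64))
    X = np.concatenate(feats, axis=0)
    y = np.concatenate(labels, axis=0)
    if y.sum() == 0:
        raise DataError(f"structure {structure!r} empty in every training scan")
    w = auto_class_weight(y) if cfg.loss_weight_mode == "auto_ratio" else cfg.fixed_weight
    model = (cfg.model_factory() if cfg.model_factory else PresenceClassifier(structure))
    opt = OptimizerConfig(**{**cfg.optimizer.__dict__, "seed": cfg.seed})
    model.fit(X, y, class_weight=w, opt_cfg=opt)
    return model


def _runs_of_ones(binary: np.ndarray) -> List[Tuple[int, int]]:
    runs = []
    start = None
    for i, v in enumerate(binary):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(binary) - 1))
    return runs


def extent_postprocess(series: SlicePresenceSeries, threshold: float = 0.5,
                       max_gap: int = 2) -> ExtentInterval:
    """Binarize, fill internal gaps of length <= ``max_gap``, take the longest run.

    Ties between equally long runs are broken toward the run with the larger
    summed probability.  Raises :class:`EmptyExtentError` when no slice
    exceeds the threshold.
    """
    probs = series.probs
    if probs.size == 0:
        raise ContractError("empty probability series")
    binary = (probs >= threshold).astype(np.int8)
    if not binary.any():
        raise EmptyExtentError(
            f"no slice reaches presence threshold {threshold} for {series.structure!r}")
    if max_gap > 0:
        ones = _runs_of_ones(binary)
        for (s1, e1), (s2, _) in zip(ones, ones[1:]):
            if s2 - e1 - 1 <= max_gap:
                binary[e1 + 1: s2] = 1
    runs = _runs_of_ones(binary)
    best = max(runs, key=lambda r: (r[1] - r[0] + 1, probs[r[0]: r[1] + 1].sum()))
    return ExtentInterval(lo=best[0], hi=best[1])


def pad_extent(extent: ExtentInterval, n_slices: int, pad: int = 1) -> ExtentInterval:
    """Pad the interval by ``pad`` slices on each end, clamped to the grid."""
    return ExtentInterval(lo=max(0, extent.lo - pad), hi=min(n_slices - 1, extent.hi + pad))
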