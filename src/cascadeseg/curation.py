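"""Semi-automatic label curation by half-split cross-training.

Each iteration: split the labeled scans in half, train one model per half,
predict each half with the other half's model, flag every label whose DSC
against the cross-prediction falls below the structure's threshold (0.7 for
the rectum, 0.8 otherwise), send flagged labels to a reviewer, and remove
the ones judged incorrect.  The loop repeats from scratch on the refined
cohort (three iterations by default) with a fresh split each time.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CurationError, DataError
from .metrics import dice
from .volume_io import StructureSet, Volume

__all__ = [
    "CurationConfig",
    "CurationRecord",
    "split_halves",
    "cross_train_flag",
    "curation_loop",
    "write_ledger_csv",
    "always_keep_reviewer",
    "oracle_reviewer",
]

DEFAULT_THRESHOLD = 0.8

# reviewer(scan_id, structure, mask, cross_dsc) -> "keep" | "remove"
Reviewer = Callable[[str, str, np.ndarray, float], str]

# train_fn(half_cohort, structure) -> predictor(volume, scan_id) -> binary mask
TrainFn = Callable[[Sequence[Tuple[Volume, StructureSet]], str],
                   Callable[[Volume, str], np.ndarray]]


@dataclass
class CurationConfig:
    dsc_threshold: Dict[str, float] = field(default_factory=lambda: {"rectum": 0.7})
    default_threshold: float = DEFAULT_THRESHOLD
    n_iterations: int = 3
    split_seed: int = 0
    reviewer: Optional[Reviewer] = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise CurationError("n_iterations must be >= 1")
        for name, thr in {**self.dsc_threshold, "_default": self.default_threshold}.items():
            if not (0.0 < thr < 1.0):
                raise CurationError(f"threshold for {name!r} must be in (0, 1)")

    def threshold(self, structure: str) -> float:
        return self.dsc_threshold.get(structure, self.default_threshold)


@dataclass
class CurationRecord:
    scan_id: str
    structure: str
    iteration: int
    cross_dsc: float
    flagged: bool
    verdict: str = "not_reviewed"  # kept | removed | not_reviewed

    def __post_init__(self) -> None:
        if self.verdict not in ("kept", "removed", "not_reviewed"):
            raise CurationError(f"unknown verdict {self.verdict!r}")
        if self.verdict != "not_reviewed" and not self.flagged:
            raise CurationError("only flagged records can carry a review verdict")


def always_keep_reviewer(scan_id: str, structure: str, mask: np.ndarray,
                         cross_dsc: float) -> str:
    return "keep"


def oracle_reviewer(corrupted_ids) -> Reviewer:
    """Reviewer that removes a label iff its (scan, structure) id is known corrupted."""
    corrupted = set(corrupted_ids)

    def review(scan_id: str, structure: str, mask: np.ndarray, cross_dsc: float) -> str:
        return "remove" if (scan_id, structure) in corrupted else "keep"

    return review


def split_halves(ids: Sequence[str], seed: int) -> Tuple[List[str], List[str]]:
    """Disjoint, exhaustive halves (sizes differ by <= 1), deterministic under seed."""
    ids = list(ids)
    if len(ids) < 4:
        raise DataError(f"need >= 4 scans to split, got {len(ids)}")
    order = list(np.random.default_rng(seed).permutation(len(ids)))
    half = (len(ids) + 1) // 2
    half_a = sorted(ids[i] for i in order[:half])
    half_b = sorted(ids[i] for i in order[half:])
    return half_a, half_b


def cross_train_flag(cohort: Sequence[Tuple[Volume, StructureSet]], structure: str,
                     cfg: CurationConfig, train_fn: TrainFn,
                     iteration: int = 0) -> List[CurationRecord]:
    """Train on each half, predict the other, flag labels below threshold."""
    labeled = [(v, s) for v, s in cohort if structure in s.masks]
    ids = [s.volume_id for _, s in labeled]
    if len(set(ids)) != len(ids):
        raise CurationError("duplicate volume ids in cohort")
    half_a, half_b = split_halves(ids, cfg.split_seed + iteration)
    by_id = {s.volume_id: (v, s) for v, s in labeled}
    set_a = [by_id[i] for i in half_a]
    set_b = [by_id[i] for i in half_b]
    if not any(structure in s.masks for _, s in set_a) or \
       not any(structure in s.masks for _, s in set_b):
        raise DataError(f"structure {structure!r} missing from one half")
    predictors = {}
    for name, train_half in (("A", set_a), ("B", set_b)):
        try:
            predictors[name] = train_fn(train_half, structure)
        except Exception as exc:
            raise CurationError(f"training failed on half {name}: {exc}") from exc
    thr = cfg.threshold(structure)
    records = []
    for predict, test_half in ((predictors["B"], set_a), (predictors["A"], set_b)):
        for vol, sset in test_half:
            pred_mask = np.asarray(predict(vol, sset.volume_id))
            cross = dice(sset.masks[structure], pred_mask)
            records.append(CurationRecord(
                scan_id=sset.volume_id, structure=structure, iteration=iteration,
                cross_dsc=cross, flagged=cross < thr))
    records.sort(key=lambda r: r.scan_id)
    return records


def curation_loop(cohort: Sequence[Tuple[Volume, StructureSet]],
                  structures: Sequence[str], cfg: CurationConfig,
                  train_fn: TrainFn
                  ) -> Tuple[List[Tuple[Volume, StructureSet]], List[CurationRecord]]:
    """Run the flag→review→remove loop for ``cfg.n_iterations`` iterations.

    Removal deletes only the flagged structure's label from the scan, never
    the scan itself, so refinement is monotone.  Returns the refined cohort
    (copies) and the full ledger.
    """
    reviewer = cfg.reviewer or always_keep_reviewer
    working = [(v, s.copy()) for v, s in cohort]
    ledger: List[CurationRecord] = []
    for iteration in range(cfg.n_iterations):
        for structure in structures:
            labeled = [(v, s) for v, s in working if structure in s.masks]
            if len(labeled) < 4:
                warnings.warn(
                    f"curation stopped early for {structure!r} at iteration "
                    f"{iteration}: only {len(labeled)} labeled scans remain",
                    stacklevel=2)
                continue
            records = cross_train_flag(working, structure, cfg, train_fn, iteration)
            by_id = {s.volume_id: s for _, s in working}
            for rec in records:
                if rec.flagged:
                    verdict = reviewer(rec.scan_id, rec.structure,
                                       by_id[rec.scan_id].masks[rec.structure],
                                       rec.cross_dsc)
                    rec.verdict = "removed" if verdict == "remove" else "kept"
                    if rec.verdict == "removed":
                        by_id[rec.scan_id].remove_mask(rec.structure)
                ledger.append(rec)
    return working, ledger


def write_ledger_csv(ledger: Sequence[CurationRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scan", "structure", "iteration", "cross_dsc",
                         "flagged", "verdict"])
        for rec in ledger:
            writer.writerow([rec.scan_id, rec.structure, rec.iteration,
                             f"{rec.cross_dsc:.6f}", int(rec.flagged), rec.verdict])
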