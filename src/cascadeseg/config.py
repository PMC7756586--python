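"""Configuration schema for the pipeline CLI.

A single YAML file drives phantom generation, training, prediction,
curation, and evaluation.  The shipped defaults route each structure the way
the full system does: bony structures through one 3D multi-label model, the
thin/elongated structures through 2D models, the compact soft organs through
3D models with coarse-to-fine refinement, and the nodal region through
refinement plus 2D∪3D fusion and the bifurcation border rule.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .errors import ContractError

__all__ = ["StructurePlan", "PipelineConfig", "load_config", "DEFAULT_CONFIG"]


@dataclass
class StructurePlan:
    name: str
    seg_mode: str = "3d"  # 2d | 3d
    members: Optional[List[str]] = None  # multi-label groups
    use_refine: bool = False
    use_fusion_2d: bool = False
    border: Optional[str] = None  # nodal_superior | pan_inferior
    crop_from: Optional[str] = None  # restrict field of view around this structure
    requires: List[str] = field(default_factory=list)
    curation_threshold: Optional[float] = None
    trim: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seg_mode not in ("2d", "3d"):
            raise ContractError(f"{self.name}: seg_mode must be 2d or 3d")
        if self.border not in (None, "nodal_superior", "pan_inferior"):
            raise ContractError(f"{self.name}: unknown border rule {self.border!r}")

    @property
    def structures(self) -> List[str]:
        return self.members if self.members else [self.name]


def _default_registry() -> Dict[str, StructurePlan]:
    plans = [
        StructurePlan("vertebra_l4l5", seg_mode="3d",
                      members=["vertebra_l4", "vertebra_l5"]),
        StructurePlan("pelvic_bone", seg_mode="3d"),
        StructurePlan("bladder", seg_mode="3d", use_refine=True),
        StructurePlan("kidney_l", seg_mode="3d", use_refine=True),
        StructurePlan("kidney_r", seg_mode="3d", use_refine=True),
        StructurePlan("rectum", seg_mode="3d", use_refine=True,
                      curation_threshold=0.7, trim=("inferior",)),
        StructurePlan("cord", seg_mode="2d", trim=("inferior",)),
        StructurePlan("vessel", seg_mode="3d", crop_from="vertebra_l4",
                      requires=["vertebra_l4l5"]),
        StructurePlan("nodal", seg_mode="3d", use_refine=True, use_fusion_2d=True,
                      border="nodal_superior", requires=["vessel"]),
        StructurePlan("pan", seg_mode="2d", border="pan_inferior",
                      requires=["vessel"], trim=("superior",)),
    ]
    return {p.name: p for p in plans}


DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "phantom": {
        "grid_shape": [64, 96, 96],
        "spacing": [2.5, 1.17, 1.17],
        "noise_sigma": 20.0,
        "contrast_scale": 1.0,
    },
    "preprocess": {"hu_low": -1000.0, "hu_high": 3000.0, "shift": 1000.0},
    "classifier": {"learning_rate": 0.3, "epochs": 200, "threshold": 0.5,
                   "max_gap": 2, "pad": 1},
    "optimizer": {"learning_rate": 0.1, "epochs": 30, "batch_size": 4096},
    "augment": {"hflip": True, "rotation_range": [-30.0, 30.0],
                "crop_center_jitter": True},
    "coarse_frac": 0.5,
    "curation": {"n_iterations": 3, "default_threshold": 0.8,
                 "thresholds": {"rectum": 0.7}},
    "structures": ["vertebra_l4l5", "bladder", "kidney_l", "kidney_r",
                   "rectum", "cord", "vessel"],
}


@dataclass
class PipelineConfig:
    raw: Dict
    registry: Dict[str, StructurePlan] = field(default_factory=_default_registry)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def plan(self, name: str) -> StructurePlan:
        if name not in self.registry:
            raise ContractError(f"no registry entry for structure {name!r}")
        return self.registry[name]

    def section(self, key: str) -> Dict:
        merged = copy.deepcopy(DEFAULT_CONFIG.get(key, {}))
        merged.update(self.raw.get(key, {}) or {})
        return merged

    @property
    def train_structures(self) -> List[str]:
        return list(self.raw.get("structures", DEFAULT_CONFIG["structures"]))


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load a YAML config merged over the shipped defaults."""
    raw = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(raw.get(key), dict):
                raw[key].update(val)
            else:
                raw[key] = val
    cfg = PipelineConfig(raw=raw)
    overrides = raw.get("registry", {}) or {}
    for name, entry in overrides.items():
        base = cfg.registry.get(name)
        kwargs = dict(base.__dict__) if base else {"name": name}
        kwargs.update(entry)
        kwargs["trim"] = tuple(kwargs.get("trim", ()))
        cfg.registry[name] = StructurePlan(**kwargs)
    return cfg
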