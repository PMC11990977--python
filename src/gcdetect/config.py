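"""YAML configuration loading for the command-line tools.

A config file is a nested mapping with optional sections ``detector``,
``backbone``, ``anchors``, ``schedule`` and ``scenes``; unknown keys are
rejected so typos fail loudly.  Example::

    detector:
      num_classes: 5
      regression_loss: eiou
    backbone:
      preset: tiny
      gct_placement: layer123
      cbam_locations: [C2, C3, C4, C5]
    schedule:
      policy: cosine_warmup
      warmup_steps: 100
    scenes:
      num_classes: 5
      image_size: [128, 128]
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .detector import AnchorConfig, DetectorConfig
from .schedule import ScheduleConfig
from .synthetic_scenes import SceneConfig

__all__ = ["load_config", "detector_from_config", "scenes_from_config",
           "schedule_from_config", "save_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {"detector", "backbone", "anchors", "schedule", "scenes"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections {sorted(unknown)}; "
                         f"expected subset of {sorted(known)}")
    return data


def _build(cls, section: dict, label: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in [{label}]")
    coerced = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in section.items()}
    return cls(**coerced)


def detector_from_config(data: dict) -> DetectorConfig:
    det = dict(data.get("detector", {}))
    unknown_keys = {"backbone", "anchors"} & set(det)
    if unknown_keys:
        raise ValueError("put backbone/anchors in their own sections")
    cfg = _build(DetectorConfig, det, "detector")
    if "backbone" in data:
        cfg.backbone = _build(BackboneConfig, data["backbone"], "backbone")
    if "anchors" in data:
        cfg.anchors = _build(AnchorConfig, data["anchors"], "anchors")
    return cfg


def schedule_from_config(data: dict, total_steps: int) -> ScheduleConfig:
    section = dict(data.get("schedule", {}))
    section.setdefault("total_steps", total_steps)
    return _build(ScheduleConfig, section, "schedule")


def scenes_from_config(data: dict) -> SceneConfig:
    return _build(SceneConfig, data.get("scenes", {}), "scenes")


def save_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
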