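"""Configuration for thresholds and body proportions.

All tunable numbers live here so a deployment can swap them without code
changes: posture-bin tolerances, the wrist-twist fold threshold, leg
anomaly limits, annotation-aggregation options, and the proportional limb
model used by the synthetic generator.  Configs load from YAML or JSON and
hash canonically for report provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "RulaConfig",
    "AggregationConfig",
    "SyntheticConfig",
    "ErgokitConfig",
    "load_config",
    "config_hash",
    "DEFAULT_LIMB_LENGTHS_MM",
    "ANATOMICAL_RANGES_DEG",
]


@dataclass(frozen=True)
class RulaConfig:
    """Thresholds for posture coding and the leg-anomaly fallback."""

    #: |wrist flexion| at or below this (deg) counts as the neutral position
    wrist_neutral_tol: float = 1.0
    #: |wrist deviation| above this (deg) adds the deviation point
    wrist_deviation_threshold: float = 10.0
    #: folded palm-normal angle below this (deg) codes the twist near end-range
    wrist_twist_end_range: float = 45.0
    #: |trunk flexion| at or below this (deg) counts as supported-upright
    trunk_upright_tol: float = 3.0
    #: neck flexion below -tol (deg) counts as extension
    neck_extension_tol: float = 1.0
    #: leg joints below this confidence trigger the upper-body-only fallback
    leg_confidence_threshold: float = 0.3
    #: leg segment lengths outside [median/r, median*r] trigger the fallback
    leg_length_ratio: float = 1.3
    #: ankle height gap (mm) beyond which legs are coded unsupported
    ankle_height_tol_mm: float = 100.0
    #: frames/second retained when assessing a sequence
    sample_fps: float = 1.0


@dataclass(frozen=True)
class AggregationConfig:
    """Options for multi-annotator consensus."""

    #: "median" (robust, default) or "mean"
    statistic: str = "median"
    #: "joints": minimal box over aggregated joints; "boxes": per-coordinate
    #: median of the annotators' boxes
    bbox_mode: str = "joints"
    #: fractional expansion of the minimal joint box per side
    bbox_margin: float = 0.05


#: 50th-percentile adult proportional model, mm
DEFAULT_LIMB_LENGTHS_MM: dict[str, float] = {
    "trunk": 450.0,
    "neck": 250.0,
    "shoulder_width": 380.0,
    "hip_width": 320.0,
    "upper_arm": 280.0,
    "forearm": 250.0,
    "hand": 180.0,
    "thumb": 60.0,
    "thigh": 420.0,
    "shank": 400.0,
    "foot": 200.0,
}

#: declared anatomical ranges for recipe validation, degrees
ANATOMICAL_RANGES_DEG: dict[str, tuple[float, float]] = {
    "upper_arm_flexion": (-60.0, 180.0),
    "elbow_flexion": (0.0, 150.0),
    "wrist_flexion": (-90.0, 90.0),
    "wrist_deviation": (-45.0, 45.0),
    "wrist_twist": (0.0, 90.0),
    "neck_flexion": (-60.0, 60.0),
    "trunk_flexion": (-30.0, 90.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Body proportions and feasibility ranges for the generator."""

    limb_lengths_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIMB_LENGTHS_MM)
    )
    anatomical_ranges_deg: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ANATOMICAL_RANGES_DEG)
    )


@dataclass(frozen=True)
class ErgokitConfig:
    rula: RulaConfig = field(default_factory=RulaConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_hash(cfg: ErgokitConfig) -> str:
    """Stable short hash of a config for report provenance."""
    payload = json.dumps(_to_plain(cfg), sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> ErgokitConfig:
    """Load a config from YAML/JSON, or return defaults when ``path`` is None.

    The file may specify any subset of keys; unspecified values keep their
    defaults.  Unknown keys raise, to catch typos early.
    """
    if path is None:
        return ErgokitConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    def build(cls, data: Mapping[str, Any]):
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**data)

    kwargs: dict[str, Any] = {}
    if "rula" in raw:
        kwargs["rula"] = build(RulaConfig, raw["rula"])
    if "aggregation" in raw:
        kwargs["aggregation"] = build(AggregationConfig, raw["aggregation"])
    if "synthetic" in raw:
        syn = dict(raw["synthetic"])
        if "anatomical_ranges_deg" in syn:
            syn["anatomical_ranges_deg"] = {
                k: tuple(v) for k, v in syn["anatomical_ranges_deg"].items()
            }
        kwargs["synthetic"] = build(SyntheticConfig, syn)
    unknown = set(raw) - {"rula", "aggregation", "synthetic"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return ErgokitConfig(**kwargs)
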