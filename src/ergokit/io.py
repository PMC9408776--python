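"""Readers, writers and report handling.

Keypoint files follow the COCO keypoints JSON layout — an ``images`` array
and an ``annotations`` array whose ``keypoints`` field is a flat
``[x, y, v, x, y, v, ...]`` triplet list in the dialect's joint order —
extended with an optional per-joint ``z`` array (mm) for 3D sources and a
top-level ``skeleton``/``fps``.  Visibility triplet flags map onto the
package's trichotomy: 2 → visible, 1 → invisible-but-identifiable,
0 → absent.

Assessment reports are flat CSV tables (UTF-8, comma, header row, '.'
decimal), one row per assessed frame, carrying the per-part codes of both
sides, the table scores, the grand score and action level, plus run
metadata (dialect, config hash, tool version) held alongside the rows.
Reports are deterministic: identical inputs and config produce identical
rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _version
from .aggregation import Annotation, RecommendedValue
from .config import ErgokitConfig, config_hash
from .rula import BodyPartScores, ManualInputs, PART_RANGES, RulaResult, score_tables
from .skeleton import (
    Keypoint,
    PoseFrame,
    PoseSequence,
    SkeletonSpec,
    Visibility,
    load_skeleton_spec,
)

__all__ = [
    "SchemaError",
    "read_keypoints",
    "write_keypoints",
    "read_annotations_jsonl",
    "write_annotations_jsonl",
    "export_coco",
    "AssessmentReport",
    "results_to_dataframe",
    "sort_report",
    "edit_and_rescore",
]

_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A keypoint or annotation file violates the documented layout."""

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path


def _require(cond: bool, message: str, path: str) -> None:
    if not cond:
        raise SchemaError(message, path)


# ---------------------------------------------------------------------------
# Keypoint JSON


def write_keypoints(seq: PoseSequence, path: str | Path) -> None:
    """Write a pose sequence as extended COCO-style keypoints JSON."""
    spec = load_skeleton_spec(seq.skeleton) if seq.skeleton else None
    images = []
    annotations = []
    for i, frame in enumerate(seq.frames):
        images.append({"id": i, "time": frame.timestamp, "subject_id": frame.subject_id})
        kps: list[float] = []
        zs: list[Optional[float]] = []
        for jname in spec.joint_names:
            kp = frame.keypoints.get(jname, Keypoint.absent())
            if kp.is_absent:
                kps += [0.0, 0.0, 0]
                zs.append(None)
            else:
                kps += [kp.x, kp.y, kp.visibility.to_coco()]
                zs.append(kp.z)
        annotations.append({"image_id": i, "keypoints": kps, "z": zs})
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "skeleton": seq.skeleton,
        "fps": seq.fps,
        "images": images,
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_keypoints(path: str | Path, dialect: Optional[str] = None) -> PoseSequence:
    """Read an extended COCO-style keypoints JSON file.

    ``dialect`` overrides the file's ``skeleton`` field; a mismatch between
    the triplet count and the dialect's joint count is a schema error.  No
    partial sequence is ever returned: any violation raises
    :class:`SchemaError` with the offending location.
    """
    raw_text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(raw_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON: {exc}", "$") from exc
    _require(isinstance(doc, dict), "root must be an object", "$")
    name = dialect or doc.get("skeleton")
    _require(isinstance(name, str), "missing skeleton dialect", "$.skeleton")
    spec = load_skeleton_spec(name)

    images = doc.get("images")
    _require(isinstance(images, list), "images must be an array", "$.images")
    annotations = doc.get("annotations")
    _require(isinstance(annotations, list), "annotations must be an array", "$.annotations")
    fps = doc.get("fps", 30.0)
    _require(isinstance(fps, (int, float)) and fps > 0, "fps must be positive", "$.fps")

    meta: dict[int, dict] = {}
    for i, img in enumerate(images):
        _require(isinstance(img, dict) and "id" in img, "image needs an id", f"$.images[{i}]")
        meta[img["id"]] = img

    frames: list[PoseFrame] = []
    for i, ann in enumerate(annotations):
        loc = f"$.annotations[{i}]"
        _require(isinstance(ann, dict), "annotation must be an object", loc)
        _require("image_id" in ann, "annotation needs image_id", loc)
        kps = ann.get("keypoints")
        _require(isinstance(kps, list), "keypoints must be an array", f"{loc}.keypoints")
        _require(
            len(kps) == 3 * len(spec),
            f"expected {3 * len(spec)} keypoint values for {name!r}, got {len(kps)}",
            f"{loc}.keypoints",
        )
        zs = ann.get("z")
        if zs is not None:
            _require(
                isinstance(zs, list) and len(zs) == len(spec),
                f"z must be an array of {len(spec)} values",
                f"{loc}.z",
            )
        keypoints: dict[str, Keypoint] = {}
        for j, jname in enumerate(spec.joint_names):
            x, y, v = kps[3 * j : 3 * j + 3]
            _require(
                isinstance(v, (int, float)) and int(v) in (0, 1, 2),
                f"visibility flag must be 0/1/2, got {v!r}",
                f"{loc}.keypoints[{3 * j + 2}]",
            )
            vis = Visibility.from_coco(int(v))
            if vis is Visibility.ABSENT:
                keypoints[jname] = Keypoint.absent()
                continue
            _require(
                all(isinstance(c, (int, float)) and math.isfinite(c) for c in (x, y)),
                "coordinates must be finite numbers",
                f"{loc}.keypoints[{3 * j}]",
            )
            z = zs[j] if zs is not None else None
            if z is not None:
                _require(
                    isinstance(z, (int, float)) and math.isfinite(z),
                    "z must be a finite number or null",
                    f"{loc}.z[{j}]",
                )
            keypoints[jname] = Keypoint(x=float(x), y=float(y), z=None if z is None else float(z), visibility=vis)
        img = meta.get(ann["image_id"], {})
        frames.append(
            PoseFrame(
                skeleton=name,
                keypoints=keypoints,
                timestamp=float(img.get("time", i / fps)),
                subject_id=str(img.get("subject_id", "")),
            )
        )
    frames.sort(key=lambda f: f.timestamp)
    return PoseSequence(frames=tuple(frames), fps=float(fps))


# ---------------------------------------------------------------------------
# Annotation JSON-lines


def write_annotations_jsonl(annotations: Sequence[Annotation], path: str | Path) -> None:
    """One Annotation object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            joints = {}
            for name, kp in a.joints.items():
                if kp.is_absent:
                    joints[name] = None
                else:
                    joints[name] = [kp.x, kp.y, kp.visibility.to_coco()]
            fh.write(
                json.dumps(
                    {
                        "annotator_id": a.annotator_id,
                        "image_id": a.image_id,
                        "joints": joints,
                        "bbox": list(a.bbox) if a.bbox else None,
                    }
                )
                + "\n"
            )


def read_annotations_jsonl(path: str | Path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            loc = f"line {lineno}"
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"invalid JSON: {exc}", loc) from exc
            _require(isinstance(rec, dict), "record must be an object", loc)
            for key in ("annotator_id", "image_id", "joints"):
                _require(key in rec, f"missing {key!r}", loc)
            joints: dict[str, Keypoint] = {}
            for name, val in rec["joints"].items():
                if val is None:
                    joints[name] = Keypoint.absent()
                else:
                    _require(
                        isinstance(val, list) and len(val) == 3,
                        f"joint {name!r} must be [x, y, v] or null",
                        loc,
                    )
                    joints[name] = Keypoint(
                        x=float(val[0]), y=float(val[1]), z=None,
                        visibility=Visibility.from_coco(int(val[2])),
                    )
            bbox = rec.get("bbox")
            out.append(
                Annotation(
                    annotator_id=str(rec["annotator_id"]),
                    image_id=str(rec["image_id"]),
                    joints=joints,
                    bbox=tuple(bbox) if bbox else None,
                )
            )
    return out


def export_coco(records: Sequence[RecommendedValue], path: str | Path, dialect: str = "dywhse25") -> None:
    """Export confirmed recommended values as COCO keypoints JSON."""
    spec = load_skeleton_spec(dialect)
    images = []
    annotations = []
    for i, rv in enumerate(records):
        if rv.status != "confirmed":
            continue
        images.append({"id": i, "file_name": rv.image_id})
        kps: list[float] = []
        for jname in spec.joint_names:
            if jname in rv.joints:
                x, y = rv.joints[jname]
                kps += [x, y, 2]
            else:
                kps += [0.0, 0.0, 0]
        ann: dict[str, Any] = {"image_id": i, "keypoints": kps}
        if rv.bbox is not None:
            ann["bbox"] = list(rv.bbox)
        annotations.append(ann)
    doc = {"schema_version": _SCHEMA_VERSION, "skeleton": dialect, "images": images, "annotations": annotations}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Assessment reports

_PARTS = tuple(PART_RANGES)


def results_to_dataframe(results: Sequence[RulaResult]) -> pd.DataFrame:
    """One row per assessed frame; deterministic column order."""
    rows = []
    for r in results:
        row: dict[str, Any] = {
            "timestamp": r.timestamp,
            "headline_side": r.headline_side,
            "grand_score": r.grand_score,
            "action_level": r.action_level,
            "upper_body_only": r.upper_body_only,
            "unassessable_reason": r.unassessable_reason or "",
        }
        for side in ("left", "right"):
            sr = getattr(r, side)
            for part in _PARTS:
                row[f"{side}_{part}"] = getattr(sr.scores, part) if sr else None
            row[f"{side}_table_a"] = sr.table_a if sr else None
            row[f"{side}_table_b"] = sr.table_b if sr else None
            row[f"{side}_grand_score"] = sr.grand_score if sr else None
            row[f"{side}_action_level"] = sr.action_level if sr else None
        if r.measurements is not None:
            row.update({f"meas_{k}": v for k, v in r.measurements.as_flat_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssessmentReport:
    """Assessment rows plus run metadata (dialect, config hash, version)."""

    rows: pd.DataFrame
    skeleton: str
    config: ErgokitConfig = field(default_factory=ErgokitConfig)
    sort_order: str = "timestamp"

    @property
    def metadata(self) -> dict[str, str]:
        return {
            "skeleton": self.skeleton,
            "config_hash": config_hash(self.config),
            "tool_version": _version,
            "sort_order": self.sort_order,
        }

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)
        Path(str(path) + ".meta.json").write_text(
            json.dumps(self.metadata, indent=1) + "\n", encoding="utf-8"
        )


_SORT_KEYS = {"score": "grand_score", "action_level": "action_level", "timestamp": "timestamp"}


def sort_report(report: AssessmentReport, key: str, threshold: Optional[int] = None) -> AssessmentReport:
    """Stable sort, descending by key; optional action-level floor filter.

    ``threshold`` keeps only rows whose action level is at or above it, the
    review interface for focusing on high-risk postures.
    """
    if key not in _SORT_KEYS:
        raise ValueError(f"sort key must be one of {sorted(_SORT_KEYS)}, got {key!r}")
    col = _SORT_KEYS[key]
    rows = report.rows
    if threshold is not None:
        rows = rows[rows["action_level"].notna() & (rows["action_level"] >= threshold)]
    rows = rows.sort_values(col, ascending=(key == "timestamp"), kind="stable").reset_index(drop=True)
    return replace(report, rows=rows, sort_order=key)


def edit_and_rescore(
    report: AssessmentReport,
    row: int,
    part_overrides: Mapping[str, int],
    side: Optional[str] = None,
    manual: ManualInputs = ManualInputs(),
) -> AssessmentReport:
    """Recompute one row's scores from expert-overridden posture codes.

    The overridden codes replace the row's codes for the chosen side (its
    headline side by default), the tables and action level are recomputed,
    and the original values are retained in ``*_orig`` audit columns.
    Overriding the legs code of an upper-body-only row is rejected: that
    row's legs contribution is fixed by the occlusion fallback.
    """
    rows = report.rows.copy()
    if not 0 <= row < len(rows):
        raise IndexError(f"row {row} out of range 0..{len(rows) - 1}")
    rec = rows.iloc[row]
    side = side or rec["headline_side"]
    if side not in ("left", "right"):
        raise ValueError(f"row {row} has no assessable side to edit")
    unknown = set(part_overrides) - set(_PARTS)
    if unknown:
        raise ValueError(f"unknown posture parts: {sorted(unknown)}")
    if bool(rec["upper_body_only"]) and "legs" in part_overrides:
        raise ValueError(
            "row is upper-body-only: the legs code is fixed at 1 by the "
            "occlusion fallback and cannot be overridden"
        )
    codes = {part: rec[f"{side}_{part}"] for part in _PARTS}
    if any(pd.isna(v) for v in codes.values()):
        raise ValueError(f"row {row} side {side!r} has uncodable parts; cannot rescore")
    codes = {k: int(v) for k, v in codes.items()}
    codes.update({k: int(v) for k, v in part_overrides.items()})
    result = score_tables(BodyPartScores(side=side, **codes), manual)

    for col in ("grand_score", "action_level", f"{side}_table_a", f"{side}_table_b"):
        audit = f"{col}_orig"
        if audit not in rows.columns:
            rows[audit] = rows[col.replace("_orig", "")]
        rows.loc[rows.index[row], audit] = rec[col]
    for part, value in part_overrides.items():
        audit = f"{side}_{part}_orig"
        if audit not in rows.columns:
            rows[audit] = rows[f"{side}_{part}"]
        rows.loc[rows.index[row], audit] = rec[f"{side}_{part}"]
        rows.loc[rows.index[row], f"{side}_{part}"] = int(value)
    idx = rows.index[row]
    rows.loc[idx, f"{side}_table_a"] = result.table_a
    rows.loc[idx, f"{side}_table_b"] = result.table_b
    rows.loc[idx, f"{side}_grand_score"] = result.grand_score
    rows.loc[idx, f"{side}_action_level"] = result.action_level
    rows.loc[idx, "grand_score"] = result.grand_score
    rows.loc[idx, "action_level"] = result.action_level
    rows.loc[idx, "headline_side"] = side
    return replace(report, rows=rows)
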