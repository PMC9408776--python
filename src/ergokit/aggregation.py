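"""Multi-annotator keypoint aggregation and inspection workflow.

Several annotators tag the same image; the consensus "recommended value"
per joint is the componentwise median over the annotators who tagged it —
robust to the occasional gross mis-entry that a mean would follow.  The
recommended bounding box is the minimal axis-aligned rectangle covering the
aggregated joints (expanded by a small margin); a per-coordinate median of
the annotators' own boxes is available behind a config switch.  An
inspector then confirms (optionally after moving joints) or drops each
record; only confirmed records are exported.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import AggregationConfig
from .skeleton import Keypoint, Visibility

__all__ = [
    "Annotation",
    "RecommendedValue",
    "ImmutabilityError",
    "aggregate_joints",
    "filter_annotators",
    "confirm_or_drop",
    "export_confirmed",
]


class ImmutabilityError(RuntimeError):
    """A confirmed or dropped record was edited."""


@dataclass(frozen=True)
class Annotation:
    """One annotator's joint tags for one image (2D pixels)."""

    annotator_id: str
    image_id: str
    joints: Mapping[str, Keypoint]
    bbox: Optional[tuple[float, float, float, float]] = None  # x, y, w, h

    def __post_init__(self) -> None:
        if self.bbox is not None:
            x, y, w, h = self.bbox
            if w <= 0 or h <= 0:
                raise ValueError(f"bbox width/height must be positive, got {self.bbox}")


@dataclass(frozen=True)
class RecommendedValue:
    """Consensus joints + box for one image, with inspection status."""

    image_id: str
    joints: Mapping[str, tuple[float, float]]
    bbox: Optional[tuple[float, float, float, float]]
    contributing_annotators: tuple[str, ...]
    status: str = "pending"  # pending | confirmed | dropped

    def __post_init__(self) -> None:
        if self.status not in ("pending", "confirmed", "dropped"):
            raise ValueError(f"invalid status {self.status!r}")


def _lower_median(values: Sequence[float]) -> float:
    """Order-statistic median: element ceil(n/2) of the sorted values.

    For odd n this is the ordinary middle value; for even n the lower of
    the two middle values, so the output is always an observed coordinate.
    """
    s = sorted(values)
    k = (len(s) + 1) // 2
    return s[k - 1]


def aggregate_joints(
    annotations: Sequence[Annotation],
    config: AggregationConfig = AggregationConfig(),
) -> RecommendedValue:
    """Fuse multiple annotators' tags into one recommended value.

    Per joint, the componentwise median (or mean, per config) over the
    annotators who tagged it with a non-absent visibility.  Raises on an
    empty annotation list.
    """
    if not annotations:
        raise ValueError("aggregate_joints requires at least one annotation")
    image_ids = {a.image_id for a in annotations}
    if len(image_ids) > 1:
        raise ValueError(f"annotations mix image ids: {sorted(image_ids)}")

    stat = _lower_median if config.statistic == "median" else statistics.fmean
    if config.statistic not in ("median", "mean"):
        raise ValueError(f"unknown aggregation statistic {config.statistic!r}")

    joint_names: list[str] = []
    for a in annotations:
        for name in a.joints:
            if name not in joint_names:
                joint_names.append(name)

    fused: dict[str, tuple[float, float]] = {}
    contributors: list[str] = []
    for name in joint_names:
        xs, ys = [], []
        for a in annotations:
            kp = a.joints.get(name)
            if kp is None or kp.is_absent or kp.x is None or kp.y is None:
                continue
            xs.append(float(kp.x))
            ys.append(float(kp.y))
            if a.annotator_id not in contributors:
                contributors.append(a.annotator_id)
        if xs:
            fused[name] = (stat(xs), stat(ys))

    bbox = _recommended_bbox(annotations, fused, config)
    return RecommendedValue(
        image_id=annotations[0].image_id,
        joints=fused,
        bbox=bbox,
        contributing_annotators=tuple(contributors),
        status="pending",
    )


def _recommended_bbox(
    annotations: Sequence[Annotation],
    fused: Mapping[str, tuple[float, float]],
    config: AggregationConfig,
) -> Optional[tuple[float, float, float, float]]:
    if config.bbox_mode == "boxes":
        boxes = [a.bbox for a in annotations if a.bbox is not None]
        if not boxes:
            return None
        return tuple(_lower_median([b[i] for b in boxes]) for i in range(4))  # type: ignore[return-value]
    if config.bbox_mode != "joints":
        raise ValueError(f"unknown bbox_mode {config.bbox_mode!r}")
    if not fused:
        return None
    xs = [p[0] for p in fused.values()]
    ys = [p[1] for p in fused.values()]
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    mx = config.bbox_margin * (x1 - x0)
    my = config.bbox_margin * (y1 - y0)
    return (x0 - mx, y0 - my, (x1 - x0) + 2 * mx, (y1 - y0) + 2 * my)


def filter_annotators(
    annotations: Sequence[Annotation], allowed_ids: Iterable[str]
) -> list[Annotation]:
    """Keep only the tags of the trusted annotators, order-stable."""
    allowed = set(allowed_ids)
    return [a for a in annotations if a.annotator_id in allowed]


def confirm_or_drop(
    rv: RecommendedValue,
    decision: str,
    moves: Optional[Mapping[str, tuple[float, float]]] = None,
) -> RecommendedValue:
    """Inspector decision on a pending recommended value.

    ``decision`` is "confirm" or "drop".  ``moves`` maps joint name to an
    (dx, dy) offset applied before confirming — the drag-to-correct
    interaction.  Confirmed and dropped records are immutable; re-deciding
    one raises :class:`ImmutabilityError`.
    """
    if rv.status != "pending":
        raise ImmutabilityError(
            f"record for image {rv.image_id!r} already {rv.status}; cannot modify"
        )
    if decision not in ("confirm", "drop"):
        raise ValueError(f"decision must be 'confirm' or 'drop', got {decision!r}")
    if decision == "drop":
        if moves:
            raise ValueError("cannot apply joint moves to a dropped record")
        return replace(rv, status="dropped")
    joints = dict(rv.joints)
    for name, (dx, dy) in (moves or {}).items():
        if name not in joints:
            raise KeyError(f"cannot move unknown joint {name!r}")
        x, y = joints[name]
        joints[name] = (x + dx, y + dy)
    return replace(rv, joints=joints, status="confirmed")


def export_confirmed(records: Sequence[RecommendedValue]) -> list[RecommendedValue]:
    """The dataset export: exactly the confirmed records, input order."""
    return [r for r in records if r.status == "confirmed"]
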