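"""Whole-body measurement: named angles and lengths from a pose frame.

This is the bridge between raw keypoints and posture coding: one pass over
a frame produces every angle and length the scorer consumes.  Angles from
the three-point primitive are unsigned; flexion/extension direction is
recovered from the sign of the segment's sagittal (forward) component, with
the body's forward axis built from the hip line and the trunk axis.

Conventions (shared with the synthetic generator):

* world up is ``(0, -1, 0)`` — camera-centered coordinates have y down;
* the subject's left axis points from the right hip to the left hip;
* forward = left x up (a right-handed sagittal direction);
* wrist flexion/deviation are read in a forearm frame whose lateral axis
  is the elbow hinge axis (forearm x upper-arm); the twist angle comes from
  the palm plane via :func:`ergokit.geometry.wrist_twist_angle`.

Positive flexion = forward bend; negative = extension.  Wrist flexion and
deviation are signed but only their magnitudes enter the posture codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import geometry
from .skeleton import PoseFrame

__all__ = [
    "SideMeasurements",
    "Measurements",
    "body_frame",
    "forearm_frame",
    "measure_frame",
    "WORLD_UP",
]

#: world up direction in camera-centered image coordinates (y points down)
WORLD_UP = np.array([0.0, -1.0, 0.0])


def _unit(v: np.ndarray, label: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n <= geometry.EPS_MM:
        raise geometry.GeometryError(f"cannot normalize zero-length vector for {label}")
    return v / n


def body_frame(frame: PoseFrame):
    """Orthogonal body reference directions ``(trunk_up, left, forward)``.

    ``trunk_up`` runs pelvis→thorax, ``left`` runs right hip→left hip, and
    ``forward`` = left x trunk_up points out of the subject's frontal
    plane.  Returns ``None`` if any required joint is missing.
    """
    pelvis = frame.point("pelvis")
    thorax = frame.point("thorax")
    lhip = frame.point("left_hip")
    rhip = frame.point("right_hip")
    if pelvis is None or thorax is None or lhip is None or rhip is None:
        return None
    trunk_up = _unit(thorax - pelvis, "trunk axis")
    left = _unit(lhip - rhip, "hip line")
    forward = _unit(np.cross(left, trunk_up), "forward axis")
    return trunk_up, left, forward


def forearm_frame(shoulder: np.ndarray, elbow: np.ndarray, wrist: np.ndarray):
    """Orthonormal forearm frame ``(f_hat, lat, n0)`` at the wrist.

    ``f_hat`` is the forearm axis elbow→wrist, ``lat`` the elbow hinge axis
    (f_hat x upper-arm direction), and ``n0`` = lat x f_hat the neutral palm
    normal.  Undefined (raises) when the elbow is fully extended, since the
    hinge axis then has no unique direction.
    """
    f_hat = _unit(wrist - elbow, "forearm axis")
    u_hat = _unit(shoulder - elbow, "upper-arm axis")
    lat = np.cross(f_hat, u_hat)
    n = float(np.linalg.norm(lat))
    if n <= 1e-9:
        raise geometry.GeometryError("elbow fully extended: forearm frame undefined")
    lat = lat / n
    n0 = np.cross(lat, f_hat)
    return f_hat, lat, n0


@dataclass(frozen=True)
class SideMeasurements:
    """Per-side angles (degrees) and leg segment lengths (mm).

    Any field may be ``None`` when the joints it needs are absent.
    """

    upper_arm_flexion: Optional[float] = None
    elbow_flexion: Optional[float] = None
    wrist_flexion: Optional[float] = None
    wrist_deviation: Optional[float] = None
    wrist_twist: Optional[float] = None
    thigh_length: Optional[float] = None
    shank_length: Optional[float] = None
    ankle_y: Optional[float] = None
    leg_confidence: Optional[float] = None


@dataclass(frozen=True)
class Measurements:
    """All named measurements of one frame."""

    trunk_flexion: Optional[float] = None
    neck_flexion: Optional[float] = None
    left: SideMeasurements = field(default_factory=SideMeasurements)
    right: SideMeasurements = field(default_factory=SideMeasurements)

    def side(self, which: str) -> SideMeasurements:
        if which == "left":
            return self.left
        if which == "right":
            return self.right
        raise ValueError(f"side must be 'left' or 'right', got {which!r}")

    def as_flat_dict(self) -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {
            "trunk_flexion": self.trunk_flexion,
            "neck_flexion": self.neck_flexion,
        }
        for side in ("left", "right"):
            sm = self.side(side)
            for name in (
                "upper_arm_flexion",
                "elbow_flexion",
                "wrist_flexion",
                "wrist_deviation",
                "wrist_twist",
                "thigh_length",
                "shank_length",
            ):
                out[f"{side}_{name}"] = getattr(sm, name)
        return out


def _signed_angle(v: np.ndarray, ref: np.ndarray, sign_axis: np.ndarray) -> float:
    """Unsigned angle(v, ref) with the sign of v's component along sign_axis."""
    cos_t = float(np.dot(v, ref)) / (np.linalg.norm(v) * np.linalg.norm(ref))
    ang = float(np.degrees(np.arccos(max(-1.0, min(1.0, cos_t)))))
    return ang if float(np.dot(v, sign_axis)) >= 0 else -ang


def _measure_side(frame: PoseFrame, side: str, trunk_up, forward) -> SideMeasurements:
    shoulder = frame.point(f"{side}_shoulder")
    elbow = frame.point(f"{side}_elbow")
    wrist = frame.point(f"{side}_wrist")
    hand = frame.point(f"{side}_hand")
    thumb = frame.point(f"{side}_thumb")
    hip = frame.point(f"{side}_hip")
    knee = frame.point(f"{side}_knee")
    ankle = frame.point(f"{side}_ankle")

    upper_arm = None
    if shoulder is not None and elbow is not None and trunk_up is not None:
        upper_arm = _signed_angle(elbow - shoulder, -trunk_up, forward)

    elbow_flex = None
    if shoulder is not None and elbow is not None and wrist is not None:
        try:
            elbow_flex = 180.0 - geometry.joint_angle(shoulder, elbow, wrist)
        except geometry.GeometryError:
            elbow_flex = None

    wrist_flex = wrist_dev = wrist_tw = None
    if shoulder is not None and elbow is not None and wrist is not None and hand is not None:
        try:
            f_hat, lat, n0 = forearm_frame(shoulder, elbow, wrist)
            h = _unit(hand - wrist, "hand direction")
            wrist_flex = float(np.degrees(np.arctan2(np.dot(h, n0), np.dot(h, f_hat))))
            wrist_dev = float(np.degrees(np.arcsin(max(-1.0, min(1.0, float(np.dot(h, lat)))))))
            if thumb is not None:
                wrist_tw = geometry.wrist_twist_angle(wrist, thumb, hand, elbow)
        except geometry.GeometryError:
            pass

    thigh = shank = ankle_y = None
    conf = None
    if hip is not None and knee is not None:
        thigh = geometry.segment_length(hip, knee)
    if knee is not None and ankle is not None:
        shank = geometry.segment_length(knee, ankle)
    if ankle is not None:
        ankle_y = float(ankle[1])
    leg_kps = [frame.keypoints.get(f"{side}_{j}") for j in ("hip", "knee", "ankle")]
    present = [kp for kp in leg_kps if kp is not None and not kp.is_absent]
    if len(present) == 3:
        conf = min(kp.confidence for kp in present)

    return SideMeasurements(
        upper_arm_flexion=upper_arm,
        elbow_flexion=elbow_flex,
        wrist_flexion=wrist_flex,
        wrist_deviation=wrist_dev,
        wrist_twist=wrist_tw,
        thigh_length=thigh,
        shank_length=shank,
        ankle_y=ankle_y,
        leg_confidence=conf,
    )


def measure_frame(frame: PoseFrame) -> Measurements:
    """Compute every named measurement available in ``frame``.

    Missing joints degrade gracefully: the affected fields come back
    ``None`` and the posture coder marks the corresponding parts uncodable.
    """
    bf = body_frame(frame)
    trunk_up = left = forward = None
    trunk_flexion = neck_flexion = None
    if bf is not None:
        trunk_up, left, forward = bf
        # horizontal forward from the hip line and gravity, so trunk lean
        # is measured against the world vertical
        fwd_h = np.cross(left, WORLD_UP)
        n = float(np.linalg.norm(fwd_h))
        fwd_h = fwd_h / n if n > geometry.EPS_MM else forward
        trunk_flexion = _signed_angle(trunk_up, WORLD_UP, fwd_h)
        nose = frame.point("nose")
        thorax = frame.point("thorax")
        if nose is not None and thorax is not None:
            neck_flexion = _signed_angle(nose - thorax, trunk_up, forward)

    return Measurements(
        trunk_flexion=trunk_flexion,
        neck_flexion=neck_flexion,
        left=_measure_side(frame, "left", trunk_up, forward),
        right=_measure_side(frame, "right", trunk_up, forward),
    )
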