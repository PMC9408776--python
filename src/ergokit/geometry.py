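"""Angle and distance measurement over joints.

The core primitive is the three-point joint angle: for points A, B, C the
angle at the vertex B is

    theta = arccos( (BA . BC) / (|BA| |BC|) )

reported in degrees, with the cosine argument clamped to [-1, 1] so that
round-off near collinear configurations cannot raise a domain error.
Distances are plain Euclidean lengths in mm.  The wrist-twist measurement
uses the plane through the wrist, thumb and hand keypoints: the reported
twist is the angle between that plane's normal and the forearm axis
(elbow→wrist), folded into [0, 90] degrees.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .skeleton import DimensionalityError, Keypoint, PoseFrame, Visibility

__all__ = [
    "GeometryError",
    "UndefinedAngleError",
    "UndefinedLengthError",
    "UndefinedPlaneError",
    "joint_angle",
    "segment_length",
    "wrist_twist_angle",
    "project_side_view",
    "EPS_MM",
]

#: arm vectors shorter than this (mm) make a joint angle undefined
EPS_MM = 1e-6


class GeometryError(ValueError):
    """Base class for undefined geometric measurements."""


class UndefinedAngleError(GeometryError):
    pass


class UndefinedLengthError(GeometryError):
    pass


class UndefinedPlaneError(GeometryError):
    pass


def _as_point(p, label: str) -> np.ndarray:
    if p is None:
        raise GeometryError(f"point {label!r} is absent")
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise GeometryError(f"point {label!r} must be 3D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"point {label!r} has non-finite coordinates")
    return arr


def joint_angle(A, B, C) -> float:
    """Angle in degrees at vertex ``B`` between arms B→A and B→C.

    Raises :class:`UndefinedAngleError` naming the degenerate segment when
    either arm vector is shorter than :data:`EPS_MM`.
    """
    a = _as_point(A, "A")
    b = _as_point(B, "B")
    c = _as_point(C, "C")
    ba = a - b
    bc = c - b
    nba = float(np.linalg.norm(ba))
    nbc = float(np.linalg.norm(bc))
    if nba <= EPS_MM:
        raise UndefinedAngleError("degenerate arm vector B-A (zero length)")
    if nbc <= EPS_MM:
        raise UndefinedAngleError("degenerate arm vector B-C (zero length)")
    cos_theta = float(np.dot(ba, bc)) / (nba * nbc)
    cos_theta = max(-1.0, min(1.0, cos_theta))
    return float(np.degrees(np.arccos(cos_theta)))


def segment_length(P, Q) -> float:
    """Euclidean distance in mm between two 3D points."""
    p = _as_point(P, "P")
    q = _as_point(Q, "Q")
    return float(np.linalg.norm(p - q))


def _plane_normal(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    n = np.cross(p1 - p0, p2 - p0)
    norm = float(np.linalg.norm(n))
    if norm <= EPS_MM:
        raise UndefinedPlaneError("plane points are collinear or coincident")
    return n / norm


def wrist_twist_angle(wrist, thumb, hand, elbow) -> float:
    """Forearm-rotation angle from the palm plane, in degrees within [0, 90].

    The palm plane is spanned by the wrist, thumb and hand keypoints.  The
    returned value is the angle between that plane's normal and the forearm
    axis (elbow→wrist), folded into [0, 90]: a normal parallel to the
    forearm axis gives 0, an orthogonal normal (forearm lying in the palm
    plane, the neutral straight-hand configuration) gives 90.
    """
    w = _as_point(wrist, "wrist")
    t = _as_point(thumb, "thumb")
    h = _as_point(hand, "hand")
    e = _as_point(elbow, "elbow")
    n = _plane_normal(w, t, h)
    f = w - e
    nf = float(np.linalg.norm(f))
    if nf <= EPS_MM:
        raise UndefinedAngleError("degenerate forearm axis elbow-wrist")
    cos_a = abs(float(np.dot(n, f)) / nf)
    cos_a = min(1.0, cos_a)
    # |cos| folds [0,180] onto [0,90]
    return float(np.degrees(np.arccos(cos_a)))


def project_side_view(frame: PoseFrame, side: str) -> PoseFrame:
    """Orthographic side-view projection of a 3D frame onto 2D.

    The right view maps (x, y, z) → (z, y); the left view mirrors the
    projected horizontal axis, (x, y, z) → (−z, y).  The result is a 2D
    frame (z absent on every keypoint).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    sign = 1.0 if side == "right" else -1.0
    projected: dict[str, Keypoint] = {}
    for name, kp in frame.keypoints.items():
        if kp.is_absent:
            projected[name] = kp
            continue
        if kp.z is None:
            raise DimensionalityError(
                f"keypoint {name!r} has no z coordinate; side view needs 3D input"
            )
        projected[name] = Keypoint(
            x=sign * kp.z,
            y=kp.y,
            z=None,
            visibility=kp.visibility,
            confidence=kp.confidence,
        )
    return PoseFrame(
        skeleton=frame.skeleton,
        keypoints=projected,
        timestamp=frame.timestamp,
        subject_id=frame.subject_id,
    )
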