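"""RULA posture scoring: codes, tables A/B/C, grand score, action level.

The Rapid Upper Limb Assessment worksheet (McAtamney & Corlett) codes the
upper arm (1-6), lower arm (1-3), wrist (1-4, twist 1-2), neck (1-6),
trunk (1-6) and legs (1-2) from joint angles and adjustment flags, combines
the arm/wrist group through Table A and the neck/trunk/legs group through
Table B, adds muscle-use and force/load points, and maps the pair through
Table C to a grand score (1-7) and one of four action levels.

Angle bins use half-open intervals [lo, hi); all bin edges and tolerances
sit in :class:`ergokit.config.RulaConfig`.  When part of the lower body is
occluded or its estimated joints are anatomically implausible, the scorer
falls back to an upper-body-only result, assuming the legs and feet are
supported (legs code 1) and flagging the frame accordingly.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .config import RulaConfig
from .measure import Measurements, SideMeasurements, measure_frame
from .skeleton import PoseFrame, PoseSequence

__all__ = [
    "AdjustmentFlags",
    "ManualInputs",
    "BodyPartScores",
    "SideResult",
    "RulaResult",
    "RulaRangeError",
    "classify_body_parts",
    "table_a_lookup",
    "table_b_lookup",
    "table_c_lookup",
    "action_level",
    "score_tables",
    "leg_occlusion_fallback",
    "assess_frame",
    "assess_sequence",
    "PART_RANGES",
]


class RulaRangeError(ValueError):
    """A posture code or table input is outside its valid range."""


#: inclusive (lo, hi) code range per body part
PART_RANGES: dict[str, tuple[int, int]] = {
    "upper_arm": (1, 6),
    "lower_arm": (1, 3),
    "wrist": (1, 4),
    "wrist_twist": (1, 2),
    "neck": (1, 6),
    "trunk": (1, 6),
    "legs": (1, 2),
}

#: number of distinct action levels exposed by the scorer
N_ACTION_LEVELS = 4

# ---------------------------------------------------------------------------
# Published RULA lookup tables.
# TABLE_A[upper_arm-1][lower_arm-1][wrist-1][wrist_twist-1]
_TABLE_A = np.array(
    [
        [  # upper arm 1
            [[1, 2], [2, 2], [2, 3], [3, 3]],
            [[2, 2], [2, 2], [3, 3], [3, 3]],
            [[2, 3], [3, 3], [3, 3], [4, 4]],
        ],
        [  # upper arm 2
            [[2, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 3], [3, 3], [3, 4], [4, 4]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
        ],
        [  # upper arm 3
            [[3, 3], [4, 4], [4, 4], [5, 5]],
            [[3, 4], [4, 4], [4, 4], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
        ],
        [  # upper arm 4
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 4], [4, 5], [5, 5]],
            [[4, 4], [4, 5], [5, 5], [6, 6]],
        ],
        [  # upper arm 5
            [[5, 5], [5, 5], [5, 6], [6, 7]],
            [[5, 6], [6, 6], [6, 7], [7, 7]],
            [[6, 6], [6, 7], [7, 7], [7, 8]],
        ],
        [  # upper arm 6
            [[7, 7], [7, 7], [7, 8], [8, 9]],
            [[8, 8], [8, 8], [8, 9], [9, 9]],
            [[9, 9], [9, 9], [9, 9], [9, 9]],
        ],
    ],
    dtype=int,
)

# _TABLE_B[neck-1][trunk-1][legs-1]
_TABLE_B = np.array(
    [
        [[1, 3], [2, 3], [3, 4], [5, 5], [6, 6], [7, 7]],
        [[2, 3], [2, 3], [4, 5], [5, 5], [6, 7], [7, 7]],
        [[3, 3], [3, 4], [4, 5], [5, 6], [6, 7], [7, 7]],
        [[5, 5], [5, 6], [6, 7], [7, 7], [7, 7], [8, 8]],
        [[7, 7], [7, 7], [7, 8], [8, 8], [8, 8], [8, 8]],
        [[8, 8], [8, 8], [8, 8], [8, 9], [9, 9], [9, 9]],
    ],
    dtype=int,
)

# _TABLE_C[score_c-1][score_d-1]; inputs above 8 / 7 are capped
_TABLE_C = np.array(
    [
        [1, 2, 3, 3, 4, 5, 5],
        [2, 2, 3, 4, 4, 5, 5],
        [3, 3, 3, 4, 4, 5, 6],
        [3, 3, 3, 4, 5, 6, 6],
        [4, 4, 4, 5, 6, 7, 7],
        [4, 4, 5, 6, 6, 7, 7],
        [5, 5, 6, 6, 7, 7, 7],
        [5, 5, 6, 7, 7, 7, 7],
    ],
    dtype=int,
)


# ---------------------------------------------------------------------------
# Data types


@dataclass(frozen=True)
class AdjustmentFlags:
    """Worksheet adjustment items that cannot be read from keypoints alone."""

    shoulder_raised: bool = False
    arm_abducted: bool = False
    arm_supported: bool = False  # arm supported / person leaning: -1
    arm_across_midline: bool = False  # working across midline or out to side: +1
    wrist_deviated: bool = False  # forced deviation flag (also auto-derived)
    neck_twisted: bool = False
    neck_side_bent: bool = False
    trunk_twisted: bool = False
    trunk_side_bent: bool = False
    trunk_supported_upright: bool = False


@dataclass(frozen=True)
class ManualInputs:
    """Manually entered load/repetition items (not observable from pose)."""

    muscle_use_a: int = 0
    muscle_use_b: int = 0
    force_load_a: int = 0
    force_load_b: int = 0

    def __post_init__(self) -> None:
        for name in ("muscle_use_a", "muscle_use_b"):
            if getattr(self, name) not in (0, 1):
                raise RulaRangeError(f"{name} must be 0 or 1")
        for name in ("force_load_a", "force_load_b"):
            if not 0 <= getattr(self, name) <= 3:
                raise RulaRangeError(f"{name} must be in 0..3")


@dataclass(frozen=True)
class BodyPartScores:
    """Per-part posture codes for one body side.

    ``None`` marks a part that could not be coded from the available
    joints (no applicable fallback).
    """

    upper_arm: Optional[int] = None
    lower_arm: Optional[int] = None
    wrist: Optional[int] = None
    wrist_twist: Optional[int] = None
    neck: Optional[int] = None
    trunk: Optional[int] = None
    legs: Optional[int] = None
    side: str = "right"

    def __post_init__(self) -> None:
        for part, (lo, hi) in PART_RANGES.items():
            v = getattr(self, part)
            if v is not None and not lo <= v <= hi:
                raise RulaRangeError(f"{part} code {v} outside {lo}..{hi}")

    def uncodable_parts(self) -> list[str]:
        return [p for p in PART_RANGES if getattr(self, p) is None]

    def is_complete(self) -> bool:
        return not self.uncodable_parts()


@dataclass(frozen=True)
class SideResult:
    scores: BodyPartScores
    table_a: int
    table_b: int
    score_c: int
    score_d: int
    grand_score: int
    action_level: int


@dataclass(frozen=True)
class RulaResult:
    """Full per-frame assessment: both sides plus the headline (worse) side."""

    timestamp: float
    left: Optional[SideResult]
    right: Optional[SideResult]
    headline_side: Optional[str]
    upper_body_only: bool = False
    unassessable_reason: Optional[str] = None
    measurements: Optional[Measurements] = None

    @property
    def headline(self) -> Optional[SideResult]:
        if self.headline_side == "left":
            return self.left
        if self.headline_side == "right":
            return self.right
        return None

    @property
    def grand_score(self) -> Optional[int]:
        h = self.headline
        return h.grand_score if h else None

    @property
    def action_level(self) -> Optional[int]:
        h = self.headline
        return h.action_level if h else None


# ---------------------------------------------------------------------------
# Table lookups


def _check_code(part: str, value: int) -> int:
    lo, hi = PART_RANGES[part]
    if not isinstance(value, (int, np.integer)) or not lo <= value <= hi:
        raise RulaRangeError(f"{part} code {value!r} outside {lo}..{hi}")
    return int(value)


def table_a_lookup(upper_arm: int, lower_arm: int, wrist: int, wrist_twist: int) -> int:
    """Arm & wrist group score from RULA Table A."""
    ua = _check_code("upper_arm", upper_arm)
    la = _check_code("lower_arm", lower_arm)
    w = _check_code("wrist", wrist)
    wt = _check_code("wrist_twist", wrist_twist)
    return int(_TABLE_A[ua - 1, la - 1, w - 1, wt - 1])


def table_b_lookup(neck: int, trunk: int, legs: int) -> int:
    """Neck, trunk & legs group score from RULA Table B."""
    n = _check_code("neck", neck)
    t = _check_code("trunk", trunk)
    l = _check_code("legs", legs)
    return int(_TABLE_B[n - 1, t - 1, l - 1])


def table_c_lookup(score_c: int, score_d: int) -> int:
    """Grand score from RULA Table C.

    Inputs are the adjusted group scores (table score + muscle use +
    force/load).  Values above the table's last row/column (8 and 7) are
    capped per the worksheet's "8+" rule.
    """
    if not isinstance(score_c, (int, np.integer)) or score_c < 1:
        raise RulaRangeError(f"score_c {score_c!r} must be a positive integer")
    if not isinstance(score_d, (int, np.integer)) or score_d < 1:
        raise RulaRangeError(f"score_d {score_d!r} must be a positive integer")
    r = min(int(score_c), 8)
    c = min(int(score_d), 7)
    return int(_TABLE_C[r - 1, c - 1])


def action_level(grand_score: int) -> int:
    """Action level 1-4 from the grand score 1-7."""
    if not isinstance(grand_score, (int, np.integer)) or not 1 <= grand_score <= 7:
        raise RulaRangeError(f"grand score {grand_score!r} outside 1..7")
    g = int(grand_score)
    if g <= 2:
        return 1
    if g <= 4:
        return 2
    if g <= 6:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Posture coding


def _clamp(v: int, part: str) -> int:
    lo, hi = PART_RANGES[part]
    return max(lo, min(hi, v))


def classify_body_parts(
    measurements: Measurements,
    side: str,
    flags: AdjustmentFlags = AdjustmentFlags(),
    config: RulaConfig = RulaConfig(),
    legs_code: Optional[int] = None,
) -> BodyPartScores:
    """Map one side's measured angles + adjustment flags to posture codes.

    A part whose required angles are missing (``None``) is marked uncodable
    (``None`` code) rather than raising.  ``legs_code`` is normally supplied
    by :func:`leg_occlusion_fallback`.
    """
    sm = measurements.side(side)

    upper_arm = None
    if sm.upper_arm_flexion is not None:
        f = sm.upper_arm_flexion
        if -20.0 <= f < 20.0:
            c = 1
        elif 20.0 <= f < 45.0 or f < -20.0:
            c = 2
        elif 45.0 <= f < 90.0:
            c = 3
        else:
            c = 4
        if flags.shoulder_raised:
            c += 1
        if flags.arm_abducted:
            c += 1
        if flags.arm_supported:
            c -= 1
        upper_arm = _clamp(c, "upper_arm")

    lower_arm = None
    if sm.elbow_flexion is not None:
        c = 1 if 60.0 <= sm.elbow_flexion < 100.0 else 2
        if flags.arm_across_midline:
            c += 1
        lower_arm = _clamp(c, "lower_arm")

    wrist = None
    if sm.wrist_flexion is not None:
        mag = abs(sm.wrist_flexion)
        if mag <= config.wrist_neutral_tol:
            c = 1
        elif mag <= 15.0:
            c = 2
        else:
            c = 3
        deviated = flags.wrist_deviated or (
            sm.wrist_deviation is not None
            and abs(sm.wrist_deviation) > config.wrist_deviation_threshold
        )
        if deviated:
            c += 1
        wrist = _clamp(c, "wrist")

    wrist_twist = None
    if sm.wrist_twist is not None:
        wrist_twist = 1 if sm.wrist_twist >= config.wrist_twist_end_range else 2

    neck = None
    if measurements.neck_flexion is not None:
        f = measurements.neck_flexion
        if f < -config.neck_extension_tol:
            c = 4
        elif f < 10.0:
            c = 1
        elif f < 20.0:
            c = 2
        else:
            c = 3
        if flags.neck_twisted:
            c += 1
        if flags.neck_side_bent:
            c += 1
        neck = _clamp(c, "neck")

    trunk = None
    if measurements.trunk_flexion is not None:
        f = measurements.trunk_flexion
        if flags.trunk_supported_upright or abs(f) <= config.trunk_upright_tol:
            c = 1
        elif f < 20.0:  # includes extension beyond the upright tolerance
            c = 2
        elif f < 60.0:
            c = 3
        else:
            c = 4
        if flags.trunk_twisted:
            c += 1
        if flags.trunk_side_bent:
            c += 1
        trunk = _clamp(c, "trunk")

    return BodyPartScores(
        upper_arm=upper_arm,
        lower_arm=lower_arm,
        wrist=wrist,
        wrist_twist=wrist_twist,
        neck=neck,
        trunk=trunk,
        legs=legs_code,
        side=side,
    )


# ---------------------------------------------------------------------------
# Occlusion fallback


def leg_occlusion_fallback(
    frame: PoseFrame,
    sequence_context: Optional[PoseSequence] = None,
    config: RulaConfig = RulaConfig(),
) -> tuple[int, bool]:
    """Legs code with the upper-body-only fallback.

    When leg joints are absent, low-confidence, or a thigh/shank length
    deviates from the sequence median by more than the configured ratio,
    the lower body is treated as unreliable: the legs are assumed supported
    (code 1) and the frame is flagged upper-body-only.  Otherwise the legs
    are coded normally: 1 when both feet are on comparable support
    (ankle heights within tolerance), 2 otherwise.
    """
    m = measure_frame(frame)

    for side in ("left", "right"):
        sm = m.side(side)
        if sm.thigh_length is None or sm.shank_length is None or sm.ankle_y is None:
            return 1, True
        if sm.leg_confidence is not None and sm.leg_confidence < config.leg_confidence_threshold:
            return 1, True

    if sequence_context is not None and len(sequence_context) >= 3:
        ratio = config.leg_length_ratio
        context_ms = [measure_frame(f) for f in sequence_context]
        for attr in ("thigh_length", "shank_length"):
            for side in ("left", "right"):
                lengths = [
                    v
                    for cm in context_ms
                    if (v := getattr(cm.side(side), attr)) is not None
                ]
                if len(lengths) < 3:
                    continue
                med = statistics.median(lengths)
                cur = getattr(m.side(side), attr)
                if med > 0 and not (med / ratio <= cur <= med * ratio):
                    return 1, True

    gap = abs(m.left.ankle_y - m.right.ankle_y)
    legs = 1 if gap <= config.ankle_height_tol_mm else 2
    return legs, False


# ---------------------------------------------------------------------------
# Full pipeline


def score_tables(scores: BodyPartScores, manual: ManualInputs = ManualInputs()) -> SideResult:
    """Tables A/B/C composition for a complete set of posture codes."""
    missing = scores.uncodable_parts()
    if missing:
        raise RulaRangeError(f"cannot score: uncodable parts {missing}")
    a = table_a_lookup(scores.upper_arm, scores.lower_arm, scores.wrist, scores.wrist_twist)
    b = table_b_lookup(scores.neck, scores.trunk, scores.legs)
    score_c = a + manual.muscle_use_a + manual.force_load_a
    score_d = b + manual.muscle_use_b + manual.force_load_b
    grand = table_c_lookup(score_c, score_d)
    return SideResult(
        scores=scores,
        table_a=a,
        table_b=b,
        score_c=score_c,
        score_d=score_d,
        grand_score=grand,
        action_level=action_level(grand),
    )


#: parts that must be codable for a frame to be assessable at all
_MANDATORY_PARTS = ("upper_arm", "lower_arm", "wrist", "wrist_twist", "neck", "trunk")


def assess_frame(
    frame: PoseFrame,
    manual: ManualInputs = ManualInputs(),
    flags: AdjustmentFlags = AdjustmentFlags(),
    config: RulaConfig = RulaConfig(),
    sequence_context: Optional[PoseSequence] = None,
) -> RulaResult:
    """Assess one frame: geometry → posture codes → tables → action level.

    Both sides are scored; the headline is the worse (max grand score)
    side, a conservative policy.  A frame whose mandatory upper-limb parts
    cannot be coded on either side is marked unassessable with a reason.
    """
    m = measure_frame(frame)
    legs_code, upper_only = leg_occlusion_fallback(frame, sequence_context, config)

    side_results: dict[str, Optional[SideResult]] = {}
    reasons: list[str] = []
    for side in ("left", "right"):
        scores = classify_body_parts(m, side, flags=flags, config=config, legs_code=legs_code)
        missing = [p for p in _MANDATORY_PARTS if getattr(scores, p) is None]
        if missing:
            side_results[side] = None
            reasons.append(f"{side}: uncodable {', '.join(missing)}")
        else:
            side_results[side] = score_tables(scores, manual)

    candidates = {s: r for s, r in side_results.items() if r is not None}
    if not candidates:
        return RulaResult(
            timestamp=frame.timestamp,
            left=None,
            right=None,
            headline_side=None,
            upper_body_only=upper_only,
            unassessable_reason="; ".join(reasons) or "no codable side",
            measurements=m,
        )
    headline_side = max(candidates, key=lambda s: (candidates[s].grand_score, s))
    return RulaResult(
        timestamp=frame.timestamp,
        left=side_results["left"],
        right=side_results["right"],
        headline_side=headline_side,
        upper_body_only=upper_only,
        unassessable_reason=None,
        measurements=m,
    )


def assess_sequence(
    seq: PoseSequence,
    manual: ManualInputs = ManualInputs(),
    flags: AdjustmentFlags = AdjustmentFlags(),
    config: RulaConfig = RulaConfig(),
    sample_fps: Optional[float] = None,
) -> list[RulaResult]:
    """Assess a sequence after subsampling it to ``sample_fps`` (default 1).

    The stride is ``round(seq.fps / sample_fps)`` frames, at least 1, so a
    10 s clip at 30 fps assessed at 1 fps yields 10 results.
    """
    fps_target = config.sample_fps if sample_fps is None else sample_fps
    if fps_target <= 0:
        raise ValueError("sample_fps must be positive")
    stride = max(1, round(seq.fps / fps_target))
    frames = seq.frames[::stride]
    return [
        assess_frame(f, manual=manual, flags=flags, config=config, sequence_context=seq)
        for f in frames
    ]
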