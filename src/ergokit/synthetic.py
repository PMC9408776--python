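"""Synthetic pose, annotator and rating generators with known ground truth.

The source images and expert labels behind this kind of system are rarely
shareable, so every other module is exercised against data generated here:
forward-kinematics skeletons in the 25-joint dialect whose measured angles
equal the recipe angles exactly, Gaussian "estimator error" perturbations,
multi-annotator tag sets with occasional gross mis-entries, and paired
categorical ratings with a controllable agreement level.

All generators draw from named substreams of one seed, so tests are
order-independent and bit-reproducible.

Generator conventions (shared with :mod:`ergokit.measure`): world up is
(0, -1, 0), the subject's left axis is +x and the subject faces the camera
(forward = -z).  The pelvis sits ~3 m from the camera with a small
seed-dependent rigid offset, which changes coordinates without changing
any angle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .aggregation import Annotation
from .config import ANATOMICAL_RANGES_DEG, DEFAULT_LIMB_LENGTHS_MM, SyntheticConfig
from .measure import WORLD_UP, forearm_frame
from .metrics import RatingPair
from .skeleton import Keypoint, PoseFrame, PoseSequence, Visibility

__all__ = [
    "PoseRecipe",
    "RecipeError",
    "substream",
    "generate_pose",
    "generate_sequence",
    "perturb_pose",
    "simulate_annotators",
    "simulate_ratings",
]


class RecipeError(ValueError):
    """A pose recipe is outside the declared anatomical ranges or infeasible."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named substream of a global seed; order-independent across call sites."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))])
    )


@dataclass(frozen=True)
class PoseRecipe:
    """Target angles (degrees) for one generated frame.

    Arm and wrist targets apply to both sides symmetrically.  The wrist
    twist target is expressed directly as the folded palm-normal angle the
    twist measurement reports, so the neutral straight hand is 90 and
    values below 90 require a bent wrist (the palm plane tilts away from
    the forearm only when the hand leaves the forearm axis).
    """

    upper_arm_flexion: float = 0.0
    elbow_flexion: float = 80.0
    wrist_flexion: float = 0.0
    wrist_deviation: float = 0.0
    wrist_twist: float = 90.0
    neck_flexion: float = 0.0
    trunk_flexion: float = 0.0
    leg_support: bool = True
    limb_lengths_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIMB_LENGTHS_MM)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in ANATOMICAL_RANGES_DEG.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise RecipeError(f"{name}={v} outside anatomical range [{lo}, {hi}]")
        for name, v in self.limb_lengths_mm.items():
            if v <= 0:
                raise RecipeError(f"limb length {name!r} must be positive, got {v}")
        # twist feasibility: the folded palm-normal angle cannot drop below
        # 90 - (total wrist bend)
        bend = np.degrees(
            np.arccos(
                np.cos(np.radians(self.wrist_flexion)) * np.cos(np.radians(self.wrist_deviation))
            )
        )
        if self.wrist_twist < 90.0 - bend - 1e-9:
            raise RecipeError(
                f"wrist_twist={self.wrist_twist} infeasible for wrist bend {bend:.3f} deg "
                f"(minimum {90.0 - bend:.3f})"
            )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _kp(p: np.ndarray) -> Keypoint:
    return Keypoint(x=float(p[0]), y=float(p[1]), z=float(p[2]), visibility=Visibility.VISIBLE)


def _wrist_chain(
    recipe: PoseRecipe,
    shoulder: np.ndarray,
    elbow: np.ndarray,
    wrist: np.ndarray,
    lengths: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Hand and thumb points realizing the recipe's wrist targets."""
    try:
        f_hat, lat, n0 = forearm_frame(shoulder, elbow, wrist)
    except Exception:
        # fully extended elbow: the hinge axis is undefined, so wrist targets
        # cannot be realized (nor measured); fall back to a straight hand
        # with an arbitrary lateral axis
        f_hat = _unit(wrist - elbow)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(float(np.dot(helper, f_hat))) > 0.9:
            helper = np.array([0.0, 0.0, 1.0])
        lat = _unit(np.cross(f_hat, helper))
        n0 = np.cross(lat, f_hat)
    fl = np.radians(recipe.wrist_flexion)
    dv = np.radians(recipe.wrist_deviation)
    h = np.cos(dv) * (np.cos(fl) * f_hat + np.sin(fl) * n0) + np.sin(dv) * lat

    cos_bend = float(np.dot(h, f_hat))
    sin_bend = float(np.sqrt(max(0.0, 1.0 - cos_bend**2)))
    cos_tau = np.cos(np.radians(recipe.wrist_twist))
    if sin_bend < 1e-9:
        # straight hand: every palm normal is orthogonal to the forearm axis
        n = n0
    else:
        a = _unit(f_hat - cos_bend * h)
        b = np.cross(h, a)
        cos_phi = min(1.0, max(-1.0, cos_tau / sin_bend))
        phi = np.arccos(cos_phi)
        n = np.cos(phi) * a + np.sin(phi) * b
    t_dir = np.cross(n, h)
    hand = wrist + lengths["hand"] * h
    thumb = wrist + lengths["thumb"] * _unit(0.5 * h + np.sqrt(3.0) / 2.0 * t_dir)
    return hand, thumb


def generate_pose(recipe: PoseRecipe, timestamp: float = 0.0, subject_id: str = "synthetic") -> PoseFrame:
    """Forward-kinematics frame in the 25-joint dialect.

    Measured back through :func:`ergokit.measure.measure_frame`, every
    recipe angle is recovered to well under 1e-6 degrees.  Deterministic
    given the recipe seed (the seed only shifts the whole skeleton
    rigidly).
    """
    L = dict(DEFAULT_LIMB_LENGTHS_MM)
    L.update(recipe.limb_lengths_mm)
    rng = substream(recipe.seed, "pose")
    up = WORLD_UP
    left = np.array([1.0, 0.0, 0.0])
    fwd_h = _unit(np.cross(left, up))  # horizontal forward
    down = -up

    pelvis = np.array([0.0, 0.0, 3000.0]) + rng.uniform(-50.0, 50.0, size=3)

    tr = np.radians(recipe.trunk_flexion)
    trunk_up = np.cos(tr) * up + np.sin(tr) * fwd_h
    thorax = pelvis + L["trunk"] * trunk_up
    fwd_t = _unit(np.cross(left, trunk_up))  # trunk-relative forward

    nk = np.radians(recipe.neck_flexion)
    nose = thorax + L["neck"] * (np.cos(nk) * trunk_up + np.sin(nk) * fwd_t)
    head_up = _unit(np.cos(nk) * trunk_up + np.sin(nk) * fwd_t)
    joints: dict[str, np.ndarray] = {
        "pelvis": pelvis,
        "thorax": thorax,
        "nose": nose,
        "left_eye": nose + 30.0 * left + 15.0 * head_up,
        "right_eye": nose - 30.0 * left + 15.0 * head_up,
        "left_ear": nose + 70.0 * left - 20.0 * fwd_t,
        "right_ear": nose - 70.0 * left - 20.0 * fwd_t,
        "left_hip": pelvis + 0.5 * L["hip_width"] * left,
        "right_hip": pelvis - 0.5 * L["hip_width"] * left,
        "left_shoulder": thorax + 0.5 * L["shoulder_width"] * left,
        "right_shoulder": thorax - 0.5 * L["shoulder_width"] * left,
    }

    ua = np.radians(recipe.upper_arm_flexion)
    el = np.radians(recipe.elbow_flexion)
    upper_dir = -np.cos(ua) * trunk_up + np.sin(ua) * fwd_t
    fore_dir = -np.cos(ua + el) * trunk_up + np.sin(ua + el) * fwd_t
    for side in ("left", "right"):
        shoulder = joints[f"{side}_shoulder"]
        elbow = shoulder + L["upper_arm"] * upper_dir
        wrist = elbow + L["forearm"] * fore_dir
        hand, thumb = _wrist_chain(recipe, shoulder, elbow, wrist, L)
        joints[f"{side}_elbow"] = elbow
        joints[f"{side}_wrist"] = wrist
        joints[f"{side}_hand"] = hand
        joints[f"{side}_thumb"] = thumb

    for side in ("left", "right"):
        hip = joints[f"{side}_hip"]
        knee = hip + L["thigh"] * down
        if recipe.leg_support or side == "right":
            ankle = knee + L["shank"] * down
        else:
            # left foot lifted: knee bent, shank swung backward
            ankle = knee + L["shank"] * (0.5 * down - np.sqrt(3.0) / 2.0 * fwd_h)
        foot = ankle + L["foot"] * fwd_h + 30.0 * down
        joints[f"{side}_knee"] = knee
        joints[f"{side}_ankle"] = ankle
        joints[f"{side}_foot"] = foot

    return PoseFrame(
        skeleton="dywhse25",
        keypoints={name: _kp(p) for name, p in joints.items()},
        timestamp=timestamp,
        subject_id=subject_id,
    )


def generate_sequence(
    recipes: Sequence[PoseRecipe], fps: float = 30.0, subject_id: str = "synthetic"
) -> PoseSequence:
    """A sequence from a list of recipes, timestamped at ``fps``."""
    frames = tuple(
        generate_pose(r, timestamp=i / fps, subject_id=subject_id) for i, r in enumerate(recipes)
    )
    return PoseSequence(frames=frames, fps=fps)


def perturb_pose(
    frame: PoseFrame,
    sigma_mm: float,
    occlude: Iterable[str] = (),
    seed: int = 0,
) -> PoseFrame:
    """Isotropic Gaussian jitter per joint; listed joints become absent.

    Emulates upstream estimator error for metric tests.  Deterministic
    given the seed; ``sigma_mm=0`` with no occlusions returns an identical
    frame.
    """
    if sigma_mm < 0:
        raise ValueError(f"sigma_mm must be >= 0, got {sigma_mm}")
    rng = substream(seed, "perturb")
    occluded = set(occlude)
    out: dict[str, Keypoint] = {}
    # iterate in sorted order so the noise draw per joint is stable
    for name in sorted(frame.keypoints):
        kp = frame.keypoints[name]
        if name in occluded:
            out[name] = Keypoint.absent()
            continue
        if kp.is_absent or sigma_mm == 0:
            out[name] = kp
            continue
        noise = rng.normal(0.0, sigma_mm, size=3)
        out[name] = Keypoint(
            x=kp.x + noise[0],
            y=kp.y + noise[1],
            z=None if kp.z is None else kp.z + noise[2],
            visibility=kp.visibility,
            confidence=kp.confidence,
        )
    return PoseFrame(
        skeleton=frame.skeleton,
        keypoints=out,
        timestamp=frame.timestamp,
        subject_id=frame.subject_id,
    )


def simulate_annotators(
    frame: PoseFrame,
    n_annotators: int,
    noise_px: float = 2.0,
    gross_error_rate: float = 0.0,
    seed: int = 0,
    image_id: str = "img0",
) -> list[Annotation]:
    """Emulate several annotators tagging the front-view projection.

    Each annotator sees the frame's (x, y) pixel projection plus Gaussian
    tag noise; with probability ``gross_error_rate`` a joint is displaced
    by a large uniform offset (200-500 px in a random direction) — the
    occasional gross mis-entry consensus aggregation must survive.
    """
    if n_annotators < 1:
        raise ValueError("n_annotators must be >= 1")
    if not 0.0 <= gross_error_rate <= 1.0:
        raise ValueError("gross_error_rate must be in [0, 1]")
    if noise_px < 0:
        raise ValueError("noise_px must be >= 0")
    rng = substream(seed, "annotators")
    annotations: list[Annotation] = []
    for i in range(n_annotators):
        tagged: dict[str, Keypoint] = {}
        for name in sorted(frame.keypoints):
            kp = frame.keypoints[name]
            if kp.is_absent:
                tagged[name] = Keypoint.absent()
                continue
            x, y = float(kp.x), float(kp.y)
            if noise_px > 0:
                dx, dy = rng.normal(0.0, noise_px, size=2)
                x, y = x + dx, y + dy
            if gross_error_rate > 0 and rng.random() < gross_error_rate:
                r = rng.uniform(200.0, 500.0)
                ang = rng.uniform(0.0, 2.0 * np.pi)
                x += r * np.cos(ang)
                y += r * np.sin(ang)
            tagged[name] = Keypoint(x=x, y=y, z=None, visibility=kp.visibility)
        xs = [k.x for k in tagged.values() if not k.is_absent]
        ys = [k.y for k in tagged.values() if not k.is_absent]
        bbox = None
        if xs:
            w = max(max(xs) - min(xs), 1.0)
            h = max(max(ys) - min(ys), 1.0)
            bbox = (min(xs), min(ys), w, h)
        annotations.append(
            Annotation(
                annotator_id=f"ann{i:02d}",
                image_id=image_id,
                joints=tagged,
                bbox=bbox,
            )
        )
    return annotations


def simulate_ratings(
    n_items: int,
    n_categories: int,
    target_agreement: float,
    seed: int = 0,
) -> RatingPair:
    """Paired categorical ratings with a controllable agreement level.

    Rater A draws uniformly over the categories; rater B copies A with
    probability ``target_agreement`` and otherwise resamples uniformly
    (so the realized raw agreement exceeds the target by chance matches).
    """
    if not 0.0 <= target_agreement <= 1.0:
        raise ValueError("target_agreement must be in [0, 1]")
    if n_items < 1 or n_categories < 1:
        raise ValueError("n_items and n_categories must be >= 1")
    rng = substream(seed, "ratings")
    a = rng.integers(0, n_categories, size=n_items)
    copy = rng.random(n_items) < target_agreement
    resample = rng.integers(0, n_categories, size=n_items)
    b = np.where(copy, a, resample)
    return RatingPair(
        rater_a=tuple(int(v) for v in a),
        rater_b=tuple(int(v) for v in b),
        categories=frozenset(range(n_categories)),
    )
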