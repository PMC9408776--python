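"""Pose-error metrics and inter-rater agreement statistics.

MPJPE is the mean over evaluated joints of the Euclidean distance between
the estimated and ground-truth joint positions, in mm:

    MPJPE = (1/J) * sum_j || Est_j - GT_j ||

PA-MPJPE first superimposes the estimate on the ground truth with a
similarity Procrustes transform (rotation + translation + uniform scale,
no reflection — the standard Protocol-1 practice), isolating pose-shape
error from global misalignment.

Agreement between two categorical raters uses Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed fraction of exact matches and p_e the agreement
expected by chance from the raters' marginals, with the conventional
strength-of-agreement labels (Poor ... Almost perfect).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .skeleton import PoseSequence

__all__ = [
    "JointSetPair",
    "RatingPair",
    "MissingJointError",
    "AlignmentError",
    "UndefinedKappaError",
    "mpjpe",
    "procrustes_align",
    "pa_mpjpe",
    "per_joint_errors",
    "cohen_kappa",
    "agreement_strength",
    "protocol_frame_sampler",
    "AGREEMENT_BINS",
]


class MissingJointError(KeyError):
    """An evaluation joint is missing from one of the joint maps."""


class AlignmentError(ValueError):
    """Procrustes alignment is undefined for this configuration."""


class UndefinedKappaError(ZeroDivisionError):
    """Chance agreement is 1, so kappa is undefined."""


@dataclass(frozen=True)
class JointSetPair:
    """An estimated and a ground-truth joint map with an evaluation subset."""

    estimated: Mapping[str, Sequence[float]]
    ground_truth: Mapping[str, Sequence[float]]
    joints: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.joints) < 1:
            raise ValueError("evaluation joint set must contain at least one joint")
        missing_est = [j for j in self.joints if j not in self.estimated]
        missing_gt = [j for j in self.joints if j not in self.ground_truth]
        if missing_est or missing_gt:
            raise MissingJointError(
                f"missing joints — estimated: {missing_est}, ground truth: {missing_gt}"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        est = np.array([self.estimated[j] for j in self.joints], dtype=float)
        gt = np.array([self.ground_truth[j] for j in self.joints], dtype=float)
        return est, gt


@dataclass(frozen=True)
class RatingPair:
    """Two equal-length categorical rating sequences."""

    rater_a: tuple
    rater_b: tuple
    categories: frozenset = frozenset()

    def __post_init__(self) -> None:
        if len(self.rater_a) != len(self.rater_b):
            raise ValueError("rating sequences must have equal length")
        if len(self.rater_a) < 1:
            raise ValueError("rating sequences must be non-empty")
        if self.categories:
            bad = (set(self.rater_a) | set(self.rater_b)) - set(self.categories)
            if bad:
                raise ValueError(f"labels outside declared category set: {sorted(map(str, bad))}")


def _coerce_pair(estimated, ground_truth=None, joints=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(estimated, JointSetPair):
        return estimated.arrays()
    if isinstance(estimated, Mapping):
        if joints is None:
            joints = [j for j in estimated if j in ground_truth]
        pair = JointSetPair(estimated, ground_truth, tuple(joints))
        return pair.arrays()
    est = np.asarray(estimated, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    if est.shape != gt.shape or est.ndim != 2:
        raise ValueError(f"point arrays must share shape (J, d); got {est.shape} vs {gt.shape}")
    return est, gt


def mpjpe(estimated, ground_truth=None, joints=None) -> float:
    """Mean per-joint position error in mm.

    Accepts a :class:`JointSetPair`, two joint-name maps (optionally with an
    explicit evaluation ``joints`` list), or two (J, 3) arrays.
    """
    est, gt = _coerce_pair(estimated, ground_truth, joints)
    return float(np.mean(np.linalg.norm(est - gt, axis=1)))


def per_joint_errors(estimated, ground_truth=None, joints=None) -> np.ndarray:
    est, gt = _coerce_pair(estimated, ground_truth, joints)
    return np.linalg.norm(est - gt, axis=1)


def procrustes_align(estimated, ground_truth=None, joints=None) -> np.ndarray:
    """Similarity-Procrustes superimposition of the estimate on ground truth.

    Finds the rotation (det +1), translation and uniform scale minimizing
    the summed squared distance to the ground-truth points over the
    evaluation joints, and returns the transformed estimate as a (J, 3)
    array in the evaluation-joint order.

    Raises
    ------
    AlignmentError
        if fewer than 3 joints are evaluated or the configuration is
        degenerate (collinear/coincident ground truth, zero-spread
        estimate).
    """
    est, gt = _coerce_pair(estimated, ground_truth, joints)
    n = est.shape[0]
    if n < 3:
        raise AlignmentError(f"need at least 3 joints to align, got {n}")

    mu_est = est.mean(axis=0)
    mu_gt = gt.mean(axis=0)
    x = est - mu_est
    y = gt - mu_gt

    var_est = float(np.sum(x**2)) / n
    if var_est <= 1e-12:
        raise AlignmentError("estimate has zero spread; alignment undefined")
    sv_gt = np.linalg.svd(y, compute_uv=False)
    if sv_gt[1] <= 1e-9 * max(sv_gt[0], 1.0):
        raise AlignmentError("ground-truth points are collinear; alignment undefined")

    cov = (y.T @ x) / n
    u, d, vt = np.linalg.svd(cov)
    s = np.ones(cov.shape[0])
    if np.linalg.det(u @ vt) < 0:
        s[-1] = -1.0
    rot = u @ np.diag(s) @ vt
    scale = float(np.sum(d * s)) / var_est
    t = mu_gt - scale * rot @ mu_est
    return scale * est @ rot.T + t


def pa_mpjpe(estimated, ground_truth=None, joints=None) -> float:
    """MPJPE after Procrustes alignment of the estimate, in mm."""
    est, gt = _coerce_pair(estimated, ground_truth, joints)
    aligned = procrustes_align(est, gt)
    return float(np.mean(np.linalg.norm(aligned - gt, axis=1)))


# ---------------------------------------------------------------------------
# Agreement statistics


def cohen_kappa(rater_a, rater_b=None) -> float:
    """Cohen's kappa between two categorical rating sequences.

    p_o is the fraction of exact matches, p_e the chance agreement from the
    product of the two raters' marginal distributions.  Raises
    :class:`UndefinedKappaError` when p_e = 1 (all probability mass in one
    agreeing cell pattern).
    """
    if isinstance(rater_a, RatingPair):
        a, b = list(rater_a.rater_a), list(rater_a.rater_b)
    else:
        a, b = list(rater_a), list(rater_b)
    if len(a) != len(b):
        raise ValueError("rating sequences must have equal length")
    n = len(a)
    if n < 1:
        raise ValueError("rating sequences must be non-empty")
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    marg_a = Counter(a)
    marg_b = Counter(b)
    p_e = sum((marg_a[c] / n) * (marg_b[c] / n) for c in set(marg_a) | set(marg_b))
    if abs(1.0 - p_e) < 1e-15:
        raise UndefinedKappaError("chance agreement p_e = 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


#: half-open strength-of-agreement bins: (upper bound, label); kappa <= 0 is Poor
AGREEMENT_BINS: tuple[tuple[float, str], ...] = (
    (0.0, "Poor"),
    (0.2, "Slight"),
    (0.4, "Fair"),
    (0.6, "Moderate"),
    (0.8, "Substantial"),
    (1.0, "Almost perfect"),
)


def agreement_strength(kappa: float) -> str:
    """Conventional strength label for a kappa value.

    Bins are half-open on the left: (-inf, 0] Poor, (0, 0.2] Slight,
    (0.2, 0.4] Fair, (0.4, 0.6] Moderate, (0.6, 0.8] Substantial,
    (0.8, 1] Almost perfect.
    """
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    for hi, label in AGREEMENT_BINS:
        if kappa <= hi:
            return label
    return AGREEMENT_BINS[-1][1]  # kappa == 1 within tolerance


def protocol_frame_sampler(seq: PoseSequence, stride: int) -> PoseSequence:
    """Every ``stride``-th frame (indices 0, stride, 2*stride, ...).

    This is the frame-subsampling rule used by the standard evaluation
    protocols (e.g. every 64th frame for testing).
    """
    if not isinstance(stride, (int, np.integer)) or stride < 1:
        raise ValueError(f"stride must be an integer >= 1, got {stride!r}")
    return PoseSequence(frames=seq.frames[::stride], fps=seq.fps / stride)
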