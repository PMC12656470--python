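"""Registration evaluation metrics.

RMSE between registered and reference point sets, precision/recall under the
<=5 px correct-match rule, detection accuracy from a confusion matrix, and the
orientation-agreement count (circular angle error strictly below 5 degrees).

Conventions followed literally: a match at distance exactly 5 px counts as
correct (the rule is "<= 5"); an angle error of exactly 5 degrees does NOT
count as agreeing (the rule is "< 5").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "MetricReport",
    "rmse",
    "precision_recall",
    "accuracy",
    "orientation_agreement",
]


@dataclass
class MetricReport:
    rmse: float | None = None
    precision: float | None = None
    recall: float | None = None
    accuracy: float | None = None
    n_matches: int = 0
    n_correct: int = 0
    n_correspond: int = 0
    orientation_agreement: int = 0

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "n_matches": self.n_matches,
            "n_correct": self.n_correct,
            "n_correspond": self.n_correspond,
            "orientation_agreement": self.orientation_agreement,
        }


def _as_points(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(-1, 2)
    return a


def rmse(points, refs) -> float:
    """Root-mean-square Euclidean distance, sqrt(sum ||p_i - r_i||^2 / N)."""
    p = _as_points(points)
    r = _as_points(refs)
    if len(p) == 0:
        raise ParameterError("rmse needs at least one point pair")
    if len(p) != len(r):
        raise ParameterError(f"length mismatch: {len(p)} points vs {len(r)} refs")
    d2 = np.sum((p - r) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def precision_recall(
    points, refs, correspond_count: int, radius: float = 5.0
) -> tuple[float | None, float | None]:
    """Precision = correct/total and recall = correct/correspond_count, where
    a match is correct iff its Euclidean distance to the reference is <= radius.

    A zero denominator makes the corresponding metric None (absent), never 0.
    """
    p = _as_points(points)
    r = _as_points(refs)
    if len(p) != len(r):
        raise ParameterError(f"length mismatch: {len(p)} points vs {len(r)} refs")
    total = len(p)
    correct = int(np.sum(np.linalg.norm(p - r, axis=1) <= radius))
    precision = correct / total if total > 0 else None
    recall = correct / correspond_count if correspond_count > 0 else None
    return precision, recall


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ParameterError("confusion-matrix counts must be non-negative")
    denom = sum(counts)
    if denom < 1:
        raise ParameterError("confusion matrix is empty")
    return (tp + tn) / denom


def circular_difference_deg(a_deg: float, b_deg: float) -> float:
    """Minimal absolute angular difference in degrees over the 2*pi wrap."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


def orientation_agreement(orients_a, orients_b, tol_deg: float = 5.0) -> int:
    """Count paired angles (degrees) whose circular difference is strictly
    below tol_deg."""
    a = np.asarray(orients_a, dtype=float).ravel()
    b = np.asarray(orients_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ParameterError(f"length mismatch: {len(a)} vs {len(b)} angles")
    d = np.abs(a - b) % 360.0
    d = np.minimum(d, 360.0 - d)
    return int(np.sum(d < tol_deg))


def correspond_count(
    kps_a, kps_b, true_map, radius: float = 5.0
) -> int:
    """Ground-truth denominator for recall: the number of keypoints in image A
    whose true corresponding location (through ``true_map``, a callable taking
    an (n,2) array of A-frame points to B-frame points) falls within ``radius``
    of some keypoint in image B."""
    if len(kps_a) == 0 or len(kps_b) == 0:
        return 0
    pa = np.array([kp.location for kp in kps_a], dtype=float)
    pb = np.array([kp.location for kp in kps_b], dtype=float)
    mapped = np.asarray(true_map(pa), dtype=float).reshape(-1, 2)
    from scipy.spatial import cKDTree

    tree = cKDTree(pb)
    d, _ = tree.query(mapped)
    return int(np.sum(d <= radius))
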