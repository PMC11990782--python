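"""Data-association costs and assignment.

Costs combine a motion term (squared Mahalanobis distance between each
detection and a track's predicted measurement distribution) with an
appearance term (minimum cosine distance between the detection descriptor
and a per-track gallery of recent descriptors):

    c[i, j] = lambda * d_motion[i, j] + (1 - lambda) * d_appearance[i, j]

Pairs whose motion distance exceeds a chi-square gate, or whose combined
cost exceeds the admissible matching threshold, are marked infeasible
(+inf) before the Hungarian solver runs.  The matching cascade prioritises
recently updated tracks, matching age groups youngest-first.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment

from .kalman import Measurement

__all__ = [
    "Detection",
    "DescriptorGallery",
    "INFEASIBLE",
    "CHI2_GATE_4DOF",
    "mahalanobis_matrix",
    "cosine_matrix",
    "combined_cost",
    "gate_cost",
    "solve_assignment",
    "matching_cascade",
]

logger = logging.getLogger(__name__)

#: Sentinel cost for pairs excluded from matching.
INFEASIBLE = np.inf

#: 0.95 quantile of the chi-square distribution with 4 degrees of freedom,
#: the standard Mahalanobis gate for a 4-D measurement space.
CHI2_GATE_4DOF = 9.487729036781154

_NORM_TOL = 1e-6


@dataclass
class Detection:
    """One detector output: a box, a confidence, an optional descriptor.

    The box is (left, top, width, height) in 0-based pixel coordinates.
    Descriptors are unit-norm appearance vectors; inputs that are not unit
    norm are re-normalised with a warning.
    """

    box: np.ndarray
    confidence: float
    descriptor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(4)
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError(f"detection box must have positive size, got {self.box}")
        self.confidence = float(self.confidence)
        if self.descriptor is not None:
            v = np.asarray(self.descriptor, dtype=float).ravel()
            norm = float(np.linalg.norm(v))
            if norm == 0.0:
                raise ValueError("descriptor must be non-zero")
            if abs(norm - 1.0) > _NORM_TOL:
                warnings.warn(
                    f"descriptor norm {norm:.4g} != 1; re-normalising", stacklevel=2
                )
                v = v / norm
            self.descriptor = v

    def to_measurement(self, gamma_mode: str = "aspect") -> Measurement:
        """Convert the box to measurement space (x, y, gamma, h).

        ``gamma_mode`` selects whether the third state component is the
        aspect ratio w/h (``"aspect"``, default) or the raw width
        (``"width"``).
        """
        left, top, w, h = self.box
        gamma = w / h if gamma_mode == "aspect" else w
        return Measurement(np.array([left + w / 2.0, top + h / 2.0, gamma, h]))

    @property
    def tlbr(self) -> np.ndarray:
        l, t, w, h = self.box
        return np.array([l, t, l + w, t + h])


class DescriptorGallery:
    """Ring buffer of the most recent unit descriptors for one track."""

    def __init__(self, budget: int = 100) -> None:
        if budget < 1:
            raise ValueError("gallery budget must be >= 1")
        self.budget = budget
        self._buf: deque[np.ndarray] = deque(maxlen=budget)

    def add(self, descriptor: np.ndarray) -> None:
        v = np.asarray(descriptor, dtype=float).ravel()
        norm = float(np.linalg.norm(v))
        if norm == 0.0:
            raise ValueError("descriptor must be non-zero")
        if abs(norm - 1.0) > _NORM_TOL:
            warnings.warn(
                f"gallery descriptor norm {norm:.4g} != 1; re-normalising",
                stacklevel=2,
            )
            v = v / norm
        self._buf.append(v)

    def __len__(self) -> int:
        return len(self._buf)

    def as_matrix(self) -> np.ndarray:
        return np.stack(list(self._buf)) if self._buf else np.empty((0, 0))


def mahalanobis_matrix(
    projected_states: Sequence[tuple[np.ndarray, np.ndarray]],
    detections: Sequence[Measurement],
) -> np.ndarray:
    """Squared Mahalanobis distance of every detection to every track.

    Entry (i, j) is ``(d_j - y_i)^T S_i^-1 (d_j - y_i)`` where ``(y_i, S_i)``
    is track i's predicted measurement distribution.
    """
    n, m = len(projected_states), len(detections)
    out = np.zeros((n, m))
    if m == 0 or n == 0:
        return out
    Z = np.stack([d.vector for d in detections])  # (m, 4)
    for i, (mean, cov) in enumerate(projected_states):
        try:
            chol = scipy.linalg.cho_factor(
                np.asarray(cov, dtype=float), lower=True, check_finite=False
            )
        except scipy.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular innovation covariance for track index {i}"
            ) from exc
        resid = (Z - np.asarray(mean, dtype=float)).T  # (4, m)
        sol = scipy.linalg.cho_solve(chol, resid, check_finite=False)
        out[i] = np.einsum("km,km->m", resid, sol)
    return out


def cosine_matrix(
    galleries: Sequence[DescriptorGallery],
    descriptors: Sequence[np.ndarray],
) -> np.ndarray:
    """Minimum cosine distance of each descriptor to each track gallery.

    Entry (i, j) = min over gallery i of (1 - r_j . r_k).  Tracks with an
    empty gallery get +inf (they are scored by motion only).
    """
    n, m = len(galleries), len(descriptors)
    out = np.full((n, m), INFEASIBLE)
    if m == 0 or n == 0:
        return out
    R = np.stack([np.asarray(r, dtype=float) for r in descriptors])  # (m, D)
    for i, gal in enumerate(galleries):
        if len(gal) == 0:
            continue
        G = gal.as_matrix()  # (L, D)
        out[i] = (1.0 - G @ R.T).min(axis=0)
    return out


def combined_cost(d1: np.ndarray, d2: np.ndarray, lam: float) -> np.ndarray:
    """Blend motion (d1) and appearance (d2) costs: lam*d1 + (1-lam)*d2."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError(f"cost shapes differ: {d1.shape} vs {d2.shape}")
    # Explicit endpoint handling so an infeasible term with zero weight
    # does not poison the blend via inf * 0 = nan.
    if lam == 0.0:
        return d2.copy()
    if lam == 1.0:
        return d1.copy()
    return lam * d1 + (1.0 - lam) * d2


def gate_cost(
    cost: np.ndarray,
    d1: np.ndarray,
    motion_gate: float = CHI2_GATE_4DOF,
    appearance_gate: float = np.inf,
) -> np.ndarray:
    """Mark pairs infeasible when motion or combined cost exceeds its gate."""
    cost = np.asarray(cost, dtype=float).copy()
    cost[np.asarray(d1) > motion_gate] = INFEASIBLE
    cost[cost > appearance_gate] = INFEASIBLE
    return cost


def solve_assignment(
    cost: np.ndarray,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one assignment over the finite entries.

    Returns (matches, unmatched_rows, unmatched_cols); pairs whose cost is
    infeasible are never matched.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    finite = np.isfinite(cost)
    if not finite.any():
        return [], list(range(n)), list(range(m))
    # fill value large enough that any all-feasible assignment beats one
    # routed through a single infeasible pair (max-cardinality behaviour)
    big = (cost[finite].max() + 1.0) * (min(n, m) + 1)
    filled = np.where(finite, cost, big)
    rows, cols = linear_sum_assignment(filled)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if finite[r, c]]
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    unmatched_rows = [i for i in range(n) if i not in matched_r]
    unmatched_cols = [j for j in range(m) if j not in matched_c]
    return matches, unmatched_rows, unmatched_cols


CostBuilder = Callable[[Sequence[int], Sequence[int]], np.ndarray]


def matching_cascade(
    track_ages: Sequence[int],
    detection_indices: Sequence[int],
    cost_builder: CostBuilder,
    max_age: int | None = None,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Age-prioritised cascade: recently updated tracks are matched first.

    ``track_ages[i]`` is track i's frames-since-last-update; groups with
    smaller age are offered the remaining detections before staler groups,
    so a fresh track always outranks a stale one competing for the same
    detection.  ``cost_builder(track_idx, det_idx)`` must return the gated
    cost sub-matrix for the given index subsets.

    Returns (matches, unmatched_tracks, unmatched_detections) in the
    caller's index space.
    """
    track_indices = list(range(len(track_ages)))
    remaining = list(detection_indices)
    matches: list[tuple[int, int]] = []
    if not track_indices or not remaining:
        return [], track_indices, remaining
    cap = max(track_ages) if max_age is None else max_age
    unmatched_tracks: list[int] = []
    for age in range(cap + 1):
        if not remaining:
            unmatched_tracks.extend(
                t for t in track_indices if track_ages[t] >= age
            )
            break
        group = [t for t in track_indices if track_ages[t] == age]
        if not group:
            continue
        sub = cost_builder(group, remaining)
        sub_matches, sub_un_tracks, sub_un_dets = solve_assignment(sub)
        matches.extend((group[r], remaining[c]) for r, c in sub_matches)
        unmatched_tracks.extend(group[r] for r in sub_un_tracks)
        remaining = [remaining[c] for c in sub_un_dets]
    else:
        pass
    leftover = {t for t in track_indices if track_ages[t] > cap}
    unmatched_tracks.extend(sorted(leftover))
    return matches, sorted(set(unmatched_tracks)), remaining
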