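"""Confidence-tiered cascaded association (COS).

Detector confidence degrades under occlusion and poor lighting, but a
low-confidence box often still marks a real, partially hidden animal.
Rather than discarding such boxes, detections are stratified into high /
medium / low confidence tiers and associated in three stages with
tier-specific admissibility thresholds:

- stage 1: all tracks vs the high tier, stringent threshold;
- stage 2: remaining tracks vs the medium tier, slightly relaxed;
- stage 3: remaining tracks vs the low tier, motion/overlap cost only —
  occluded crops corrupt appearance descriptors, so the appearance term
  is not trusted here and matched low-tier descriptors never enter the
  gallery.

Low-tier detections carry the lowest priority: they are only considered
after both higher tiers have had their chance, and they never initiate
new tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .association import Detection, matching_cascade, solve_assignment

__all__ = ["TierConfig", "TieredDetections", "stratify_detections", "tiered_associate", "iou_matrix"]


@dataclass
class TierConfig:
    """Confidence tier boundaries and per-tier matching thresholds.

    Thresholds are maximum admissible association distances: the high tier
    gets the most stringent (smallest) ceiling.  ``thr_low`` bounds
    ``1 - IoU`` in the motion-only third stage.
    """

    tau_high: float = 0.6
    tau_low: float = 0.3
    tau_discard: float = 0.1
    thr_high: float = 0.2
    thr_medium: float = 0.3
    thr_low: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_discard < self.tau_low < self.tau_high < 1.0):
            raise ValueError(
                "confidence tiers must satisfy 0 <= tau_discard < tau_low < tau_high < 1, "
                f"got {self.tau_discard}, {self.tau_low}, {self.tau_high}"
            )
        if not (self.thr_high <= self.thr_medium <= self.thr_low):
            raise ValueError(
                "tier thresholds must satisfy thr_high <= thr_medium <= thr_low, "
                f"got {self.thr_high}, {self.thr_medium}, {self.thr_low}"
            )


@dataclass
class TieredDetections:
    """Index partition of one frame's detections by confidence tier."""

    high: list[int] = field(default_factory=list)
    medium: list[int] = field(default_factory=list)
    low: list[int] = field(default_factory=list)
    discarded: list[int] = field(default_factory=list)


def stratify_detections(
    detections: Sequence[Detection], cfg: TierConfig
) -> TieredDetections:
    """Partition detection indices by confidence.

    conf >= tau_high -> high; tau_low <= conf < tau_high -> medium;
    tau_discard <= conf < tau_low -> low; below tau_discard -> discarded.
    All bounds are closed below.
    """
    tiers = TieredDetections()
    for idx, det in enumerate(detections):
        c = det.confidence
        if c >= cfg.tau_high:
            tiers.high.append(idx)
        elif c >= cfg.tau_low:
            tiers.medium.append(idx)
        elif c >= cfg.tau_discard:
            tiers.low.append(idx)
        else:
            tiers.discarded.append(idx)
    return tiers


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two sets of (left, top, width, height) boxes."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.maximum(
        0.0, np.minimum(ax2[:, None], bx2[None]) - np.maximum(ax1[:, None], bx1[None])
    )
    iy = np.maximum(
        0.0, np.minimum(ay2[:, None], by2[None]) - np.maximum(ay1[:, None], by1[None])
    )
    inter = ix * iy
    union = (a[:, 2] * a[:, 3])[:, None] + (b[:, 2] * b[:, 3])[None] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


# cost_builder(track_indices, det_indices, threshold) -> gated cost sub-matrix
TierCostBuilder = Callable[[Sequence[int], Sequence[int], float], np.ndarray]


def tiered_associate(
    track_ages: Sequence[int],
    tiers: TieredDetections,
    cfg: TierConfig,
    appearance_cost_builder: TierCostBuilder,
    iou_cost_builder: TierCostBuilder,
) -> tuple[list[tuple[int, int, str]], list[int], list[int]]:
    """Three-stage tiered association.

    Parameters
    ----------
    track_ages
        Frames-since-update per track; drives the per-stage matching
        cascade.
    appearance_cost_builder, iou_cost_builder
        Callables producing gated cost sub-matrices for (tracks, dets,
        threshold); the first blends motion and appearance (stages 1-2),
        the second is 1 - IoU (stage 3).

    Returns
    -------
    (matches, unmatched_tracks, unmatched_high)
        ``matches`` are (track_index, detection_index, tier) triples; only
        unmatched *high*-tier detections are reported back, since they
        alone may initiate new tracks.
    """
    remaining_tracks = list(range(len(track_ages)))
    matches: list[tuple[int, int, str]] = []

    def run_stage(det_idx: list[int], thr: float, tier: str, builder: TierCostBuilder):
        nonlocal remaining_tracks
        if not remaining_tracks or not det_idx:
            return det_idx
        ages = [track_ages[t] for t in remaining_tracks]

        def sub_cost(rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
            t_idx = [remaining_tracks[r] for r in rows]
            d_idx = [det_idx[c] for c in cols]
            return builder(t_idx, d_idx, thr)

        st_matches, st_un_tracks, st_un_dets = matching_cascade(
            ages, list(range(len(det_idx))), sub_cost
        )
        matches.extend(
            (remaining_tracks[r], det_idx[c], tier) for r, c in st_matches
        )
        remaining_tracks = [remaining_tracks[r] for r in st_un_tracks]
        return [det_idx[c] for c in st_un_dets]

    unmatched_high = run_stage(list(tiers.high), cfg.thr_high, "high", appearance_cost_builder)
    run_stage(list(tiers.medium), cfg.thr_medium, "medium", appearance_cost_builder)
    run_stage(list(tiers.low), cfg.thr_low, "low", iou_cost_builder)
    return matches, remaining_tracks, unmatched_high
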