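"""Per-frame tracking orchestration.

Each call to :meth:`Tracker.step` runs one frame through the pipeline:
Kalman predict for every live track, camera-motion compensation of the
predicted states when an image pair is available, confidence-tiered
association against the frame's detections, Kalman/gallery updates for
the matches, and lifecycle management (tentative / confirmed / missing /
deleted).  Only confirmed tracks that were matched in the current frame
are emitted.

Track identities are positive integers, allocated in increasing order and
never reused within a run.  A confirmed track that goes unmatched becomes
"missing" but stays in the association pool for up to ``max_age`` frames;
if it is re-matched it resumes under its original identity.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import kalman
from .association import (
    CHI2_GATE_4DOF,
    DescriptorGallery,
    Detection,
    INFEASIBLE,
    combined_cost,
    cosine_matrix,
    gate_cost,
    mahalanobis_matrix,
    solve_assignment,
)
from .cmc import AffineMotion, CMCParams, compensate_track, estimate_frame_motion
from .cos import TierConfig, TieredDetections, iou_matrix, stratify_detections, tiered_associate
from .kalman import NoiseConfig, TrackState

__all__ = ["Track", "TrackStatus", "TrackerConfig", "FrameResult", "Tracker", "embed_patch"]

logger = logging.getLogger(__name__)


class SequencingError(ValueError):
    """Frame indices must be fed in strictly increasing order."""


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    MISSING = "missing"
    DELETED = "deleted"


@dataclass
class TrackerConfig:
    """All tracker tunables in one place (see docs/methods.md)."""

    n_init: int = 3
    max_age: int = 30
    lam: float = 0.0
    motion_gate: float = CHI2_GATE_4DOF
    #: max 1 - IoU for the final rescue stage that re-associates tentative
    #: and freshly lost tracks with leftover confident detections
    #: (Deep SORT's IoU matching stage)
    max_iou_distance: float = 0.7
    gallery_budget: int = 100
    gamma_mode: str = "aspect"  # "aspect" | "width"
    use_cmc: bool = True
    use_cos: bool = True
    tiers: TierConfig = field(default_factory=TierConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cmc: CMCParams = field(default_factory=CMCParams)

    def __post_init__(self) -> None:
        if self.n_init < 1 or self.max_age < 1:
            raise ValueError("n_init and max_age must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class Track:
    """One tracked target and its bookkeeping."""

    track_id: int
    state: TrackState
    gallery: DescriptorGallery
    status: TrackStatus = TrackStatus.TENTATIVE
    hits: int = 1
    time_since_update: int = 0
    last_confidence: float = 0.0

    def to_box(self, gamma_mode: str = "aspect") -> np.ndarray:
        """Current state as a (left, top, width, height) box."""
        x, y, gamma, h = self.state.mean[:4]
        w = gamma * h if gamma_mode == "aspect" else gamma
        return np.array([x - w / 2.0, y - h / 2.0, w, h])


@dataclass
class FrameResult:
    """Confirmed, currently-matched tracks for one frame."""

    frame_index: int
    tracks: list[tuple[int, np.ndarray, float]]  # (track_id, tlwh box, confidence)


def embed_patch(frame: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Deterministic appearance descriptor from an 8x8x8 colour histogram.

    The box is clipped to the frame; grayscale frames are treated as three
    identical channels.  The histogram is L2-normalised, so identical
    patches give identical unit descriptors.

    Raises ``ValueError`` if the box does not intersect the frame.
    """
    img = np.asarray(frame)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    H, W = img.shape[:2]
    l, t, w, h = np.asarray(box, dtype=float)
    x0, y0 = int(np.floor(max(0.0, l))), int(np.floor(max(0.0, t)))
    x1, y1 = int(np.ceil(min(W, l + w))), int(np.ceil(min(H, t + h)))
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"box {box} does not intersect frame of shape {frame.shape}")
    patch = img[y0:y1, x0:x1].reshape(-1, 3)
    bins = np.clip(patch.astype(int) // 32, 0, 7)  # 256 / 8 = 32 levels per bin
    flat = bins[:, 0] * 64 + bins[:, 1] * 8 + bins[:, 2]
    hist = np.bincount(flat, minlength=512).astype(float)
    return hist / np.linalg.norm(hist)


class Tracker:
    """Online multi-object tracker (Deep-SORT-style with CMC and COS)."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._id_counter = itertools.count(1)
        self._last_frame_index: int | None = None
        self._prev_image: np.ndarray | None = None
        self._prev_detections: list[Detection] = []
        self.last_motion: AffineMotion | None = None
        self._warned_no_descriptors = False

    # -- association cost builders -------------------------------------

    def _appearance_cost(self, track_idx, det_idx, threshold, detections):
        cfg = self.config
        active = self.tracks
        projected = [
            kalman.project(active[t].state, cfg.noise) for t in track_idx
        ]
        meas = [detections[j].to_measurement(cfg.gamma_mode) for j in det_idx]
        d1 = mahalanobis_matrix(projected, meas)
        lam = cfg.lam
        descriptors = [detections[j].descriptor for j in det_idx]
        if any(d is None for d in descriptors):
            if lam < 1.0 and not self._warned_no_descriptors:
                logger.warning(
                    "no appearance descriptors available; falling back to "
                    "pure motion cost (lambda = 1)"
                )
                self._warned_no_descriptors = True
            lam = 1.0
        if lam == 1.0:
            # Pure motion: the chi-square gate is the only admissibility test.
            return gate_cost(d1, d1, cfg.motion_gate, np.inf)
        galleries = [active[t].gallery for t in track_idx]
        d2 = cosine_matrix(galleries, descriptors)
        cost = combined_cost(d1, d2, lam)
        return gate_cost(cost, d1, cfg.motion_gate, threshold)

    def _iou_cost(self, track_idx, det_idx, threshold, detections):
        cfg = self.config
        track_boxes = np.stack(
            [self.tracks[t].to_box(cfg.gamma_mode) for t in track_idx]
        )
        det_boxes = np.stack([detections[j].box for j in det_idx])
        cost = 1.0 - iou_matrix(track_boxes, det_boxes)
        cost[cost > threshold] = INFEASIBLE
        return cost

    # -- pipeline stages ------------------------------------------------

    def _predict_all(self) -> None:
        for tr in self.tracks:
            tr.state = kalman.predict(tr.state, self.config.noise)
            tr.time_since_update += 1

    def _compensate_all(self, motion: AffineMotion) -> None:
        cfg = self.config
        for tr in self.tracks:
            Qn = (
                kalman.process_noise(tr.state.mean[3], cfg.noise)
                if cfg.cmc.extra_process_noise
                else None
            )
            tr.state = compensate_track(tr.state, motion, Qn, cfg.cmc.apply)

    def _start_track(self, det: Detection) -> Track:
        state = kalman.initiate(det.to_measurement(self.config.gamma_mode), self.config.noise)
        gallery = DescriptorGallery(self.config.gallery_budget)
        if det.descriptor is not None:
            gallery.add(det.descriptor)
        track = Track(
            track_id=next(self._id_counter),
            state=state,
            gallery=gallery,
            status=TrackStatus.CONFIRMED
            if self.config.n_init <= 1
            else TrackStatus.TENTATIVE,
        )
        self.tracks.append(track)
        return track

    def update_lifecycle(
        self,
        matches: list[tuple[int, int, str]],
        unmatched_tracks: list[int],
        detections: list[Detection],
    ) -> None:
        """Apply the status-transition rules after association.

        Matched tracks are Kalman-updated, their hit counts advanced, and
        (for high/medium tiers) the detection descriptor is appended to the
        gallery; tentative tracks confirm after ``n_init`` hits, missing
        tracks resume as confirmed under their original id.  Unmatched
        tentative tracks are deleted immediately; unmatched confirmed
        tracks become missing; missing tracks older than ``max_age`` are
        deleted.
        """
        cfg = self.config
        for t_idx, d_idx, tier in matches:
            tr = self.tracks[t_idx]
            det = detections[d_idx]
            tr.state = kalman.update(
                tr.state, det.to_measurement(cfg.gamma_mode), cfg.noise
            )
            tr.hits += 1
            tr.time_since_update = 0
            tr.last_confidence = det.confidence
            if tier != "low" and det.descriptor is not None:
                tr.gallery.add(det.descriptor)
            if tr.status is TrackStatus.TENTATIVE and tr.hits >= cfg.n_init:
                tr.status = TrackStatus.CONFIRMED
            elif tr.status is TrackStatus.MISSING:
                tr.status = TrackStatus.CONFIRMED
        for t_idx in unmatched_tracks:
            tr = self.tracks[t_idx]
            if tr.status is TrackStatus.TENTATIVE:
                tr.status = TrackStatus.DELETED
            elif tr.status is TrackStatus.CONFIRMED:
                tr.status = TrackStatus.MISSING
            if (
                tr.status is TrackStatus.MISSING
                and tr.time_since_update > cfg.max_age
            ):
                tr.status = TrackStatus.DELETED
        self.tracks = [t for t in self.tracks if t.status is not TrackStatus.DELETED]

    def step(
        self,
        frame_index: int,
        detections: list[Detection],
        image: np.ndarray | None = None,
    ) -> FrameResult:
        """Process one frame and return the confirmed tracks.

        ``image`` (grayscale or RGB) enables camera-motion compensation
        against the previously supplied frame and, if detections carry no
        descriptors, the built-in patch-histogram embedder.
        """
        if self._last_frame_index is not None and frame_index <= self._last_frame_index:
            raise SequencingError(
                f"frame index {frame_index} not greater than previous "
                f"{self._last_frame_index}"
            )
        self._last_frame_index = frame_index
        cfg = self.config

        gray = None
        if image is not None:
            gray = np.asarray(image, dtype=float)
            if gray.ndim == 3:
                # ITU-R BT.601 luma
                gray = gray @ np.array([0.299, 0.587, 0.114])
            if any(d.descriptor is None for d in detections):
                for d in detections:
                    if d.descriptor is None:
                        try:
                            d.descriptor = embed_patch(gray, d.box)
                        except ValueError:
                            d.descriptor = None

        self._predict_all()

        self.last_motion = None
        if cfg.use_cmc and gray is not None and self._prev_image is not None:
            motion = estimate_frame_motion(
                self._prev_image, gray, self._prev_detections, detections, cfg.cmc
            )
            self.last_motion = motion
            if self.tracks:
                self._compensate_all(motion)

        if cfg.use_cos:
            tiers = stratify_detections(detections, cfg.tiers)
        else:
            # Baseline: keep confident detections only, single high tier.
            tiers = TieredDetections(
                high=[i for i, d in enumerate(detections) if d.confidence >= cfg.tiers.tau_high],
                discarded=[i for i, d in enumerate(detections) if d.confidence < cfg.tiers.tau_high],
            )

        ages = [tr.time_since_update for tr in self.tracks]
        matches, unmatched_tracks, unmatched_high = tiered_associate(
            ages,
            tiers,
            cfg.tiers,
            lambda t, d, thr: self._appearance_cost(t, d, thr, detections),
            lambda t, d, thr: self._iou_cost(t, d, thr, detections),
        )
        # Deep SORT's final IoU stage: tentative and freshly lost tracks get
        # one more chance at the leftover confident detections, absorbing
        # single-frame gate failures that would otherwise spawn duplicates.
        rescue_tracks = [
            t
            for t in unmatched_tracks
            if self.tracks[t].status is TrackStatus.TENTATIVE
            or self.tracks[t].time_since_update == 1
        ]
        if rescue_tracks and unmatched_high:
            cost = self._iou_cost(rescue_tracks, unmatched_high, cfg.max_iou_distance, detections)
            iou_matches, un_r, un_d = solve_assignment(cost)
            matches = matches + [
                (rescue_tracks[r], unmatched_high[c], "high") for r, c in iou_matches
            ]
            rescued = {rescue_tracks[r] for r, _ in iou_matches}
            unmatched_tracks = [t for t in unmatched_tracks if t not in rescued]
            unmatched_high = [unmatched_high[c] for c in un_d]
        self.update_lifecycle(matches, unmatched_tracks, detections)
        for d_idx in unmatched_high:
            self._start_track(detections[d_idx])

        if image is not None:
            self._prev_image = gray
            self._prev_detections = list(detections)

        emitted = [
            (tr.track_id, tr.to_box(cfg.gamma_mode), tr.last_confidence)
            for tr in self.tracks
            if tr.status is TrackStatus.CONFIRMED and tr.time_since_update == 0
        ]
        return FrameResult(frame_index=frame_index, tracks=emitted)


def run_tracker(
    detections_by_frame: dict[int, list[Detection]],
    config: TrackerConfig | None = None,
    images: dict[int, np.ndarray] | None = None,
) -> list[FrameResult]:
    """Track a whole sequence of per-frame detections."""
    tracker = Tracker(config)
    results = []
    for frame in sorted(detections_by_frame):
        image = images.get(frame) if images else None
        results.append(tracker.step(frame, detections_by_frame[frame], image))
    return results
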