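"""Camera motion compensation (CMC).

UAV footage carries global frame-to-frame motion (the aircraft translates,
yaws and changes altitude) that violates the tracker's constant-velocity
assumption.  This module estimates the background motion between
consecutive frames as a 2-D affine transform and warps every track's
predicted Kalman state by it:

1. locate the horizon as the image row of maximal mean absolute vertical
   gradient, and mask out everything above it (sky / far terrain);
2. mask out every detected animal box (dilated by a margin) so only static
   ground texture anchors keypoints;
3. detect FAST corners in the masked regions of both frames, describe them
   with BRIEF, match with a ratio-test nearest-neighbour search plus a
   spatial-distance filter;
4. fit a full 6-dof affine [M|T] with RANSAC; on failure fall back to the
   identity transform.

The 2x2 block M is lifted to an 8x8 block-diagonal matrix acting on the
state (x, y, gamma, h, vx, vy, vgamma, vh) pairwise, and T to an 8-vector
touching only (x, y); mean and covariance are transformed accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from skimage.feature import BRIEF, corner_fast, corner_peaks, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform

from .association import Detection
from .kalman import TrackState, symmetrize

__all__ = [
    "CMCParams",
    "AffineMotion",
    "detect_horizon",
    "build_static_mask",
    "match_keypoints",
    "estimate_affine",
    "compensate_track",
]


@dataclass
class CMCParams:
    """Tunables for background-motion estimation.

    max_shift is expressed as a fraction of the frame diagonal; matched
    keypoint pairs displaced farther than that are discarded before RANSAC.
    """

    fast_threshold: float = 0.08
    fast_n: int = 9
    max_keypoints: int = 400
    lowe_ratio: float = 0.75
    max_shift_frac: float = 0.10
    ransac_threshold: float = 3.0
    ransac_confidence: float = 0.995
    ransac_max_trials: int = 500
    min_pairs: int = 8
    mask_margin: float = 0.1
    use_horizon: bool = True
    apply: str = "full"  # "full" | "position_only"
    extra_process_noise: bool = True
    seed: int = 0


@dataclass
class AffineMotion:
    """Estimated background motion from the previous to the current frame."""

    M: np.ndarray
    T: np.ndarray
    inlier_count: int = 0
    source: str = "estimated"  # "estimated" | "identity_fallback"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float).reshape(2, 2)
        self.T = np.asarray(self.T, dtype=float).reshape(2)

    @classmethod
    def identity(cls, source: str = "identity_fallback") -> "AffineMotion":
        return cls(M=np.eye(2), T=np.zeros(2), inlier_count=0, source=source)

    def extended(self, mode: str = "full") -> tuple[np.ndarray, np.ndarray]:
        """Lift (M, T) to state space: 8x8 block-diagonal M_ext, 8-vector T_ext.

        ``mode="full"`` applies M to all four component pairs, including
        (gamma, h); ``mode="position_only"`` applies it to the positional
        pairs (x, y) and (vx, vy) only.
        """
        if mode == "full":
            M_ext = scipy.linalg.block_diag(self.M, self.M, self.M, self.M)
        elif mode == "position_only":
            M_ext = scipy.linalg.block_diag(self.M, np.eye(2), self.M, np.eye(2))
        else:
            raise ValueError(f"unknown cmc apply mode {mode!r}")
        T_ext = np.zeros(8)
        T_ext[:2] = self.T
        return M_ext, T_ext

    def apply_point(self, xy: np.ndarray) -> np.ndarray:
        return (np.asarray(xy, dtype=float) @ self.M.T) + self.T

    def compose(self, other: "AffineMotion") -> "AffineMotion":
        """Return the motion 'other then self' (self applied second)."""
        return AffineMotion(
            M=self.M @ other.M,
            T=self.M @ other.T + self.T,
            inlier_count=min(self.inlier_count, other.inlier_count),
            source="estimated"
            if self.source == other.source == "estimated"
            else "identity_fallback",
        )


def detect_horizon(frame: np.ndarray) -> int:
    """Row of maximal mean absolute vertical gradient.

    The vertical gradient is the backward difference I[y] - I[y-1] (zero
    for the top row), so a hard horizontal edge is attributed to the first
    row of the new region; ties break to the smallest row index.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"frame must be 2-D, at least 2x2, got shape {img.shape}")
    gy = np.diff(img, axis=0, prepend=img[:1])
    row_strength = np.abs(gy).mean(axis=1)
    return int(np.argmax(row_strength))


def build_static_mask(
    shape: tuple[int, int],
    detections: list[Detection],
    horizon: int = 0,
    margin: float = 0.1,
) -> np.ndarray:
    """Boolean mask of pixels usable for background keypoints.

    False strictly above the horizon row and inside every detection box
    dilated by ``margin`` (a fraction of the box size per side).
    """
    mask = np.ones(shape, dtype=bool)
    mask[: max(0, horizon)] = False
    H, W = shape
    for det in detections:
        l, t, w, h = det.box
        x0 = int(np.floor(l - margin * w))
        y0 = int(np.floor(t - margin * h))
        x1 = int(np.ceil(l + w + margin * w))
        y1 = int(np.ceil(t + h + margin * h))
        mask[max(0, y0) : min(H, y1), max(0, x0) : min(W, x1)] = False
    return mask


def _keypoints_and_descriptors(
    frame: np.ndarray, mask: np.ndarray, params: CMCParams
) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(frame, dtype=float) / 255.0
    response = corner_fast(img, n=params.fast_n, threshold=params.fast_threshold)
    response[~mask] = 0.0
    corners = corner_peaks(
        response, min_distance=3, threshold_rel=0.0, num_peaks=params.max_keypoints
    )
    if len(corners) == 0:
        return np.empty((0, 2)), np.empty((0, 0), dtype=bool)
    extractor = BRIEF(descriptor_size=256, patch_size=25, sigma=1.0)
    extractor.extract(img, corners)
    return corners[extractor.mask], extractor.descriptors


def match_keypoints(
    prev: np.ndarray,
    curr: np.ndarray,
    prev_mask: np.ndarray | None = None,
    curr_mask: np.ndarray | None = None,
    params: CMCParams | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Matched background keypoint pairs between two frames.

    Returns a list of ``(p_prev, p_curr)`` pairs in (x, y) pixel
    coordinates after ratio-test matching and the spatial-distance filter.
    An empty list is a valid result (featureless frames).
    """
    params = params or CMCParams()
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError("frames must share a shape")
    if prev_mask is None:
        prev_mask = np.ones(prev.shape, dtype=bool)
    if curr_mask is None:
        curr_mask = np.ones(curr.shape, dtype=bool)
    kp1, d1 = _keypoints_and_descriptors(prev, prev_mask, params)
    kp2, d2 = _keypoints_and_descriptors(curr, curr_mask, params)
    if len(kp1) == 0 or len(kp2) == 0:
        return []
    pairs_idx = match_descriptors(
        d1, d2, cross_check=True, max_ratio=params.lowe_ratio
    )
    max_shift = params.max_shift_frac * float(np.hypot(*prev.shape))
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for i, j in pairs_idx:
        p = kp1[i][::-1].astype(float)  # (row, col) -> (x, y)
        q = kp2[j][::-1].astype(float)
        if np.linalg.norm(q - p) <= max_shift:
            out.append((p, q))
    return out


def estimate_affine(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    params: CMCParams | None = None,
) -> AffineMotion:
    """RANSAC fit of the 6-dof affine [M|T] mapping prev points to curr.

    Falls back to the identity transform when there are fewer than
    ``min_pairs`` correspondences, the fit degenerates, or the recovered
    linear part is orientation-reversing.
    """
    params = params or CMCParams()
    if len(pairs) < params.min_pairs:
        return AffineMotion.identity()
    src = np.stack([p for p, _ in pairs])
    dst = np.stack([q for _, q in pairs])
    try:
        model, inliers = ransac(
            (src, dst),
            AffineTransform,
            min_samples=3,
            residual_threshold=params.ransac_threshold,
            max_trials=params.ransac_max_trials,
            stop_probability=params.ransac_confidence,
            rng=params.seed,
        )
    except Exception:
        return AffineMotion.identity()
    if model is None or inliers is None or inliers.sum() < params.min_pairs // 2:
        return AffineMotion.identity()
    A = model.params  # 3x3 homogeneous
    M = A[:2, :2]
    T = A[:2, 2]
    if not np.all(np.isfinite(A)) or np.linalg.det(M) <= 0:
        return AffineMotion.identity()
    return AffineMotion(M=M, T=T, inlier_count=int(inliers.sum()), source="estimated")


def compensate_track(
    state: TrackState,
    motion: AffineMotion,
    Qn: np.ndarray | None = None,
    mode: str = "full",
) -> TrackState:
    """Warp a predicted track state by the estimated background motion.

    mean' = M_ext mean + T_ext;  cov' = M_ext P M_ext^T + Qn.

    ``Qn`` is an optional extra process-noise term added at compensation
    time (pass None or zeros to disable); with identity motion and no
    noise the state is returned unchanged.
    """
    M_ext, T_ext = motion.extended(mode)
    mean = M_ext @ state.mean + T_ext
    cov = M_ext @ state.covariance @ M_ext.T
    if Qn is not None:
        cov = cov + np.asarray(Qn, dtype=float)
    return TrackState(mean=mean, covariance=symmetrize(cov))


def estimate_frame_motion(
    prev: np.ndarray,
    curr: np.ndarray,
    prev_detections: list[Detection],
    curr_detections: list[Detection],
    params: CMCParams | None = None,
) -> AffineMotion:
    """Full pipeline: horizon, static masks, keypoints, RANSAC affine."""
    params = params or CMCParams()
    horizon_prev = detect_horizon(prev) if params.use_horizon else 0
    horizon_curr = detect_horizon(curr) if params.use_horizon else 0
    prev_mask = build_static_mask(
        prev.shape, prev_detections, horizon_prev, params.mask_margin
    )
    curr_mask = build_static_mask(
        curr.shape, curr_detections, horizon_curr, params.mask_margin
    )
    pairs = match_keypoints(prev, curr, prev_mask, curr_mask, params)
    return estimate_affine(pairs, params)
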