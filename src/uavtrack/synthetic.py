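"""Seeded generator of UAV-like tracking scenes.

The generator emulates the statistical structure of drone footage of a
herd of ungulates without any photorealism:

- targets follow smooth correlated random walks (per-frame heading noise
  on a constant per-target speed), reflecting off the frame borders;
- the camera carries global frame-to-frame jitter — translation, small
  rotation and zoom about the frame centre — composed into a cumulative
  world-to-camera affine per frame, which is the exact ground truth the
  camera-motion-compensation module should recover;
- occlusion is modelled as scheduled episodes per target during which the
  detector's confidence drops to a configured floor, so tier membership
  under the confidence-stratified matcher is controllable and exactly
  known;
- detections are the camera-coordinate ground truth corrupted by box
  jitter, random misses, uniform false positives and confidence noise;
- appearance descriptors are per-identity fixed unit anchors plus
  Gaussian noise, re-normalised;
- rendered frames place a value-noise ground texture below a dark sky
  split at a known horizon row, warp it by the true camera affine, and
  draw each target as a filled ellipse with a per-identity intensity.

Every random draw comes from a stream derived from ``(seed, component)``
so toggling one noise source never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.ndimage

from .association import Detection
from .cmc import AffineMotion

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "simulate_scenario",
    "corrupt_detections",
    "synthesize_descriptors",
    "render_frames",
    "scenario_digest",
]

# spawn keys of the per-component random streams
_TRAJ, _CAMERA, _OCCLUSION, _DETNOISE, _DESCRIPTOR, _RENDER = range(6)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scene.

    Defaults describe a desk-scale UAV grassland scene: a handful of
    animal-sized targets in a 320x240 crop, moving a few pixels per frame,
    under moderate camera jitter and occasional occlusion episodes.
    """

    n_targets: int = 6
    n_frames: int = 60
    frame_size: tuple[int, int] = (320, 240)  # (width, height)
    # target motion
    speed_range: tuple[float, float] = (1.0, 3.0)  # px / frame
    turn_rate_std: float = 0.15  # rad / frame
    target_height_range: tuple[float, float] = (14.0, 24.0)
    aspect_range: tuple[float, float] = (1.2, 1.8)
    # camera jitter (per frame)
    cam_translation_std: float = 4.0  # px
    cam_rotation_std_deg: float = 0.5
    cam_zoom_std: float = 0.005
    # occlusion episodes
    occlusion_rate: float = 0.02  # episode starts / target / frame
    occlusion_duration: tuple[int, int] = (5, 15)  # frames, inclusive
    occlusion_conf_floor: float = 0.15
    # detection corruption
    miss_rate: float = 0.05
    bbox_jitter_std: float = 1.0  # px
    false_positive_rate: float = 0.5  # expected FPs / frame
    conf_noise_std: float = 0.05
    # appearance descriptors
    descriptor_dim: int = 128
    descriptor_noise_std: float = 0.1
    # rendering
    horizon_frac: float = 0.2  # horizon row as a fraction of frame height
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occlusion_rate", "miss_rate", "conf_noise_std", "horizon_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.descriptor_dim < 8:
            raise ValueError("descriptor_dim must be >= 8")
        W, H = self.frame_size
        if self.target_height_range[1] * max(self.aspect_range) >= min(W, H):
            raise ValueError("targets larger than the frame are infeasible")


@dataclass
class Scenario:
    """Ground truth + corrupted observations for one synthetic scene.

    Frame indices are 1-based throughout (MOTChallenge convention).
    ``gt_world`` holds boxes in static world coordinates, ``gt_camera``
    the same boxes pushed through the cumulative camera affine of each
    frame.  ``true_affines[f]`` is the frame-to-frame background motion
    (frame f-1 to f); ``cumulative_affines[f]`` maps world to camera.
    """

    config: ScenarioConfig
    gt_world: dict[int, list[tuple[int, np.ndarray]]]
    gt_camera: dict[int, list[tuple[int, np.ndarray]]]
    true_affines: dict[int, AffineMotion]
    cumulative_affines: dict[int, AffineMotion]
    occluded: dict[int, set[int]]
    detections: dict[int, list[Detection]] = field(default_factory=dict)
    det_labels: dict[int, list[int]] = field(default_factory=dict)  # gt id or -1
    horizon_world: int = 0
    horizon_rows: dict[int, int] = field(default_factory=dict)
    frames: dict[int, np.ndarray] = field(default_factory=dict)


def _sample_frame_affine(cfg: ScenarioConfig, rng: np.random.Generator) -> AffineMotion:
    W, H = cfg.frame_size
    theta = np.deg2rad(rng.normal(0.0, cfg.cam_rotation_std_deg))
    scale = 1.0 + rng.normal(0.0, cfg.cam_zoom_std)
    t = rng.normal(0.0, cfg.cam_translation_std, size=2)
    c, s = np.cos(theta), np.sin(theta)
    M = scale * np.array([[c, -s], [s, c]])
    centre = np.array([W / 2.0, H / 2.0])
    T = centre - M @ centre + t
    return AffineMotion(M=M, T=T, inlier_count=0, source="ground_truth")


def _transform_box(box: np.ndarray, motion: AffineMotion) -> np.ndarray:
    """Push a (l, t, w, h) box through an affine: centre moves, size scales
    isotropically by sqrt(det M), aspect preserved."""
    l, t, w, h = box
    centre = motion.apply_point(np.array([l + w / 2.0, t + h / 2.0]))
    s = float(np.sqrt(np.linalg.det(motion.M)))
    w2, h2 = w * s, h * s
    return np.array([centre[0] - w2 / 2.0, centre[1] - h2 / 2.0, w2, h2])


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate trajectories, camera affines, occlusions and detections."""
    W, H = cfg.frame_size
    traj_rng = _rng(cfg.seed, _TRAJ)
    cam_rng = _rng(cfg.seed, _CAMERA)
    occ_rng = _rng(cfg.seed, _OCCLUSION)

    horizon_world = int(round(cfg.horizon_frac * H))
    heights = traj_rng.uniform(*cfg.target_height_range, size=cfg.n_targets)
    aspects = traj_rng.uniform(*cfg.aspect_range, size=cfg.n_targets)
    speeds = traj_rng.uniform(*cfg.speed_range, size=cfg.n_targets)
    headings = traj_rng.uniform(0.0, 2 * np.pi, size=cfg.n_targets)
    widths = heights * aspects
    # keep targets below the horizon and inside the frame
    y_lo = horizon_world + heights
    pos = np.column_stack(
        [
            traj_rng.uniform(widths, W - widths),
            traj_rng.uniform(y_lo, H - heights),
        ]
    )

    gt_world: dict[int, list[tuple[int, np.ndarray]]] = {}
    for f in range(1, cfg.n_frames + 1):
        if f > 1:
            headings = headings + traj_rng.normal(0.0, cfg.turn_rate_std, cfg.n_targets)
            step = np.column_stack([np.cos(headings), np.sin(headings)]) * speeds[:, None]
            pos = pos + step
            # reflect at the habitable band edges
            for k in range(cfg.n_targets):
                x, y = pos[k]
                if x < widths[k] or x > W - widths[k]:
                    headings[k] = np.pi - headings[k]
                    pos[k, 0] = np.clip(x, widths[k], W - widths[k])
                if y < y_lo[k] or y > H - heights[k]:
                    headings[k] = -headings[k]
                    pos[k, 1] = np.clip(y, y_lo[k], H - heights[k])
        gt_world[f] = [
            (
                tid + 1,
                np.array(
                    [
                        pos[tid, 0] - widths[tid] / 2.0,
                        pos[tid, 1] - heights[tid] / 2.0,
                        widths[tid],
                        heights[tid],
                    ]
                ),
            )
            for tid in range(cfg.n_targets)
        ]

    true_affines: dict[int, AffineMotion] = {1: AffineMotion.identity("ground_truth")}
    cumulative: dict[int, AffineMotion] = {1: AffineMotion.identity("ground_truth")}
    for f in range(2, cfg.n_frames + 1):
        A = _sample_frame_affine(cfg, cam_rng)
        true_affines[f] = A
        cumulative[f] = A.compose(cumulative[f - 1])

    gt_camera = {
        f: [(tid, _transform_box(box, cumulative[f])) for tid, box in boxes]
        for f, boxes in gt_world.items()
    }

    # occlusion episodes: memoryless starts, uniform integer durations
    occluded: dict[int, set[int]] = {f: set() for f in range(1, cfg.n_frames + 1)}
    for tid in range(1, cfg.n_targets + 1):
        remaining = 0
        for f in range(1, cfg.n_frames + 1):
            if remaining > 0:
                occluded[f].add(tid)
                remaining -= 1
            elif occ_rng.random() < cfg.occlusion_rate:
                lo, hi = cfg.occlusion_duration
                remaining = int(occ_rng.integers(lo, hi + 1)) - 1
                occluded[f].add(tid)

    horizon_rows = {}
    for f in range(1, cfg.n_frames + 1):
        p = cumulative[f].apply_point(np.array([W / 2.0, float(horizon_world)]))
        horizon_rows[f] = int(round(p[1]))

    scenario = Scenario(
        config=cfg,
        gt_world=gt_world,
        gt_camera=gt_camera,
        true_affines=true_affines,
        cumulative_affines=cumulative,
        occluded=occluded,
        horizon_world=horizon_world,
        horizon_rows=horizon_rows,
    )
    corrupt_detections(scenario, cfg)
    return scenario


def synthesize_descriptors(
    identity: int, cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Noisy unit descriptor for one identity.

    The anchor is a fixed random unit vector derived from (seed, identity);
    ``rng`` supplies the additive Gaussian noise (omit it for the clean
    anchor itself).
    """
    anchor_rng = _rng(cfg.seed, _DESCRIPTOR, identity)
    anchor = anchor_rng.normal(size=cfg.descriptor_dim)
    anchor /= np.linalg.norm(anchor)
    if rng is None or cfg.descriptor_noise_std == 0.0:
        return anchor
    # per-component std scaled by 1/sqrt(dim) so that noise_std is the
    # expected perturbation *magnitude* relative to the unit anchor,
    # independent of descriptor dimension
    sigma = cfg.descriptor_noise_std / np.sqrt(cfg.descriptor_dim)
    v = anchor + rng.normal(0.0, sigma, cfg.descriptor_dim)
    return v / np.linalg.norm(v)


def corrupt_detections(scenario: Scenario, cfg: ScenarioConfig) -> dict[int, list[Detection]]:
    """Derive detector output from the camera-coordinate ground truth.

    Visible targets score ``1 - |N(0, conf_noise_std)|``; occluded targets
    score near the configured confidence floor.  Boxes get Gaussian
    position/size jitter, targets are dropped at the miss rate, and
    Poisson-many false positives with low-to-medium confidences are added
    per frame.  Results are stored on the scenario and returned.
    """
    det_rng = _rng(cfg.seed, _DETNOISE)
    W, H = cfg.frame_size
    scenario.detections = {}
    scenario.det_labels = {}
    for f in sorted(scenario.gt_camera):
        dets: list[Detection] = []
        labels: list[int] = []
        for tid, box in scenario.gt_camera[f]:
            missed = det_rng.random() < cfg.miss_rate
            jitter = det_rng.normal(0.0, cfg.bbox_jitter_std, size=4)
            noise_mag = abs(det_rng.normal(0.0, cfg.conf_noise_std))
            if missed:
                continue
            b = box.copy()
            if cfg.bbox_jitter_std > 0:
                b[:2] += jitter[:2]
                b[2:] = np.maximum(1.0, b[2:] + 0.5 * jitter[2:])
            if tid in scenario.occluded[f]:
                conf = float(np.clip(cfg.occlusion_conf_floor + det_rng.normal(0.0, cfg.conf_noise_std), 0.0, 1.0))
            else:
                conf = float(np.clip(1.0 - noise_mag, 0.0, 1.0))
            descriptor = synthesize_descriptors(tid, cfg, det_rng)
            dets.append(Detection(box=b, confidence=conf, descriptor=descriptor))
            labels.append(tid)
        n_fp = det_rng.poisson(cfg.false_positive_rate)
        for _ in range(n_fp):
            h = det_rng.uniform(*cfg.target_height_range)
            w = h * det_rng.uniform(*cfg.aspect_range)
            l = det_rng.uniform(0.0, max(1.0, W - w))
            t = det_rng.uniform(0.0, max(1.0, H - h))
            conf = float(det_rng.uniform(cfg.occlusion_conf_floor, 0.6))
            v = det_rng.normal(size=cfg.descriptor_dim)
            v /= np.linalg.norm(v)
            dets.append(Detection(box=np.array([l, t, w, h]), confidence=conf, descriptor=v))
            labels.append(-1)
        scenario.detections[f] = dets
        scenario.det_labels[f] = labels
    return scenario.detections


def _value_noise(shape: tuple[int, int], rng: np.random.Generator, cell: int = 6) -> np.ndarray:
    """Ground-like texture in [0, 1]: smooth value noise plus fine grain
    and scattered dark/bright blobs (stones, shrubs) that anchor corners."""
    coarse = rng.random((shape[0] // cell + 2, shape[1] // cell + 2))
    up = np.kron(coarse, np.ones((cell, cell)))[: shape[0], : shape[1]]
    smooth = scipy.ndimage.gaussian_filter(up, sigma=cell / 2.0)
    fine = rng.random(shape)
    tex = 0.55 * smooth + 0.25 * scipy.ndimage.gaussian_filter(fine, 0.6) + 0.2 * fine
    n_blobs = max(20, shape[0] * shape[1] // 2500)
    ys = rng.integers(2, shape[0] - 2, n_blobs)
    xs = rng.integers(2, shape[1] - 2, n_blobs)
    vals = rng.choice([0.0, 1.0], n_blobs)
    sizes = rng.integers(2, 5, n_blobs)
    for y, x, v, sz in zip(ys, xs, vals, sizes):
        tex[y : y + sz, x : x + sz] = v
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def target_intensity(tid: int, n_targets: int) -> float:
    """Per-identity ellipse intensity, spaced for histogram separability."""
    levels = np.linspace(40.0, 250.0, max(2, n_targets))
    return float(levels[(tid - 1) % len(levels)])


def render_frames(scenario: Scenario, cfg: ScenarioConfig | None = None) -> dict[int, np.ndarray]:
    """Render grayscale frames consistent with the scene's ground truth.

    A static world canvas (dark above the horizon, textured below) is
    warped per frame by the cumulative camera affine; targets are drawn as
    filled ellipses at their camera-coordinate positions.
    """
    cfg = cfg or scenario.config
    W, H = cfg.frame_size
    pad = 80
    render_rng = _rng(cfg.seed, _RENDER)
    canvas = np.empty((H + 2 * pad, W + 2 * pad))
    texture = _value_noise(canvas.shape, render_rng)
    hz_row = scenario.horizon_world + pad
    canvas[:] = 80.0 + 120.0 * texture  # ground
    sky = 20.0 + 25.0 * texture[:hz_row]
    canvas[:hz_row] = sky

    yy, xx = np.mgrid[0:H, 0:W]
    frames: dict[int, np.ndarray] = {}
    for f in sorted(scenario.gt_camera):
        C = scenario.cumulative_affines[f]
        Minv = np.linalg.inv(C.M)
        tinv = -Minv @ C.T
        # affine_transform maps output (row, col) -> input coords
        matrix_rc = np.array(
            [[Minv[1, 1], Minv[1, 0]], [Minv[0, 1], Minv[0, 0]]]
        )
        offset_rc = np.array([tinv[1] + pad, tinv[0] + pad])
        frame = scipy.ndimage.affine_transform(
            canvas, matrix_rc, offset=offset_rc, output_shape=(H, W), order=1, mode="reflect"
        )
        for tid, box in scenario.gt_camera[f]:
            l, t, w, h = box
            cx, cy = l + w / 2.0, t + h / 2.0
            a, b = max(w / 2.0, 1.0), max(h / 2.0, 1.0)
            inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
            frame[inside] = target_intensity(tid, cfg.n_targets)
        frames[f] = np.clip(frame, 0.0, 255.0)
    scenario.frames = frames
    return frames


def scenario_digest(scenario: Scenario) -> str:
    """SHA-256 digest of the scenario's numerical content (determinism aid)."""
    hasher = hashlib.sha256()
    for f in sorted(scenario.gt_world):
        for tid, box in scenario.gt_world[f]:
            hasher.update(np.int64(tid).tobytes())
            hasher.update(np.asarray(box, dtype=np.float64).tobytes())
        for tid, box in scenario.gt_camera[f]:
            hasher.update(np.asarray(box, dtype=np.float64).tobytes())
        A = scenario.true_affines[f]
        hasher.update(A.M.astype(np.float64).tobytes())
        hasher.update(A.T.astype(np.float64).tobytes())
        for tid in sorted(scenario.occluded[f]):
            hasher.update(np.int64(tid).tobytes())
        for det in scenario.detections.get(f, []):
            hasher.update(det.box.astype(np.float64).tobytes())
            hasher.update(np.float64(det.confidence).tobytes())
            if det.descriptor is not None:
                hasher.update(det.descriptor.astype(np.float64).tobytes())
    for f in sorted(scenario.frames):
        hasher.update(np.asarray(scenario.frames[f], dtype=np.float64).tobytes())
    return hasher.hexdigest()
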