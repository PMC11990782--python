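# Methods

## Tracking model

### State and filter

Each track is a linear-Gaussian belief over the 8-vector
(x, y, γ, h, ẋ, ẏ, γ̇, ḣ): box centre (pixels), aspect ratio w/h
(dimensionless), box height (pixels), and their per-frame rates. The
motion model is constant-velocity with dt fixed at one frame; frame
timestamps are not modelled. γ is the aspect ratio by default; a
`gamma_mode="width"` switch interprets the third component as the raw
box width instead, for users whose detectors parameterise boxes that
way.

Noise follows the height-proportional convention: the position and size
components of the process noise have standard deviation
`std_weight_position · h` (default weight 1/20), velocities
`std_weight_velocity · h` (default 1/160), and the dimensionless aspect
component uses small fixed stds (1e-2 process, 1e-1 measurement, 1e-5
velocity). Track birth doubles the positional stds and multiplies the
velocity stds by 10, reflecting that velocity is unobserved at birth.
The covariance is re-symmetrised ((P + Pᵀ)/2) after every update to
suppress floating-point drift; a Cholesky failure in the innovation
solve raises an explicit numerical error rather than continuing
silently.

### Association

Costs: squared Mahalanobis distance in measurement space (motion), and
minimum cosine distance to a ring-buffer gallery of the last
`gallery_budget` (default 100) unit descriptors per track (appearance).
The blend weight λ defaults to 0 — appearance-driven cost with the
Mahalanobis term used purely as a gate — because under residual camera
motion the motion term is the less trustworthy of the two; any λ in
[0, 1] is accepted and applied exactly. The motion gate is the χ²
0.95 quantile at 4 dof (9.4877). When detections carry no descriptors at
all, the tracker falls back to pure motion cost (λ = 1) with a logged
warning, and the tier thresholds (which are appearance-scale distances)
are replaced by the motion gate alone.

Incoming descriptors that are not unit-norm are re-normalised with a
warning rather than rejected. Assignment is solved by
`scipy.optimize.linear_sum_assignment` over the finite entries (verified
against exhaustive permutation enumeration in the tests); infeasible
pairs are filled with a value large enough that the solver always
prefers maximal feasible cardinality. The solver is deterministic for
fixed inputs, which is what the pipeline's bit-level reproducibility
relies on; among exactly-tied optima it returns scipy's canonical
solution rather than an explicitly lexicographic one.

The matching cascade offers detections to track age groups in
increasing time-since-update order, so a track updated last frame always
outranks a stale one competing for the same detection. After the tiered
stages, a final IoU stage (max 1 − IoU = 0.7) re-associates tentative
and freshly lost tracks with leftover confident detections — without it,
a single missed gate on a manoeuvring target spawns a duplicate track
and an avoidable identity switch.

### Camera motion compensation

Pipeline per frame pair: horizon detection → static mask → FAST/BRIEF
keypoint matching → RANSAC affine → state warping.

- **Horizon.** The horizon row maximises the row-mean absolute vertical
  gradient. The gradient is the backward difference I[y] − I[y−1] (zero
  for the top row), which attributes a hard edge to the first row of the
  new region; ties break to the smallest row. Central differences would
  split an ideal step edge across two rows and shift the argmax up by
  one. Everything strictly above the horizon is masked out: in UAV
  grassland footage the stable reference is the ground texture below
  the horizon, not sky or far terrain (configurable via
  `use_horizon=False`).
- **Static mask.** Every detection box, dilated by 10 % of its size per
  side, is excluded so that moving animals never anchor keypoints. Each
  frame is masked with its own detections.
- **Keypoints.** FAST corners (threshold 0.08, up to 400 peaks) with
  256-bit BRIEF descriptors, matched by cross-checked nearest-neighbour
  search with a 0.75 ratio test, then a spatial filter discarding pairs
  displaced by more than 10 % of the frame diagonal. Grayscale
  conversion uses ITU-R BT.601 luma weights.
- **Affine.** A full 6-dof affine [M|T] is fitted by RANSAC (3 px
  reprojection threshold, 0.995 confidence, 500 trials max, seeded).
  With fewer than 8 pairs, a degenerate fit, or an
  orientation-reversing M, the module falls back to the identity
  transform — the tracker then degrades gracefully to its uncompensated
  behaviour for that frame.
- **Warping.** M is lifted to M̂ = diag(M, M, M, M) acting on the state
  pairwise — including the (γ, h) pair and both velocity pairs — and
  T̂ = (T, 0, …, 0); mean and covariance transform as x̂ ← M̂x̂ + T̂,
  P ← M̂PM̂ᵀ + Qₙ. Two deliberate toggles: `apply="position_only"`
  restricts M to the positional pairs and leaves (γ, h) untouched
  (the convention of some recent trackers; the pairwise-on-everything
  default follows the formulation this package implements), and
  `extra_process_noise=False` drops the additional Qₙ added at
  compensation time (the default adds it, on top of the Qₙ already
  added in predict). Compensation is applied to the *predicted* prior,
  before association.

### Confidence tiers

Boundaries default to τ_high = 0.6, τ_low = 0.3, τ_discard = 0.1 (all
bounds closed below, all configurable). Matching thresholds are distance
ceilings, stringent-to-lenient as confidence falls: 0.2 (high), 0.3
(medium) on the blended cost, and an IoU stage for the low tier with
minimum IoU 0.5 (cost ceiling 1 − IoU ≤ 0.5). The low tier uses overlap
only because occluded crops corrupt appearance; for the same reason
low-tier matches never push descriptors into the gallery, and low-tier
detections never initiate tracks. A low-tier match otherwise counts as a
full update (time-since-update resets to zero). Disabling COS
(`--no-cos`) yields the classic baseline: only detections at or above
τ_high participate, in a single cascade stage.

An adaptive threshold scheduler that would adjust tier criteria from
prior matching outcomes is deliberately not implemented; the tiers are
static per run.

### Lifecycle

Tracks are born tentative from unmatched high-tier detections and
confirm after `n_init` = 3 consecutive hits (with `n_init` = 1 they are
born confirmed). Unmatched tentative tracks are deleted immediately;
unmatched confirmed tracks become "missing" but remain in the
association pool — reactivation is simply the cascade matching them
again, under their original identity — until `max_age` = 30 frames
without an update, after which they are deleted. Identifiers are
positive integers, strictly increasing, never reused within a run. Only
confirmed tracks matched in the current frame are emitted.

## CARAFE reassembly

The operator is channel-count-agnostic and takes kernel logits as data
(the kernel-prediction convolution is a learned component and out of
scope). Logits are softmax-normalised over the k_up² tap axis, so each
output location owns a convex weight vector; the output at location ℓ is
the weighted sum of the k_up × k_up source neighbourhood centred at
⌊ℓ/σ⌋ (floor mapping: each σ×σ output block shares one source centre),
identically per channel. Borders are zero-padded, so constant inputs are
preserved exactly only at interior outputs whose neighbourhoods avoid
the pad — the tests assert exactly that. Defaults k_up = 5, σ = 2.

## Evaluation metrics

CLEAR matching per frame: correspondences from previous frames persist
while their IoU stays ≥ the threshold (default 0.5); the remainder is
matched by Hungarian assignment on 1 − IoU with pairs below threshold
forbidden. An identity switch is counted when a ground-truth identity's
matched prediction differs from its last known correspondence, which
persists across gaps. MOTA = 1 − (ΣFN + ΣFP + ΣIDSW)/ΣGT. The per-match
distance in MOTP is taken as IoU, making MOTP a higher-is-better score
(mean matched IoU) — the convention under which values near 80 % are
reported for this kind of footage; a centre-distance reading would
invert the scale. IDF1 maximises frame-level overlaps over a single
global bipartite trajectory pairing (Hungarian on the overlap-count
matrix; equivalent to the min-cost formulation because unmatched
pairings contribute zero credit). AP uses all-point interpolation (area
under the monotone precision envelope), each ground-truth box creditable
once, greedy best-IoU matching in confidence-descending order; mAP
averages per-class APs, excluding classes with no ground truth.

## Synthetic scenes

The generator emulates the statistical structure of UAV herd footage,
not its appearance. Default study conditions, chosen once as a
desk-scale analogue of the real setting: 320×240 frames, 60 frames, 6
targets of height 14–24 px moving 1–3 px/frame along correlated random
walks (heading noise σ = 0.15 rad/frame, reflecting at the frame
edges); per-frame camera jitter of σ = 4 px translation, 0.5°
rotation and 0.5 % zoom about the frame centre, composed into a
cumulative world→camera affine that is the exact ground truth for the
compensation module; occlusion as scheduled episodes (start rate
0.02/target/frame, duration 5–15 frames) during which detector
confidence drops to a floor of 0.15 — below the low-tier boundary —
rather than as geometric overlap, so occlusion ground truth is exact
and tier outcomes controllable; detection corruption with 5 % misses,
1 px box jitter, 0.5 false positives/frame (confidence 0.15–0.6, so
they never seed tracks), and confidence noise σ = 0.05 on visible
targets (score 1 − |N(0, σ)|).

Appearance descriptors are per-identity fixed random unit anchors plus
Gaussian noise re-normalised to the sphere; the noise parameter (default
0.1) is the expected *magnitude* of the perturbation (per-component
std = noise/√dim), so within-identity cosine distances (~noise²/2) are
dimension-independent and far below cross-identity distances (~1).
Rendered frames place value-noise ground texture with scattered
high-contrast blobs below a dark sky at a known horizon row, warp the
world canvas by the cumulative affine, and draw targets as filled
ellipses with per-identity intensities spaced widely enough for the
patch-histogram embedder to separate.

Random streams are split per component (trajectories / camera /
occlusion / detection noise / descriptors / rendering) from the single
scenario seed, so toggling one noise source never perturbs the others —
essential for clean one-factor ablations.

What the generator does *not* model — perspective and terrain parallax
(the background motion is exactly affine, so compensation can in
principle be exact), appearance drift with pose and lighting, detector-
correlated failure modes, geometric occlusion between specific animals,
and animal behaviour (herding, flight responses). Passing ablations
therefore show that each component does its job *when the scene matches
its assumptions*; they do not quantify performance on real footage.

## Experiments and the acceptance script

`uavtrack.experiments` runs the two one-factor studies used by
`scripts/acceptance.py` and the test suite. The compensation study uses
the default conditions above (jitter on) over 20 seeded scenarios,
tracking each with and without CMC (frames rendered only for the
compensated arm; the ablated arm sees identical detections). The tier
study isolates occlusion: static camera, episode rate raised to 0.04 so
every target is occluded roughly twice per clip, tracker run with and
without COS. The perfect-input check uses a noiseless scene with
`n_init` = 1 (immediate confirmation), since any warm-up frames would
register as misses against ground truth that starts at frame 1. Problem
sizes (20 scenarios per study, 60-frame clips, 5-scenario headline
average) are the package's chosen desk-scale study conditions.

## Known limitations

- The affine background model ignores parallax; strong perspective or
  3-D structure would need a homography or dense flow, both out of
  scope.
- The patch-histogram embedder is a deterministic stand-in for a learned
  re-identification network: adequate to separate the generator's
  palette and to exercise the gallery machinery, far weaker than a CNN
  on real animals.
- MOTP-as-IoU and all-point AP are documented interpretations where the
  metric definitions admit variants.
- Tier thresholds are static; no adaptive scheduling.
- Single camera, single class, online (no global/offline association).
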