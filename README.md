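# uavtrack

Multi-object tracking of wild ungulates in UAV (drone) video.

Monitoring endangered herding species such as Przewalski's gazelle
(*Procapra przewalskii*) from a drone means following many
similar-looking animals through footage where the *camera itself* is
moving — the aircraft translates, yaws and changes altitude while it
follows the herd — and where animals repeatedly occlude one another, so
detector confidence collapses exactly when identity is hardest to keep.
`uavtrack` implements a tracking-by-detection pipeline built for this
regime, plus the evaluation metrics and a seeded synthetic-scene
simulator so every component can be validated end to end without field
data.

## The method

Per-frame detections (boxes + confidences, optionally with appearance
descriptors) are associated to tracks by a Deep-SORT-style tracker with
two extensions:

**Kalman motion model.** Each track carries an 8-D state
(x, y, γ, h, ẋ, ẏ, γ̇, ḣ) — box centre, aspect ratio, height and their
per-frame velocities — filtered by a constant-velocity Kalman filter
whose process/measurement noise scales with box height. Motion
similarity is the squared Mahalanobis distance
d¹ᵢⱼ = (dⱼ − yᵢ)ᵀ Sᵢ⁻¹ (dⱼ − yᵢ) between a detection and a track's
predicted measurement distribution; appearance similarity is the minimum
cosine distance d²ᵢⱼ = min(1 − rⱼᵀrₖ) over a per-track gallery of recent
unit descriptors. The association cost is the blend
cᵢⱼ = λ·d¹ᵢⱼ + (1 − λ)·d²ᵢⱼ, gated by the χ²(4) 0.95 quantile on motion,
and solved by the Hungarian algorithm in an age-ordered matching cascade.

**Camera motion compensation (CMC).** Between consecutive frames the
global background motion is estimated as an affine transform [M|T]:
the horizon is located as the row of maximal mean absolute vertical
gradient, detected animals and the sky are masked out, FAST corners with
BRIEF descriptors are matched (ratio test + spatial-distance filter) and
RANSAC fits the affine. Every predicted track state is then warped,
x̂ ← M̂x̂ + T̂ and P ← M̂PM̂ᵀ + Q, with M̂ = diag(M, M, M, M) acting on the
state pairwise, so camera motion never masquerades as target motion.

**Confidence-tiered association (COS).** Detections are stratified into
high / medium / low confidence tiers. High-confidence boxes are matched
first under a stringent threshold, medium next under a relaxed one, and
low-confidence boxes — usually occluded animals — are matched last, by
predicted-box IoU only (their appearance is untrustworthy), and never
start new tracks or pollute descriptor galleries. This recovers targets
through occlusion episodes instead of dropping them.

The package also provides the CARAFE content-aware feature-reassembly
operator (softmax-normalised per-location kernels applied to source
neighbourhoods at upsampling factor σ) as a standalone numeric operator,
and the standard evaluation suite: CLEAR-MOT (MOTA, MOTP, FP, FN, ID
switches), identity F1 (IDF1) and detection AP/mAP.

## Worked example

Simulate a 60-frame scene of six animals under camera jitter and
occlusion, track it, and score it:

```bash
uavtrack simulate --config cfg.yaml --out scene --seed 7
uavtrack track --det scene/det.txt --descriptors scene/descriptors.csv \
               --frames scene/frames --config cfg.yaml --out results.txt --seed 7
uavtrack evaluate --gt scene/gt.txt --results results.txt
```

with `cfg.yaml` containing:

```yaml
seed: 7
scenario:
  n_targets: 6
  n_frames: 60
```

prints:

```
  MOTA:   80.8 %
  MOTP:   82.7 %
  IDF1:   70.7 %
    FP:      0
    FN:     61
   IDs:      8
    GT:    360
```

MOTA is 1 − (FN + FP + IDs)/GT: of 360 ground-truth boxes, 61 were
missed (mostly track warm-up and occlusions), none were false alarms,
and identity switched 8 times. MOTP 82.7 % is the mean IoU of matched
boxes; IDF1 70.7 % is the identity-level F1 of the globally best
trajectory pairing. Re-running with `--no-cmc` drops MOTA to 54.2 % and
IDF1 to 37.4 % with 34 switches — the cost of leaving camera motion
uncompensated on the same scene.

The same pipeline runs on real data: `--det` takes a MOTChallenge det
CSV, `--frames` a directory of per-frame images (000001.png, ...), and
`--descriptors` an optional sidecar CSV of unit appearance vectors; when
frames are given but descriptors are not, a deterministic patch-histogram
embedder stands in for a learned re-identification network.

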