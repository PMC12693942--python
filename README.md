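# aqa — unsupervised skeleton-based action quality assessment

`aqa` scores how well a recorded execution of a slow, whole-body exercise
(qigong-style routines, physiotherapy movements, calisthenics) matches a
standard "template" execution, using only 3D skeletal keypoints — no score
annotations, no trained scoring model. It is aimed at movement-science and
sports-education practitioners who already run a pose-estimation stack and
need an objective, explainable 0–100 score per clip.

## Method

The input is a sequence of `n` frames, each holding 17 named 3D keypoints
in the Human3.6M-style convention (hip midpoint, spine chain, arms, legs).
Three stages produce the score:

1. **Kinematic features.** Every frame becomes a 27-dimensional angle
   vector `F = [θ₁…θ₁₁, P₁…P₄, α₁…α₄, β₁…β₄, γ₁…γ₄]`: eleven joint angles
   at named triples (`θ = arccos(v₁·v₂ / |v₁||v₂|)`), four limb-block
   angles against the spine vector from a hip reference (`P`) and a neck
   reference (`α`), body-orientation and opening features (`β`, with the
   forward-facing direction mapped to 1.5π and the reverse to 0.5π), and
   four contralateral forearm/shank angles (`γ`). Angles make the features
   translation-invariant and unit-agnostic.

2. **Acceleration anomaly detection.** For each of 14 retained keypoints
   the per-frame acceleration `a(i) = ‖x(i+2) − x(i)‖ · fps²` is clustered
   with DBSCAN, whose radius ε is chosen per keypoint at the maximum slope
   change of the sorted k-distance graph. Template and test outlier totals
   `o₁, o₂` are compared through `r = |o₁ − o₂| / o₁` and binned into a
   threshold coefficient `t ∈ {1, 0.2, 0.15, 0.1}`; `r = 0` (identical
   outlier distributions — suspected copying of the template) gives
   `t = 1`, which zeroes the score.

3. **QAQA alignment and scoring.** Template and test feature sequences are
   aligned by an adaptive-penalty DTW

   `ACDTW(i,j) = MED(i,j) + min(ACDTW(i−1,j−1), ACDTW(i−1,j) + C·MED(i,j),
   ACDTW(i,j−1) + C·MED(i,j))`, `C = 2·max(a,b)/(a+b)`,

   run multi-resolution: coarsen by averaging adjacent frame pairs, align
   at low resolution, project the warp path up and refine inside a window
   dilated by `radius` cells. Evaluated cells grow linearly in `n` instead
   of quadratically. Along the final path each pair gets a divergence
   `q = ‖F_test − F_temp‖₁ / ‖F_test‖₁` and a frame score (full marks for
   `q ≤ t`, linear penalty `100·(1 − q + t)` for `t < q ≤ 1`, zero beyond);
   the final score is the mean.

A synthetic-motion module generates rigid-skeleton exercise clips with
controllable time warps, amplitude errors, jitter, acceleration spikes and
dropout, so the whole pipeline is testable with known ground truth.

## Worked example

```python
from aqa import QAQAScorer, generate_template, perturb, PerturbationSpec

template = generate_template(n_frames=150, fps=30, motion_preset="reach", seed=7)
test, truth = perturb(template, PerturbationSpec(
    time_warp_strength=0.3, noise_sd=0.004, n_spikes=4, seed=8))

scorer = QAQAScorer(radius=10, anomaly=True).fit(template)
report = scorer.assess(test)
print(f"threshold coefficient t : {report['t']}")
print(f"outlier totals          : o1={report['o1']} (template), o2={report['o2']} (test)")
print(f"final score             : {report['final']:.2f} / 100")
print(f"cells computed          : {report['cells_computed']} (full matrix: {150*150})")
```

prints

```
threshold coefficient t : 0.1
outlier totals          : o1=148 (template), o2=15 (test)
final score             : 99.98 / 100
cells computed          : 10200 (full matrix: 22500)
```

The test clip is the same movement re-timed with mild sensor noise and four
injected tracking glitches, so it still scores near full marks, but the
outlier-count discrepancy tightens the tolerance to `t = 0.1` and the
windowed alignment evaluates under half the cost cells of the full matrix.
Scoring the template against an exact copy of itself instead returns
`t = 1` and a score of 0 — identical outlier distributions are treated as
suspected cheating.

The same pipeline is scriptable from the shell:

```sh
aqa simulate --scenario warped --n-frames 150 --seed 7 --out-dir pair/
aqa score --template pair/template.json --test pair/test.json --radius 10 --anomaly on
aqa detect-anomalies --template pair/template.json --test pair/test.json
aqa bench --lengths 128,256,512 --radii 2,5,10 --out bench.csv
```

Keypoint files are plain JSON (`{"fps": 30, "convention": "h36m17",
"frames": [[[x,y,z] × 17], …]}`, missing keypoint = `null`) or long-format
CSV (`frame,kp,x,y,z` with an fps sidecar).

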