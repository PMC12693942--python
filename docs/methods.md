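# Methods

This note documents the models, conventions and design choices behind the
package: what is computed, which parameters matter, what the synthetic
generator does and does not emulate, and where genuinely open design
questions were settled.

## Skeleton convention and input contract

Sequences hold `n ≥ 3` frames of 17 keypoints (Human3.6M-style indexing:
0 hip midpoint, 1–3 right leg, 4–6 left leg, 7 spine, 8 thorax, 9 neck,
10 head, 11–13 left arm, 14–16 right arm) at a frame rate `fps > 0`.
Coordinates are unit-agnostic: every downstream feature is an angle or a
ratio of distances, and outlier detection is scale-relative, so metres,
millimetres or normalized units all behave identically. A missing keypoint
is an explicit NaN triple; feature construction imputes it by
previous-frame carry-forward (configurable, on by default) because the
scoring stage handles quality degradation through the anomaly coefficient,
not through interpolation quality. Axis convention (used by the generator
and the orientation features): z up, the canonical subject faces +y.

## Kinematic features (27 per frame)

* **Joint angles θ₁…θ₁₁.** Each is the angle at a vertex keypoint between
  the vectors to two neighbouring keypoints, with the dot product clamped
  to [−1, 1] before `arccos`. The triple table places the vertex at the
  anatomical hinge of each listed triple (neck, hip midpoint or thorax for
  the axial rows; the elbow and knee for the limb rows), so a straight
  limb reads π and a right-angle bend reads π/2. The table is exposed as
  `JOINT_ANGLE_TRIPLES` and overridable per call.
* **Limb-block angles P₁…P₄ and α₁…α₄.** Four 4-keypoint blocks (two arms,
  two legs; index sets kept exactly as published even though the printed
  "left arm" uses right-side indices — the map is configurable) are
  reduced to their coordinate mean `p₀`. With spine vector `M` = hip →
  thorax, `P = ∠(M, hip → p₀)` and `α = ∠(M, neck → p₀)`. The split into
  two reference points (hip for `P`, neck for `α`) is a design decision:
  the source material defines one centre-point angle but counts eight
  features, and 11 + 4 + 4 + 4 + 4 is the only decomposition consistent
  with the stated 27 dimensions.
* **Orientation/opening β₁…β₄.** The shoulder line (11→14) and hip line
  (4→1), both taken left→right, define a facing normal `up × line`
  projected to the horizontal plane; `β = (1.5π − signed∠(forward,
  facing)) mod 2π`, anchoring forward = 1.5π and reverse = 0.5π with a
  configurable forward axis (default +y). β₃ = 1.5π iff the feet are
  strictly more than 0.5 shoulder-widths apart, β₄ = 1.5π iff the wrists
  are strictly more than 1.5 shoulder-widths apart, else 0.5π — strict
  inequalities exactly as published.
* **Contralateral angles γ₁…γ₄.** Angles between forearm and shank
  direction vectors: the two published same-side pairs (15→16 vs 2→3,
  12→13 vs 5→6) plus the two cross-side completions, since only two of the
  four pairs are enumerated in the source.

Degenerate geometry (coincident keypoints, zero-length facing projection)
yields NaN for that feature, which is then carried forward from the
previous frame (first frame: 0 with a warning). This keeps NaN out of the
alignment cost matrix at the cost of slightly stale values in pathological
frames.

## Acceleration anomaly detection

`a(i) = ‖x(i+2) − x(i)‖ / Δt²` with `Δt = 1/fps` treats each two-frame span
as uniform motion; the series has length `n − 2` and is non-negative. The
hip midpoint, spine and thorax are excluded (near-stationary in slow
exercise), leaving 14 keypoints that are analysed independently — motion
ranges differ by an order of magnitude between, say, wrist and hip, so a
shared DBSCAN radius would be wrong for most joints.

Per keypoint and sequence: the k-distance graph (k = `min_sample`,
default 5 — a standard DBSCAN heuristic; the source never states it) is
sorted ascending and ε taken at the maximum consecutive difference (ties:
smallest index; flat graph: the common value, with a warning). DBSCAN
with (ε, `min_sample`) labels noise points; counts are summed across
keypoints into o₁ (template) and o₂ (test). Clustering is done on raw 1-D
acceleration values by default; a 2-D (normalized time, value) embedding
is available behind `clustering_space` for shift-sensitive analyses.

The threshold coefficient follows the published bins on
`r = |o₁ − o₂|/o₁` (1 / 0.2 / 0.15 / 0.1 for r = 0 / ≤0.3 / ≤0.5 / >0.5),
configurable via `bins`/`t_values`. An outlier-free template leaves `r`
undefined; we define r = 0 when the test is also clean (preserving the
anti-cheat clause) and take the strictest bin (t = 0.1) otherwise.

On *noise-free* synthetic templates the absolute outlier totals are
governed by the elbow rule's granularity on smooth series and can be
large; only the relative discrepancy `r` enters the score, so this does
not affect behaviour, but absolute counts should not be interpreted as
glitch counts the way they can be on real, noisy capture.

## Alignment

`MED` is the Euclidean distance between 27-D feature frames (Manhattan
behind `distance_metric`). The ACDTW recursion penalises vertical and
horizontal steps by `C·MED(i,j)` with the constant `C = 2·max(a,b)/(a+b)`
(≥ 1, equal to 1 for equal lengths). A match-count variant in which the
penalty grows with the run length of repeated matches is available behind
`acdtw(..., penalty="adaptive")` for comparison; the constant form is the
default and the one used by the scorer. Backtracking prefers diagonal,
then vertical, then horizontal on exact ties, minimising singularities and
making paths deterministic.

QAQA recursion: sequences are coarsened by averaging adjacent frame pairs
(odd trailing frame kept) until either length is ≤ `min_size` (default
`radius + 2`, the usual multi-resolution base case), aligned with full
ACDTW there, and refined upward: each coarse path cell maps to its 2×2
block, the block set is dilated by `radius` cells (Chebyshev) and clipped,
and window-restricted ACDTW runs at the finer level. `C` is recomputed
from the lengths at each level. Windows are stored as per-row column
ranges, so refined-level memory is proportional to evaluated cells; the
dense base case and full-matrix fallback use O(a·b). `cells_computed`
counts exactly the evaluated cost cells and is the hardware-independent
complexity measure used in tests; wall-clock times are reported by the
benchmark harness but never asserted. With `radius ≥ max(a,b)` the window
saturates and QAQA is exactly full ACDTW (identical distance and path).
`radius = 10` is the accuracy/cost sweet spot reported for this method
and the package default.

## Scoring

`q = ‖F_test − F_temp‖₁ / ‖F_test‖₁` aggregates the 27 features into one
relative divergence (the printed form is a scalar ratio; the ratio of L1
norms is its natural vector extension and is robust to single near-zero
features — a per-feature mean-of-ratios is available behind
`divergence_mode`). The test frame normalises, as published. `q` is
well-defined for any valid pose because β features are ≥ 0.5π. The frame
score is `base` for `q ≤ t`, `base·(1 − q + t)` for `t < q ≤ 1`, and 0 for
`q > 1` or `t = 1`, clamped at 0; `base = 100` gives the familiar 0–100
scale. The final score is the mean over the warp path. When the anomaly
module is off, `t = 0.2` (the mildest non-cheat bin) is used — the
module-off rows of the source's ablations do not state their t.

## Synthetic motion generator

Forward kinematics over a fixed-bone-length tree (pelvis root, spine
chain, arms from the thorax, legs from the pelvis; adult average segment
lengths in metres) driven by slow sinusoidal joint angles (0.08–0.2 Hz)
in three presets: `reach` (arm raises), `squat` (hip/knee flexion), `flow`
(asymmetric twisting). Defaults — 150 frames at 30 fps — represent a 5 s
consumer-camera clip. The seed jitters amplitudes and phases ±10%, giving
distinct executions of the same movement.

Perturbations apply in a fixed order: monotone time warp (smooth
reparameterization, strength < 1 guarantees monotonicity), amplitude
scaling about the mean pose, Gaussian coordinate jitter, spike injection,
dropout. Spikes displace one keypoint in isolated frames (≥ 4 frames
apart) by `spike_magnitude` (default 10×) times the keypoint's clean
acceleration maximum, converted to a displacement; individual sizes are
jittered uniformly in [1.0, 1.5]× because identical-size spikes would form
a dense value cluster of their own once `2·n_spikes ≥ min_sample` and
evade density-based detection — real glitches vary. All injected sites and
the true warp are returned as ground truth.

What the generator does **not** emulate: soft-tissue and footwear
artifacts, camera-projection error structure (depth-dependent,
anisotropic), correlated multi-joint occlusions, inter-subject
anthropometric variation, and genuinely different *styles* of correct
execution. Passing tests therefore demonstrate algorithmic correctness
and the intended qualitative behaviour (anti-cheat, spike recovery,
score ordering, linear scaling), not score agreement with human expert
ratings on real video — that requires a rated dataset, which is out of
scope here.

## Numerical choices and edge cases

* Dot products are clamped to [−1, 1] before `arccos`.
* ε = 0 (duplicate-heavy series) is mapped to the smallest positive float
  so exact duplicates still cluster under scikit-learn's positive-ε
  requirement.
* Alignment of empty sequences, windows not containing (1,1)/(a,b), and
  empty warp paths are errors, not silent fallbacks.
* The windowed and full dynamic programs use identical arithmetic
  expressions and tie rules, so a saturated window reproduces the full
  result bit-for-bit.
* Spearman correlation uses average ranks for ties (the rank-difference
  formula assumes none).
* Benchmark problem sizes in the test suite and acceptance script (small
  brute-force instances ≤ 8 frames, 50 reduction pairs ≤ 64, scaling runs
  to n = 4096, recall over 10 seeds × 5 spikes) are chosen so the whole
  suite completes in well under a minute on one CPU while still spanning
  a 32× length range for the scaling fit.

## Known limitations

* The anomaly coefficient is a global per-clip scalar; localized glitches
  tighten scoring everywhere rather than at the affected frames.
* The anti-cheat rule (`o₁ = o₂ ⇒ t = 1`) is exact-equality based and will
  zero genuinely honest tests whose outlier totals happen to tie the
  template's, which becomes more likely for very short clips.
* Orientation features assume the subject is roughly upright; a prone
  subject makes the horizontal facing projection degenerate (handled by
  carry-forward, but uninformative).
* The published block index sets mix left/right labels; they are kept
  verbatim for fidelity and configurability rather than "corrected".
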