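# Methods

## The counting problem and the model

`budcount` counts objects (tea buds) that drift through the field of view of
a camera carried at uniform walking speed along a crop row. The count must
be once-per-object although each object is visible for tens of frames, the
detector occasionally misses it, and clutter detections appear and vanish.
The package solves this with a SORT-family tracker — a linear
constant-velocity Kalman filter per object, Hungarian IoU association, and
a hit/miss lifecycle — feeding a cross-line counter.

### Kalman state model

Each track's state is the 8-vector `(cx, cy, a, h, v_cx, v_cy, v_a, v_h)`:
box center (px), width/height aspect ratio (dimensionless), height (px),
and their per-frame velocities. The transition is the identity plus a unit
coupling of position to velocity (one frame per step; no wall-clock time is
modelled, because at video frame rates the inter-frame displacement is small
and effectively linear in time). The observation selects `(cx, cy, a, h)`
from the state — the measured box.

The filter's only free parameters are the noise magnitudes, expressed as
multiples of the box height so near (large) and far (small) objects are
filtered with comparable relative uncertainty:

| parameter | default | meaning |
| --- | --- | --- |
| `position_scale` | 1/20 | std of position-like process and measurement noise, × height |
| `velocity_scale` | 1/80 | std of velocity process noise, × height |
| `aspect_sigma` | 1e-2 | fixed noise floor for the aspect ratio |
| `aspect_vel_sigma` | 1e-5 | fixed noise floor for the aspect velocity |

`velocity_scale = 1/80` is twice the value conventional in pedestrian
tracking. The scene flow of a steadily advancing camera is fast (~10
px/frame at the defaults) and genuinely constant, so the filter is tuned to
lock onto a constant velocity quickly: with this setting the one-step-ahead
predicted center of a noiseless constant-velocity track is within 1 px of
truth after five predict/update cycles for flows up to ~15 px/frame. At
birth a track's velocity is zero with inflated velocity variance (10× the
velocity noise std), so the first few updates transfer the observed
displacement into the velocity estimate.

Numerical safeguards: the posterior covariance is symmetrised after every
update, and the aspect and height components of the mean are floored at
1e-3 and 1 px (with their velocities zeroed when the floor engages) so that
a long-coasting track whose size velocity went negative cannot predict a
degenerate box.

### Association

Tracker predictions and detections are paired by minimum-cost bipartite
assignment (`scipy.optimize.linear_sum_assignment`) on cost `1 − IoU`.
Boxes are half-open intervals `[x1, x2) × [y1, y2)`, so edge-sharing boxes
have IoU 0. Two gating layers apply: pairs with IoU exactly 0 are pre-masked
to an effectively infinite cost (disjoint boxes can never be forced together
by the global optimum), and after assignment any pair with IoU below the
gate (default 0.3) is demoted to unmatched on both sides. Gating after
assignment keeps the assignment itself globally optimal; the demotion then
removes pairs too weak to be credible. Ties between equal-cost optima are
broken deterministically toward the lexicographically smallest (track,
detection) index pairs via an index-ordered cost perturbation of magnitude
~1e-10 — far below any meaningful IoU difference.

### Lifecycle

Per frame, in order: predict all tracks; discard detections below the
confidence floor (default 0.25) or with centers still inside the entering
area; associate; update matched tracks (miss counter reset, hit count +1);
spawn a track per unmatched detection; increment the miss counter of
unmatched tracks, which coast on their prediction (the Kalman prediction is
the only position estimate available during a dropout); remove tracks whose
miss counter reached `max_misses`.

* `max_misses = 5` (miss threshold): a track survives up to 4 consecutive
  detector dropouts. Larger values bridge longer occlusions but keep stale
  clutter tracks alive longer.
* `min_hits = 3` (validity threshold): a count event is valid only when the
  track's cumulative matched frames *strictly exceed* this value, i.e. from
  the 4th matched frame on. Single-frame false positives die with 1 hit and
  are never counted; at the default scene flow a real bud accumulates ~30
  hits before reaching the baseline.

Both thresholds define roles, not magic numbers; they are configurable. A
bud lost longer than the miss threshold and re-detected later gets a new
identity — re-identification is out of scope, and such a bud can be counted
twice by design (the entering/counting-area split exists to make this rare).

### Zones and cross-line counting

Two horizontal lines split the image: the entering limit at
`entering_fraction × H` (default 0.25) and the counting baseline at
`baseline_fraction × H` (default 0.75). Detections in the entering area
(top of the image, where a tilted camera distorts the view at the frame
edge) are invisible to the tracker; objects are tracked only after their
center passes the entering limit. A count fires the first time a valid
track's center satisfies `prev_y < baseline ≤ curr_y` (strict/non-strict
chosen so a center parked exactly on the line can never fire twice). Flow
direction is downward in image coordinates by default; `invert_flow`
mirrors both zones and the crossing direction for walks the other way.
Crossings against the flow direction are never counted, and each track id
counts at most once, enforced by a counted flag plus a counted-id set.

## The synthetic camera-scan simulator

The simulator emulates the survey geometry the tracker is designed for: a
hand-held camera tilted ~45° downward, carried at ~0.15 m/s along a ~1.5 m
ridge, yielding 960×608 frames in which the scene scrolls downward at a
constant rate. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| image | 960 × 608 px | the working crop size of the detector this pairs with |
| `camera_speed` | 10 px/frame | ~0.15 m/s at ~30 fps with ~0.3 m of ground per frame height |
| `n_frames` | 300 | a ~10 s segment ≈ 1.5 m of ridge at walking speed |
| `mean_instances_per_frame` | 14.6 | the measured mean bud density per frame in field imagery |
| bud width, height | 45 ± 10, 60 ± 12 px | plausible bud scale at 30–50 cm range; truncated at 2 SD below the mean (a pickable bud has a bounded minimum size, and the far-left normal tail is unphysical) |
| `miss_probability`, `false_positives_per_frame`, jitter | 0 | noise off unless asked for |

Objects are placed by a homogeneous Poisson process along the virtual strip
with linear intensity `mean_instances_per_frame / H`, so at stationarity the
expected number of visible centers per frame equals the configured mean.
At frame 0 the strip is populated only above the entering limit — the scene
"scrolls in" as in a real walk-up — so every object passes through the
entering area before it can reach the baseline and the tracker can
accumulate enough hits for a valid count. The stationary density is reached
after the ~(H − entering limit)/speed ≈ 46-frame burn-in, and density checks
in the test suite measure post-burn-in frames. Trajectories are exactly
linear in frame index: the constant-velocity assumption is true by
construction, which is what makes the noiseless benchmark a sharp
correctness oracle rather than a robustness exercise.

Detector corruption is a pure function of the scene and never alters the
ground truth: each true box is dropped independently with
`miss_probability`; survivors get Gaussian center jitter and multiplicative
size jitter; false positives (uniform position, 10–60 px, confidence
0.1–0.6 vs 0.6–0.98 for true boxes) arrive per frame at a Poisson rate and
live one frame. The true crossing count — the number of objects whose
center passes the baseline between two consecutive visible frames — is
computed from the clean scene and is invariant to every noise parameter.

What the simulator does *not* model: perspective and parallax (camera
motion is pure translation), appearance, correlated misses (e.g. a bud
missed for many consecutive frames due to occlusion or over-exposure),
detection failures that depend on brightness, and wind-induced plant
motion. Passing the simulated benchmarks therefore demonstrates that the
tracking/counting logic is correct and robust to independent per-frame
detector noise; it does not certify accuracy on real field video, where
correlated failure modes dominate.

## Benchmarks and evaluation

`make_benchmark` builds a set of independent videos (default 21, mirroring
an evaluation on segments cut from a longer survey), each with its own
derived seed and mild ±20% length and density variation. One master seed
drives everything through fixed substream offsets (scene geometry, detector
noise, benchmark variation), so each component is independently
reproducible and reruns are bit-identical.

Counts are scored by per-video error (`predicted − true`; overcount
positive), MAE, the fraction of videos with `|error| ≤ k`, and the R² of an
ordinary least-squares regression of predicted on true counts (with
intercept; for simple linear regression this equals the squared Pearson
correlation, so the two common conventions coincide). R² requires at least
3 pairs and a non-constant truth vector and errors out otherwise.

Measured under the default conditions (`scripts/acceptance.py --seed 1`,
21 videos of ~300 frames): noiseless MAE 0 and R² exactly 1; with 10%
misses, 0.5 false positives/frame and 2 px jitter, MAE ≈ 0.05 and
R² ≈ 0.9997, with 100% of videos within ±6 counts. The problem sizes (21
videos, ~300 frames, ~14.6 objects/frame) are the package's standard
benchmark configuration.

## Design choices where the design was open

* **Coordinates.** Continuous pixels, origin top-left, y downward,
  half-open boxes — the common detection-format convention. Degenerate
  boxes are rejected at construction, not silently given IoU 0.
* **Hits count matched frames, not age.** "Supported existence" is the
  stricter reading and is what makes the validity threshold reject clutter;
  a mere-age reading would validate any track that survives long enough
  while unmatched.
* **Entering-area rule discards detections before association** (not just
  birth suppression): objects in the entering area are invisible to the
  tracker entirely, matching the rule that boxes there are neither tracked
  nor counted.
* **Validity is strict** (`hits > min_hits`); a ≥ semantics is available by
  configuring `min_hits − 1`.
* **One-directional counting.** Crossings are counted along the flow
  direction only; a bud oscillating across the line (e.g. from jitter)
  cannot produce net double counts, and the counted flag makes re-crossing
  immaterial anyway.
* **Counting while coasting is allowed.** A track that crosses the baseline
  on a predicted (unmatched) frame still counts if valid: the prediction is
  the best available position during a dropout, and refusing such counts
  would systematically undercount under detector noise.

## Known limitations

* Counting accuracy inherits every upstream detection failure the noise
  model does not represent (systematic misses for small/over-exposed buds,
  duplicate boxes on one bud).
* A track that dies and is re-detected after the miss threshold is a new
  identity and can recross the baseline; only the zone layout limits this.
* The evaluation's R² is computed across videos; with few videos of similar
  true counts it is an unstable summary (the MAE and error fractions are
  the more robust numbers).
* The CLI's YOLO dialect derives frame indices from file-name digits; exotic
  naming schemes need renaming first.
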