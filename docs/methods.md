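# Methods

`eyehand` is an offline measurement pipeline for eye–hand coordination in a
seated AR stamping task, aimed at behavioral markers of unilateral spatial
neglect (USN). This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data does and does not
emulate.

## Task and coordinate conventions

The task presents one virtual sheet of paper at a time on a table; the user
finds it, dips a hand into one of two ink pads (color-cued), and stamps the
sheet. All quantities live in a single *table frame*: origin at the table
center, +x toward the seated user's right, +y away from the user, +z up.
Horizontal angles (yaw) are degrees about +z, **positive rightward** — the
ipsilesional direction for a right-hemisphere lesion, matching the sign
convention of clinical gaze-bias scores. Units are meters, seconds and
degrees internally; centimeters and milliseconds appear only in reports.

## Layout and schedule (`task_schedule`)

21 locations form a radial fan of 7 angular sectors × 3 rings. Ring radii
step by the `spacing` parameter (default 0.140 m); within each ring the
sector angle is chosen so the chord between angular neighbors equals
`spacing` exactly. The fan is symmetric about the mid-sagittal plane;
sector i mirrors onto sector 8−i at equal ring, and the middle sector has
no mirror. The fan origin sits at the user edge of the table (a package
choice — the precise decomposition of the original apparatus is not
published) so the whole fan fits a 1.2 × 0.8 m table. Adjacency is defined
in (sector, ring) index space including diagonals.

A session is 63 episodes: three rounds, each visiting every location once,
with hard constraints enforced by randomized backtracking (never silently
relaxed):

* no two consecutive episodes within a round at adjacent locations;
* round 1 entirely right-handed; rounds 2/3 give each location its second
  right-hand interaction (12 locations in round 2, 9 in round 3; totals
  21/12/9 right-hand episodes per round, 42 per session);
* colors: 33 violet / 30 orange per session, balanced within and between
  the left (sectors 1–3) and right (sectors 5–7) table sides
  (14/13 violet/orange on each side, 5/4 in the middle sector);
* post-stamp delay uniform in [1, 3] s; search timeout 10 s.

Generation is deterministic per (layout, seed).

## Behavior simulation (`behavior_sim`)

The generator scripts one episode as: search scanpath → target fixation →
reaction (120 ms) → move to the cued ink pad (0.45 s) → ink dwell (0.5 s) →
minimum-jerk reach to the paper (`reach_duration_s`, default 0.7 s) → stamp.
Ground truth is sampled on a 200 Hz grid (the rate of the optical
motion-capture reference the accuracy benchmark emulates).

Behavioral parameters and defaults:

* `gaze_bias_deg` — mean yaw of search-scanpath fixation *directions*
  (sampled as gaze-ray yaw, so the downstream gaze-angle metric recovers
  the parameter directly); spread `fixation_noise_deg` = 15°.
* `base_find_time_s` = 1.8 s with `find_time_sd_s` = 0.5 s of noise;
  `left_find_penalty_s` added for targets in the two leftmost sectors.
* `anchor_lead_left_s` / `anchor_lead_right_s` — time from motion onset to
  the re-fixation of the reach target (negative = gaze arrives first).
* `omission_prob_left/right` — probability that a left/right target is
  never found before the 10 s timeout (the middle three sectors never omit,
  as observed clinically for central targets).
* Presets: `BehaviorParams.control()` (no asymmetries) and
  `BehaviorParams.usn()` (bias +7.5°, left penalty 1.0 s, anchoring lead
  −112 ms left / 0 right, torso −3.8°, omissions 9%/3%), magnitudes chosen
  to match a mild-to-moderate right-lesion profile.

Scanpath fixations deliberately avoid the active paper (8 cm margin) until
the scripted find time — otherwise random fixations would "find" targets
early and destroy the injected find-time structure.

The sensor model (`SensorParams`) renders: a 40 Hz headset stream (gaze ray
with 1.5° angular noise, hand position with 1 cm/axis noise and bursty
dropout — exponential burst lengths, mean 0.4 s, long-run loss 25%) and a
30 Hz external stream (joints and a second hand source with 2 cm/axis
noise, 3% per-sample loss, a constant frame offset of (2, 0, 0) cm from
imperfect camera-to-headset calibration, and receiver timestamps delayed by
92 ms ± 3 ms jitter). Gaze-object hits are recomputed from the noisy rays
against the scene geometry, as the live system did.

What the generator does **not** emulate: saccade dynamics and smooth
pursuit, biomechanical arm models, hand-over-hand occlusions, soft-tissue
artifacts, drift or skew between device clocks, and correlated (non-white)
sensor noise. Passing tests therefore demonstrate that the pipeline
recovers the statistical structure it is designed for, not that it is
robust to every artifact of real hardware.

## Temporal synchronization (`temporal_sync`)

Initial offset = median of receiver-minus-sender timestamp differences
(robust to network spikes). Refinement maximizes the per-axis z-scored
cross-correlation of the two hand-position series on a common 40 Hz grid,
over integer lags within ±0.5 s; z-scoring makes the estimate invariant to
constant position biases such as the uncorrected frame offset. No
sub-sample interpolation is attempted — the 30 vs 40 Hz rate mismatch does
not support it. Clock drift (linear skew) is out of scope.

## Hand fusion (`hand_fusion`)

A single Kalman filter fuses both hand sources. State (12D): position,
velocity, acceleration, and a 3D offset `b` attached to the external
measurement model (external observes p + b), so the residual inter-source
frame offset is estimated online. Parameters:

| parameter | default | meaning |
|---|---|---|
| `sigma_accel` | 3 m/s² | process SD of hand acceleration |
| `sigma_offset_walk` | 1e-4 m/√s | random walk SD of the offset state |
| `r_headset` | 0.01 m | headset measurement noise SD |
| `r_external` | 0.02 m | external measurement noise SD |
| `gate_confidence` | 0.90 | chi-square confidence for innovation gating |
| `availability_sd_cap` | 0.05 m | predictive SD above which a frame counts as lost |

Process noise uses the discrete Wiener-process acceleration model (per-axis
gain vector [dt²/2, dt, 1] scaled by `sigma_accel²`); the offset block adds
`sigma_offset_walk² · dt`. Measurements are processed in timestamp order
(headset first on ties — the lower-noise source); gating applies to both
sources at the 3-dof chi-square 90% bound (6.2514). Updates use the
Joseph-form covariance; covariances are re-symmetrized each step.
Initialization: first measurement sets the position; velocity /
acceleration / offset start at zero with diagonal covariance
(1, 10, 100, 0.01) in SI units².

Zero-phase output comes from a Rauch–Tung–Striebel backward pass. The
uniform output grid (40 Hz) is carried through the filter as
prediction-only steps, so gaps in both streams surface as inflated
*predictive* (forward, pre-update) position SD; availability is the
fraction of grid points with predictive SD ≤ `availability_sd_cap`.
Positions and velocities are read from the smoothed states. The per-step
loop is numba-jitted when numba is importable and falls back to the
identical pure-Python code otherwise.

## Gaze pipeline (`gaze_pipeline`)

Scene intersection is analytic ray-vs-table-plane with priority
paper > ink pad > table for coincident hits (all objects are coplanar).
Paper sheets are axis-aligned A5 rectangles (0.148 × 0.210 m — the original
sheet size is not published).

The categorical gaze-target series is cleaned with a majority filter over
seven samples (0.175 s at 40 Hz): a sample is labeled with an interest
target (papers and ink pads only) when that target covers ≥ 50% of the
centered window; ties between two targets go to the earlier-intersected
one. Each fixation interval's onset is back-dated to the first raw
intersection of its target within one window before the filtered
acceptance, so a target counts as fixated from first contact provided the
gaze then stays on it — the filter can delay detection but never invents a
label absent from the raw window. Continuous gaze origin/direction vectors
get a 0.35 s time-windowed running median per axis (time-based rather than
a fixed sample count, robust to frame drops), with directions renormalized.

## Torso and head (`body_pose`)

Torso yaw: horizontal shoulder axis (right − left), rotated −90° in the yaw
sense, gives the torso forward direction; its signed yaw is the torso
rotation. Frames fail the sanity check when a shoulder is missing, the
horizontal axis is shorter than 5 cm, or the head does not project onto the
shoulder segment within a 0.15 margin (the published check states no
tolerance; the margin avoids discarding natural head translation). The
chest joint is recorded but takes no part in the yaw formula. Head yaw
comes straight from the headset pose stream, unfiltered.

## Episode metrics (`metrics`)

Search phase: [t_appear, first registered fixation on the episode's paper],
or the full 10 s for omissions. Orientation averages are computed over
valid samples in that phase. Time-to-find = fixation onset − appearance.

Motion onset: candidates are local minima of the smoothed hand speed (the
smoothed Kalman velocity magnitude) in [t_ink_exit − 0.5 s, t_stamp]. Each
candidate is scored by the unweighted mean of four components:

1. distance to the ink pad, normalized by the pad-to-target distance;
2. speed, normalized by the window's peak speed;
3. misalignment (1 − cos)/2 of the subsequent 150 ms displacement with the
   pad-to-target vector; displacements under 1 mm are treated as tracking
   noise and get no directional credit;
4. |t_stamp − t_candidate − reference| normalized by the window length,
   with reference = the user's running median of recorded
   pad-exit-to-stamp durations (fallback: the current episode's).

The lowest combined score wins; ties go to the earliest candidate; with no
local minimum the recorded ink-exit time is used. Components are
normalized to these *physical* scales rather than min–max across
candidates: during the stationary ink dwell all candidates cluster at
near-zero speed and distance, and a min–max rescale amplifies sub-noise
differences to full weight (empirically ~0.1 s of side-dependent onset
bias). On the default synthetic sessions the detector is unbiased within
~10 ms with ~50 ms SD.

Gaze anchoring offset = onset of the first fixation on the episode's paper
beginning at or after the ink selection, minus the motion onset (negative:
gaze led the hand).

Lateral analysis: every location in the two leftmost sectors is paired with
its right mirror. Per user, the pair difference is (left location mean −
right location mean) of included episodes; pairs missing either side are
dropped; the per-user value is the mean over pairs (so a positive
time-to-find difference means right targets were found sooner, and a
negative anchoring difference means left targets were fixated earlier).
Motion metrics (onset, anchoring, motion duration) are restricted to
right-hand episodes, matching the study's analysis population; perception
metrics use all episodes.

Statistics: two-sided one-sample Wilcoxon signed-rank against zero
(zeros discarded, midranks for ties, exact null distribution by subset-sum
enumeration for n ≤ 25, tie-corrected normal approximation beyond), at
α = 0.05; Pearson correlation with a t-distribution p-value; group
summaries as median [Q1–Q3] with linear-interpolated quartiles (the same
quartile convention used for the 1.5 × IQR review fences). Episodes whose
motion duration or time-to-find exceeds the user's IQR fences are *flagged*
for digital-twin review; they are excluded only by an explicit reviewer
decision or the headless `auto_exclude_flagged` switch — automated flags
alone never drop data.

## Accuracy evaluation (`accuracy_eval`)

Benchmark protocol against a dense (200 Hz) reference: temporal lag by
maximizing the summed cross-correlation of speed and acceleration
magnitudes (bias-invariant); spatial alignment by Kabsch (SVD with proper
rotation) initialized on matched samples and refined by an ICP-like
iteration over nearest-in-time correspondences (monotone non-increasing
residual); then per-sample Euclidean errors on valid frames in the
evaluation windows (by default the reaching phases): RMSE, median AE, 95th
percentile AE, and availability = valid / total frames. Per-source
evaluations skip the spatial refinement so residual frame offsets count as
error, as they would in practice.

## Digital twin (`digital_twin`)

Deterministic top-down 2D frames (PIL, byte-stable PNGs): table, location
marks, active paper, ink pads, head marker, torso wedge, hand marker,
current fixation X, motion start–end line, and 3 s hand/gaze trails with
linear alpha fade (fade shape unspecified in the original tool; linear
chosen). Review decisions are plain records (keep/exclude + reason) folded
into an exclusion table; decisions for unflagged episodes are logged but
ignored. Rendering never mutates analysis inputs.

## Problem sizes and determinism

All stochastic outputs are fully determined by (inputs, seed); user-level
seeds are spawned from a cohort seed, and every simulated user gets an
individual schedule seed (per-participant randomization; a shared schedule
would correlate schedule-specific geometry effects across users and
inflate cohort-level false-positive rates for the 25 ms-quantized
anchoring metric). The test suite exercises full-size sessions
(63 episodes, ≈ 6 min simulated time) and cohorts of 7 users; recovery
checks use 5 cohort replicates and the type-I control 20 replicates —
sizes chosen to estimate medians and rejection rates with useful precision
at desk scale.

## Known limitations

* Onset detection is grid-quantized (25 ms at 40 Hz) and noise-limited to
  ~50 ms SD per episode; lateral anchoring differences below ~20 ms per
  user are not resolvable at the study's episode counts.
* The offset state models a pure translation; rotational calibration
  residuals fold into the measurement noise.
* No clock-drift estimation; sessions are short enough (< 10 min) that
  device-crystal skew is negligible relative to the 25 ms grid.
* The Wilcoxon exact distribution conditions on the observed (mid)ranks;
  for heavily tied data at n ≤ 25 the p-value is exact only in that
  conditional sense.
* The torso estimate uses shoulders only; how the original system folded
  the chest joint into the rotation estimate is unpublished.
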