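# eyehand

Offline measurement pipeline for **eye–hand coordination in a seated AR
stamping task**, built for research on unilateral spatial neglect (USN) —
the post-stroke attentional deficit toward the side of space opposite the
brain lesion. The package is aimed at researchers who want to study
search behavior and visuomotor coordination with multimodal tracking
(headset gaze + hand at 40 Hz, external body tracking at 30 Hz) but need
the whole measurement chain — from raw, asynchronous, noisy streams to
group statistics — to be reproducible and testable at the desk.

It provides, end to end:

* a **task generator**: a radial 21-location layout (7 sectors × 3 rings,
  140 mm spacing) and balanced 63-episode session schedules under the task
  constraints (no adjacent consecutive targets, 21/12/9 right-hand
  episodes per round, 33/30 color balance within and between table sides);
* a **session simulator**: scripted search → ink dip → minimum-jerk reach
  behavior with injectable USN-like asymmetries (rightward search-gaze
  bias in degrees, longer left time-to-find, omissions, earlier gaze
  anchoring on left reach targets), rendered through a realistic sensor
  model (per-source Gaussian noise, 25% bursty headset dropout, a constant
  external frame offset, 92 ms network latency);
* the **processing pipeline**: clock synchronization (median initial
  offset + z-scored cross-correlation refinement), fusion of both hand
  sources with a constant-acceleration Kalman filter carrying a 3D
  inter-source offset state (innovation gating at the 90% chi-square
  bound, Rauch–Tung–Striebel smoothing for zero-phase output), gaze
  fixation filtering (7-sample majority rule, 0.35 s vector medians), and
  torso-yaw reconstruction with plausibility checks;
* **metrics and statistics**: per-episode search-phase orientation
  averages, time-to-find, velocity-minimum motion-onset detection,
  gaze-anchoring offsets, mirrored-pair lateral differences, 1.5 × IQR
  review flags, exact Wilcoxon signed-rank and Pearson tests;
* an **accuracy benchmark** (kinematic temporal alignment, Kabsch + ICP
  spatial alignment, RMSE / median AE / 95th-percentile AE /
  availability) and a deterministic 2D **digital-twin replay** for
  qualitative review of flagged episodes.

The model at the core of the fusion is a 12-state Kalman filter
x = [p, v, a, b] with constant-acceleration kinematics, where the headset
observes p and the external tracker observes p + b; the offset b follows a
slow random walk, so residual calibration error between the two coordinate
systems is estimated online rather than left in the data.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 7-user cohort with a mild-to-moderate neglect profile
(search-gaze bias +7.5°, +1.0 s left find-time penalty, gaze anchoring
112 ms earlier on the left), process every session through the full
pipeline, and run the group analysis:

```python
from eyehand import BehaviorParams, LayoutSpec, generate_layout
from eyehand.pipeline import analyze_cohort, run_cohort

layout = generate_layout(LayoutSpec())
frames = run_cohort(7, BehaviorParams.usn(), layout, seed=1)
report = analyze_cohort(frames, layout)
g, t, a = report.gaze_bias, report.time_to_find, report.anchoring
print(f"search gaze bias: median {g.summary['median']:+.2f} deg, p={g.p_value:.4f}")
print(f"time-to-find, left - right: median {t.summary['median']:+.2f} s, p={t.p_value:.4f}")
print(f"gaze anchoring, left - right: median {a.summary['median']*1000:+.0f} ms, p={a.p_value:.4f}")
```

prints

```
search gaze bias: median +6.97 deg, p=0.0156
time-to-find, left - right: median +1.00 s, p=0.0156
gaze anchoring, left - right: median -125 ms, p=0.0156
```

Reading the numbers: the pipeline recovers the injected +7.5° ipsilesional
search bias from the noisy gaze stream; the +1.00 s lateral time-to-find
difference means left-side papers took a second longer to find than their
right mirrors; the −125 ms anchoring difference means the reach target was
fixated about an eighth of a second earlier (relative to hand-motion
onset) when it lay on the left. Each p-value is the exact two-sided
Wilcoxon signed-rank test of the 7 per-user values against zero
(p = 0.0156 is the smallest attainable value at n = 7, i.e. all users
agree in direction).

The same steps are available from the shell:

```
eyehand schedule --seed 1 --out schedule.json
eyehand simulate --seed 1 --profile usn --out rec.jsonl --truth-out truth.csv
eyehand process  --in rec.jsonl --out fused.csv
eyehand metrics  --in rec.jsonl --out metrics.csv --report report.json
eyehand eval     --in rec.jsonl --truth truth.csv --out errors.json
eyehand replay   --in rec.jsonl --fps 10 --out frames/ --start 10 --end 14
```

Recordings are single JSON-Lines files (a metadata header line followed by
typed `schedule` / `gaze` / `head` / `hand` / `body` / `event` records);
metric tables are CSV.

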