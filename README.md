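# gaitconcord

Agreement analysis between markerless skeleton-tracking cameras (e.g.
depth-camera body trackers) and a marker-based optical motion-capture
reference during treadmill gait.

Markerless cameras are attractive for clinical gait screening — no marker
placement, one sensor, works at home — but their joint estimates live in
their own coordinate frame, on their own jittery clock, and inside the
body rather than on the skin. Validating them against an optical reference
therefore needs a whole pipeline, not a single statistic. `gaitconcord`
implements that pipeline end to end:

1. **Spatial calibration** — a checkerboard with four retro-reflective
   corner markers links the two frames. A synthetic grid
   Q = {(x·s, y·s, 0) : 1 ≤ x ≤ w, 1 ≤ y ≤ h} is registered onto the
   device-detected intersection points by least-squares rigid registration
   (SVD solution of argmin_{R,t} Σᵢ‖(R pᵢ + t) − qᵢ‖², with
   R = V·diag(1, 1, det(V Uᵀ))·Uᵀ so reflections are excluded), the corner
   markers are extrapolated through the fit, and the pooled corner pairs
   over all board placements yield the device→reference transform.
2. **Preprocessing** — resampling of the jittery device stream to a
   uniform 100 Hz grid, quadratic interpolation of short dropout gaps, and
   a zero-phase 4th-order Butterworth low-pass (5 Hz) on the reference.
3. **Temporal synchronization** — the subject jumps three times before
   and after each walking bout; cross-correlating the second derivative of
   a central marker's vertical channel (sternum vs. pelvis) recovers the
   inter-system lag to one 10 ms sample.
4. **Gait events** — on a treadmill the anterio-posterior (AP) position
   of a foot marker relative to the sacrum is a sinusoid-like curve; heel
   strikes are its maxima (t_HS = (x_heel − x_sacrum)max) and toe offs the
   minima of the toe signal, thresholded at the signal mean.
5. **Spatio-temporal parameters** — step length (ankle-to-ankle distance
   at heel strike), step width (its medio-lateral component), step time
   (between contralateral heel strikes) and stride time (between
   ipsilateral heel strikes).
6. **Agreement statistics** — per-joint 3D distances after zero-mean
   shifting, per-axis Pearson r with qualitative levels (poor < 0.4 ≤
   moderate < 0.7 ≤ good < 0.9 ≤ excellent), paired Wilcoxon signed-rank
   tests with an exact small-sample null, absolute error e_a = |dev − ref|,
   signed relative error e_r = dev − ref, RMSE, and device-on-reference
   regressions.

Because no public recordings exist for this protocol, the package ships a
**synthetic treadmill-gait simulator** (`gaitconcord.simulate`) that
generates a ground-truth world — periodic gait between two triple-jump
bouts — and renders it through configurable camera models (rigid frame,
clock jitter, dropout gaps, noise, systematic joint offsets, temporal
lag). Every injected quantity is recorded, so each pipeline stage is
verifiable against a known answer.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_full_agreement_pipeline.py` (simulated device: 30 Hz
nominal, 14.92 ms clock jitter, 2 mm position noise, 1% dropout, 0.37 s
lag, random rigid frame) prints:

```
sync lag 0.37 s, calibration residual 0.35 mm
event timing: +0.6 ± 2.0 frames vs reference
pelvis      distance   2.7 ±  1.2 mm, r(AP/ML/V) = 0.96/0.99/0.99
ankle_left  distance   5.4 ±  1.6 mm, r(AP/ML/V) = 1.00/0.99/1.00
foot_left   distance   7.9 ±  2.2 mm, r(AP/ML/V) = 1.00/0.99/1.00
step_length_m  e_a 0.003 ± 0.003, e_r -0.002, rmse 0.004
step_width_m   e_a 0.002 ± 0.002, e_r +0.000, rmse 0.003
step_time_s    e_a 0.024 ± 0.018, e_r -0.000, rmse 0.030
stride_time_s  e_a 0.019 ± 0.018, e_r +0.000, rmse 0.025
```

Reading: the injected 0.37 s lag came back exactly; the checkerboard
calibration closed to 0.35 mm; gait events agree to a fraction of a 10 ms
frame on average; per-joint trajectories differ by a few mm after removing
the systematic offset; and all four gait parameters are recovered with
millimetre/centisecond errors, with e_r signs showing the direction of any
device bias.

A thin CLI mirrors the library:

```bash
gaitconcord simulate --out-dir run/ --seed 1
gaitconcord preprocess --in run/device.csv --rate 100 --out dev100.csv
gaitconcord sync --ref ref100.csv --dev dev100.csv
gaitconcord run --config pipeline.yaml      # the whole workflow from YAML
```

## Layout

```
src/gaitconcord/
  core.py          data model, axis conventions, marker mapping, CSV/TRC I/O
  calibration.py   rigid registration + two-stage checkerboard calibration
  preprocess.py    resampling, gap filling, filtering, synchronization
  events.py        heel-strike / toe-off detection, event matching
  parameters.py    step length/width, step/stride time
  stats.py         distances, correlations, Wilcoxon, error metrics
  simulate.py      synthetic gait world + camera observation models
  pipeline.py      one-config orchestration with manifest
  cli.py           thin click front end
docs/methods.md    model assumptions, defaults, limitations
examples/          one narrative script per capability
```
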