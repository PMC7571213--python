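# Methods

This note documents the models, defaults and numerical choices behind
`gaitconcord`, and what the synthetic benchmark does and does not show.

## Coordinate conventions and data model

All positions are millimetres; times are seconds. The canonical gait
frame is x = anterio-posterior (AP, direction of progression),
y = medio-lateral (ML), z = vertical (V, up). `AxisConvention` permits
signed permutations per system, because depth cameras commonly flip axes
relative to the laboratory frame. Missing samples are explicit NaN
triplets rather than dropped rows, so gap handling operates on a known
grid. Wide CSV (`time,<joint>_x/_y/_z`) is the canonical interchange
format; TRC is read-only. The shipped marker-to-joint mapping
(ankles ← ANK, feet ← TOE, pelvis ← mean(RPSI, LPSI), sternum ← STRN) is
a reconstruction for the synthetic marker set; for real device skeletons
the mapping is configuration, not code.

## Rigid registration and calibration

Registration solves argmin over proper rotations and translations of the
summed squared correspondence error via SVD of the centred
cross-covariance S = XYᵀ, with R = V·diag(1,1,det(VUᵀ))·Uᵀ and
t = q̄ − R p̄. The determinant correction makes mirrored inputs return the
best *proper* rotation rather than a reflection. Orthonormality and
determinant are validated at 1e-9.

A degenerate-configuration warning is raised when the covariance's second
singular value falls below 1e-12 of the largest: a planar point set
(rank 2) — the normal checkerboard case — still determines the rotation
uniquely once reflections are excluded, so only near-collinear sets
(rank ≤ 1), where the in-plane spin is genuinely unconstrained, warrant
the warning.

Checkerboard calibration is two-stage: fit the synthetic grid into each
placement's detected intersections, extrapolate the four corner-marker
offsets through that fit into the device frame, then register the pooled
(extrapolated, measured) corner pairs across all placements in one final
solve. Pooling (rather than averaging per-placement transforms) keeps the
estimate the least-squares optimum of the combined correspondence set.
Intersection points must arrive in the grid's row-major order; ordering
unlabelled detections is upstream image-processing work and out of scope,
though `GridSpec.corner_marker_offsets` and the w/h/s parameters are all
explicit so any physical board can be described. The corner markers
default to the board's outer corners at (0,0), ((w+1)s,0), (0,(h+1)s),
((w+1)s,(h+1)s) — the true offsets on a physical board are measured
configuration.

## Preprocessing and synchronization

* Resampling is piecewise-linear onto a uniform grid (cubic optional).
  Grid points inside source gaps longer than 1.5 sampling periods stay
  missing; `fill_gaps_quadratic` then replaces interior runs up to
  `max_gap_frames` (default 10 at 100 Hz) with a quadratic fitted to up
  to three support frames per flank. Quadratics are restored exactly; for
  band-limited signals the residual is bounded by the local
  third-derivative Taylor remainder. Edge runs are never extrapolated.
* The reference stream is filtered with a 4th-order Butterworth low-pass
  at 5 Hz, applied forward–backward (zero phase) so filtering cannot bias
  event timing; device streams are left unfiltered by default (flag to
  filter both). Zero-phase filtering squares the magnitude response, so
  stopband suppression is at least the single-pass value.
* Synchronization cross-correlates the second finite difference of the
  vertical channel of a central marker (sternum for the reference, pelvis
  for devices) over a ±10 s window, returning an integer lag at the
  100 Hz working rate (10 ms resolution; sub-sample refinement is out of
  scope). Positive lag means the device content is delayed — the same
  jump carries a later timestamp in the device stream — and the simulator
  injects lags with the same convention. Because double differentiation
  amplifies sensor noise as rate², both channels are smoothed with a
  zero-phase 10 Hz Butterworth before differencing; the jump spikes
  (σ ≈ 0.1 s, bandwidth ≈ 1.6 Hz) pass through unchanged, so the
  estimate acquires no bias while the noise floor drops enough to keep
  the lag within ±1 sample at 2 mm position noise.

## Event detection and parameters

Heel strikes are local maxima of the sacrum-relative AP heel signal above
its mean; toe offs are minima of the toe signal below its mean. Two
guards harden the mean-threshold rule on realistic data: a minimum peak
separation of half the dominant period (from the autocorrelation's first
side peak) suppresses near-duplicate peaks on noisy streams, and a
prominence floor of 5% of the channel's range rejects millimetre-scale
ripples in the rest segments flanking the walking bout. Endpoints are
never peaks. Events are detected independently per system after
synchronization, then matched greedily nearest-first per (type, side)
within half the median stride; frame differences are signed
(device − reference, negative = device earlier).

Step length is the full 3D ankle-to-ankle distance at heel strike by
default; a config switch (`mode="ap"`) gives the AP-component convention,
since published definitions differ and the plain wording ("distance
between the ankle markers") does not disambiguate. Step width is the
absolute ML component; step time excludes intervals between two same-side
strikes (a missed contralateral event) instead of silently doubling;
stride times are per-side differences, pooled.

## Agreement statistics

Zero-mean shifting subtracts each joint-axis channel mean over the
analysed walking segment, removing the constant offset between
skin-mounted markers and in-body joint estimates before distances and
correlations are computed. Standard deviations use the n−1 denominator
throughout. Pearson r is computed per joint per gait axis on the common
non-missing frames; qualitative levels use half-open intervals with 0.4,
0.7 and 0.9 boundaries (boundary values round up: r = 0.4 is moderate).
The paired Wilcoxon signed-rank test drops zero differences, mid-ranks
ties, and evaluates the exact two-sided null for n ≤ 25 via a dynamic
program over doubled ranks — identical to enumerating all 2ⁿ sign
assignments at polynomial cost — switching to the tie-corrected normal
approximation above. No multiple-testing correction is applied; the
report metadata says so. Regressions of device on reference values are
skipped when the reference values span less than 2% of their magnitude
(a single perfectly periodic trial), where a fitted slope is noise.

## The synthetic world

The simulator emulates the study conditions the pipeline targets:

* **Gait signal**: the AP position of each foot relative to the sacrum is
  a pure sinusoid with period = stride time and a π phase offset between
  sides — the treadmill belt pulls the stance foot back — with amplitude
  set so the 3D ankle separation at heel strike equals the configured
  step length exactly. The toe signal leads by π − 2π·duty so toe-off
  falls duty·stride after the ipsilateral heel strike (duty factor
  default 0.62, valid range 0.5–0.8). A shared ML sway (cancelling in the
  ankle difference), a small trunk AP bob, a two-per-stride pelvic
  vertical oscillation and a raised-cosine foot lift during swing (zero
  at every heel strike, so configured parameters stay exact) add
  realistic per-axis structure. The walking bout spans an integer number
  of strides between the jump bouts, so all analytic event times are
  known and recorded in the `GroundTruth` ledger together with per-step
  parameters computed from the trajectories themselves.
* **Jump protocol**: three Gaussian vertical spikes (amplitude 300 mm,
  σ = 0.1 s) before and after the bout, on pelvis and sternum alike.
* **Observation models**: per device, a rigid world→device transform, a
  truncated-normal inter-frame interval (configurable mean/sd matching
  reported device behaviour, e.g. 33.3 ± 14.9 ms), geometric-length
  dropout gaps, isotropic Gaussian position noise, constant per-joint
  offsets (the in-body vs on-skin bias), and a content delay
  (device records world(t − lag)). One master seed spawns per-observer
  generators deterministically; identical configs reproduce trials bit
  for bit.
* **Default regimes**: slow/medium/fast presets with stride times
  1.28/1.13/1.04 s, step lengths 0.48/0.55/0.61 m and widths
  0.21/0.20/0.20 m, the typical healthy-adult values for treadmill belt
  speeds of 3.0/3.9/4.7 km/h.

What the simulator does *not* model: whole-body kinematics and kinetics,
soft-tissue artifact (markers moving over bone), marker occlusion and
relabelling errors, device-specific tracking failure modes, or gait
pathology. Passing the synthetic benchmark therefore demonstrates that
the pipeline's algorithms are correct and its error propagation behaves
as designed — not that any particular camera meets a clinical accuracy
bar on real patients.

## Pipeline defaults and problem sizes

The orchestrated run uses a 40 s trial (≈ 21 strides per side at the slow
regime; the long-trial event benchmark uses 80 s ≈ 52 strides), a 100 Hz
working rate, five checkerboard placements at 0.5 mm detection noise, and
a 3 s segmentation margin after the last pre-bout jump spike — enough to
clear both the jump decay and the walk-onset transient, whose filter
ringing would otherwise sit exactly at the segment edge. The walking
segment is located from the jump spikes themselves (prominent vertical
peaks, split at the largest inter-spike gap), not from the ground truth.
With a single simulated trial the Wilcoxon input is the per-occurrence
parameter pairs truncated to common length; with multiple trials it
should be per-trial means, which is how the report metadata labels the
aggregation.

## Known limitations

* Correspondence between detected checkerboard intersections and grid
  points is assumed given in row-major order.
* Integer-sample lags only; clock drift within a trial is not modelled or
  estimated.
* The event detector's mean threshold assumes treadmill (stationary-sacrum)
  walking; overground data would need detrending first.
* TRC reading covers the common tab-separated layout with mm/cm/m units,
  not every historical variant.
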