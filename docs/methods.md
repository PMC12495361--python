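# Methods

This note documents the models and procedures implemented in
`couchcorr`, the parameter choices that matter, and the design decisions
taken where more than one reasonable option existed.

## Coordinate model and correction

A fixed, ceiling-mounted optical tracker reports each rigid marker as a
4×4 homogeneous transform in the camera ("global") frame.  The camera
views the patient at a pitch angle θ about the lateral (y) axis, so the
patient's anterior–posterior (AP) motion mixes into global x and z.  The
pitch rotation

    R(θ) = [[cos θ, 0, sin θ], [0, 1, 0], [−sin θ, 0, cos θ]]

maps global to patient coordinates (AP, medial–lateral,
cranial–caudal); the AP component of a global position v is
`v_x cos θ + v_z sin θ`.  θ is read from a marker orientation matrix as
`arcsin(−R₃₁)` (principal branch).  One self-consistent convention is
fixed throughout: marker orientation matrices store R(θ) itself, whose
(3,1) element is −sin θ, and positions are embedded into the global
frame via R(θ)ᵀ.  The correction is the exact sample-wise subtraction
`x_corrected = x_breathing − x_table`; no smoothing or scaling is
applied at this stage, so the correction's fidelity is limited only by
tracking noise and the two markers genuinely sharing the table motion.

Because the AP projection is the first row of R(θ) applied to the
global position, any motion or constant offset along the patient's own
medial–lateral and cranial–caudal axes cancels identically in the
projection — table feed (a cranial–caudal translation) drops out even
before the subtraction; sag (an AP translation) is removed by the
subtraction.

**Session pitch estimate.** θ is estimated once per session as the
median of per-frame `arcsin(−R₃₁)` over the first 1 s of the
table-marker stream.  The camera angle is rigid for a session; a
per-frame θ would inject marker-orientation noise into the position
correction, and the table marker is preferred because it is rigid and
never occluded by breathing motion.  The source of θ (patient marker,
table marker, or calibration frame) is genuinely open in this class of
system; the table-marker median is this package's choice, and an
explicit `theta=` override is available.

**Input validation.** Rotation sub-matrices must satisfy
`‖RᵀR − I‖∞ ≤ 1e-6` and `det R = 1 ± 1e-6`; poses beyond tolerance are
rejected rather than re-orthogonalised, because silently repairing a
corrupt tracker frame would hide hardware faults.

## Stream pairing and alignment

The two marker streams are asynchronous in general.  The table AP
signal is linearly interpolated onto the patient timestamps; linear
interpolation suffices because table motion is slow and piecewise
smooth compared with any plausible frame rate.  Patient samples whose
nearest table frame is farther than `max_gap` (default 0.2 s, several
frames at a ~60 Hz tracker) are dropped as table-stream dropouts.
Traces from different systems are aligned at the first X-ray-on
transition; beam-on flags are carried per sample and maximal on-runs
are exposed as ordered, non-overlapping events.  No de-jitter or
clock-drift compensation is applied.

## Metrics

* **Plateau detection.**  The signal is smoothed with a centered moving
  average (default 0.25 s); candidate samples have smoothed-derivative
  magnitude ≤ `slope_tol` (default 1.0 mm/s) *and* smoothed amplitude ≥
  50 % of the trace's 95th-percentile amplitude (an adaptive height
  gate that rejects quiet-breathing stretches).  Candidate runs are then
  *boundary-refined*: the run is expanded over raw samples that stay
  within a noise-scaled tolerance (4 robust σ, estimated from
  first differences via the MAD, floored at 1e-6 mm) of the run mean.
  Refinement matters because a centered smoothing window blurs each
  plateau edge by about half a window, which would bias detected
  durations short by ~0.2 s; with refinement, noise-free durations are
  exact to one sample.  Runs shorter than `min_duration` (default 5 s,
  the usual minimum clinical breath-hold) are discarded.  Per-plateau
  mean amplitude and drift are computed over the interior after
  trimming 10 % of samples at each end, excluding inhale/exhale ramps
  that would bias the drift.  Boundary refinement assumes the hold is
  locally flat; on deliberately tilted plateaus it degenerates
  gracefully to the smoothed-mask boundaries.
* **Plateau drift** is the ordinary-least-squares slope (mm/s) of
  amplitude vs time; drift is computed over the whole plateau interior
  by default (a beam-on-restricted variant is a caller-side filter).
* **Baseline shift** is the amplitude of the last end-expiration
  minimum minus the first (negative = sagging baseline).  Minima are
  prominence-filtered local minima of the smoothed signal (prominence ≥
  0.2 × signal range, separation ≥ 0.5 s) — robust against 0.06 mm RMS
  tracking noise — and the *smoothed* values are differenced, so the
  smoothing's small systematic attenuation cancels between the two
  ends.
* **Cycle segmentation** uses the mirrored rule on maxima; per-cycle
  amplitude is the raw max − raw min within the inter-peak interval
  (raw, so peak amplitudes are not attenuated), duration the inter-peak
  interval.
* **Cohort aggregation** takes per-subject (mean, SD) pairs and reports
  the mean ± sample SD of the means and the mean ± sample SD of the
  SDs.  All SDs in the package use the n−1 convention.  Values are
  carried at full precision; presentation rounding is one decimal,
  half-away-from-zero (banker's rounding would alter .x5 cells).
* **Scenario comparison** follows a normality-gated rule: Shapiro–Wilk
  on both groups; if both p > 0.05 a paired t-test (an unpaired variant
  is available), otherwise Mann–Whitney U.  Zero-variance paired
  differences are reported as a degenerate test rather than p = NaN.

## Feedback logic

The guidance waveform is a cosine-power respiratory model,
`g(t) = A (1 − cos^k(π t / T))` with k even (default 6).  The
orientation is chosen so that g(0) = 0 is the end-exhale resting
baseline and A is the peak-to-trough amplitude; the even power gives
the long-exhale/short-inhale shape of relaxed breathing.  Defaults
A = 30 mm, T = 10 s.  The DIBH window is a static corridor (default
width 5 mm, draggable via configuration); the 4DCT window has a fixed
half-width (default 2.5 mm) centered on g(t).  States are classified
per sample: `outside` beyond the bounds, `edge` within `edge_margin` of
a bound (default 10 % of window width — the display's yellow zone is
shown but not quantified in practice, so a round fraction is used),
`within` otherwise.  Dynamic-window bounds may go negative near
end-exhale; clipping is left to the display layer so the classifier
stays exact.

## Simulator

The simulator is the package's test bed, standing in for tracker,
table and phantom/volunteer:

* **Breathing patterns.**  Sinusoid `(A/2)(1 − cos 2πft)` (defaults
  0.2 Hz, 20 mm peak-to-trough — the phantom 4DCT protocol); the
  guidance waveform itself; and a DIBH sequence of `n_plateaus` holds
  (default 3) at level A (default 20 mm) with 6.5 s hold duration,
  1 s smoothstep ramps, a lead-in of three free-breathing periods and
  one period of rest between holds.  Free breathing within the DIBH
  sequence is a half-amplitude sinusoid, and all segment joints fall at
  end-exhale so the signal is continuous.
* **Table sag and feed.**  Sag follows a smoothstep (3u² − 2u³) from 0
  to `sag_scale(load) × sag_max` across the table-travel interval —
  the beam-on block for helical scans, stepwise ramps across each feed
  gap for axial 4DCT.  `sag_max` defaults to −5 mm (worst-case
  full-load deflection); the load scale is linear,
  `0.2 + 0.8·load/104`, so 0 / 52 / 104 kg map to 20 / 60 / 100 % —
  only the full-load endpoint is empirically anchored, the interior of
  the scale is a modelling choice.  Axial scans use 6 s beam-on blocks
  with 2 s feed gaps of 34.5 mm each; both markers share the sag and
  the cranial–caudal feed.
* **Camera and noise.**  Default pitch 0.35 rad (~20°).  Tracking
  noise is seeded isotropic Gaussian per global axis, default 0.06 mm
  RMS per axis, independent between markers — only an overall RMS
  figure is available for such trackers, so isotropy is the neutral
  assumption.  The corrected signal therefore carries ≈ 0.06·√2 ≈
  0.085 mm RMS residual noise, which the test suite verifies by
  variance addition.  A constant `latency` on the table stream is
  supported (tracker pipelines report ~16.6 ms); the default is 0 so
  that the documented noise-free exactness property (corrected output
  equals breathing truth to 1e-9 mm) holds for default configurations,
  and latency is switched on explicitly where wanted.  Jitter is out of
  scope.
* **Presets.**  Twelve named scenarios: phantom DIBH and 4DCT at the
  three loads, and volunteer DIBH/4DCT under audio guidance, visual
  guidance, and visual guidance with table travel.  Volunteer visual
  4DCT presets use the guidance parameters (30 mm, 10 s, 30 s runs);
  volunteer amplitudes (13–16 mm natural, −2 mm thorax-scan sag
  endpoint) are realistic round values, not measured ones.

**What the simulator does not emulate:** anatomical deformation and
patient-specific breathing irregularity, marker occlusion, orientation
noise (noise is positional only), clock drift between streams,
imaging-chain artifacts, and surface-patch re-registration jumps of
camera-based commercial systems.  Passing tests therefore demonstrate
the correctness of the geometry, correction and metric chain under the
stated noise model — not clinical performance on real patients.

## Problem sizes and determinism

The residual-sag experiment runs the worst-case axial 4DCT scenario
(60 s at 50 Hz, 3001 samples per stream) for 100 seeds and summarises
|baseline shift| of the corrected traces at the 95th percentile; the
parameter-recovery checks use single noise-free runs of the same
protocols.  These sizes make the whole validation complete in seconds
while keeping Monte-Carlo summaries stable to well under the 0.25 mm
bound being tested.  All randomness flows through
`numpy.random.default_rng` seeded from the configuration (the
acceptance script spawns per-run seeds from its `--seed` via
`SeedSequence`), so every run is exactly reproducible; simulator file
output is byte-identical under a fixed seed.

## Known limitations

* Pitch-only rotation correction: roll/yaw misalignment between camera
  and patient axes is not corrected.
* The plateau detector's boundary refinement assumes holds are flat at
  the sample scale; strongly drifting holds fall back to
  smoothed-mask boundaries (durations then read ~0.25 s short).
* Baseline shift is undefined on traces with fewer than two qualifying
  end-expiration minima and is reported as an explicit error, not 0.
* The table-sag model is phenomenological (smoothstep, linear load
  scale); it reproduces deflection endpoints, not couch mechanics.
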