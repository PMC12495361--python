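# couchcorr

Couch-motion-corrected optical respiratory surrogate signals for
CT-based respiratory motion management (DIBH and 4DCT).

## The problem

Radiotherapy imaging workflows such as deep-inspiration breath-hold
(DIBH) CT and respiration-resolved 4DCT rely on an external *respiratory
surrogate* — typically the anterior–posterior (AP) height of a marker
block on the patient's chest.  The CT table contaminates that signal:
table feed moves the marker through the camera's field of view, and the
table sags by several millimetres under patient weight as it travels.
Uncorrected, this shows up as spurious baseline shifts in 4DCT traces
and plateau drift in breath-hold traces, and it corrupts amplitude-based
gating and visual breathing coaching.

`couchcorr` implements a dual-marker correction: a ceiling-mounted
optical tracker reports 4×4 homogeneous transforms for a patient marker
and a second marker rigidly mounted on the CT table at the same
longitudinal position.  With the camera pitch angle
θ = arcsin(−R₃₁) read from a marker orientation matrix R, the AP
components are

    x_breathing = x_global,patient · cos θ + z_global,patient · sin θ
    x_table     = x_global,table   · cos θ + z_global,table   · sin θ
    x_corrected = x_breathing − x_table

so that table feed and sag — which both markers share — cancel exactly,
leaving the breathing motion.

The package provides, for people building or evaluating such systems:

* **geometry** — pitch extraction, global→patient rotation, AP
  projection, and the subtraction correction;
* **streams** — trace/pose-log file formats, asynchronous stream
  pairing, X-ray-event extraction and first-beam-on alignment;
* **metrics** — breath-hold plateau detection, plateau drift (OLS
  slope, mm/s), baseline shift (last minus first end-expiration
  minimum, mm), max-to-max cycle segmentation, cohort aggregation, and
  a normality-gated scenario comparison (Shapiro–Wilk → paired t or
  Mann–Whitney U);
* **feedback** — the cos⁶ guidance waveform
  g(t) = A·(1 − cos⁶(πt/T)), static (DIBH) and dynamic (4DCT)
  breathing windows, and green/yellow/red state classification;
* **simulator** — a synthetic test bed generating both marker pose
  streams with configurable breathing patterns, load-dependent table
  sag, table feed, camera pitch, seeded tracking noise and X-ray
  schedules, plus a ground-truth channel.

## Worked example

Simulate the worst-case phantom 4DCT scenario (sinusoidal breathing at
0.2 Hz with 20 mm peak-to-trough, −5 mm table sag at full load,
0.06 mm RMS tracking noise), correct it, and analyze the result:

```sh
couchcorr simulate --preset phantom_4dct_104kg --seed 1 --outdir run/
couchcorr correct --patient run/patient_poses.csv --table run/table_poses.csv \
    --truth run/ground_truth.csv --out run/corrected.csv \
    --uncorrected-out run/uncorrected.csv
couchcorr analyze run/corrected.csv --mode 4dct
```

The `correct` step prints the recovered camera pitch and sample count:

```
theta = 0.350000 rad; 3001 samples (0 dropped)
```

and `analyze` reports (abridged):

```json
{
  "n_cycles": 11,
  "amplitude_mean_mm": 20.24,
  "duration_mean_s": 5.004,
  "baseline_shift_mm": 0.016
}
```

The corrected trace recovers the generated 20 mm / 5 s breathing and a
baseline shift of a few hundredths of a millimetre, while the same
command on `run/uncorrected.csv` shows the injected table sag as a
baseline shift of −5.006 mm.  The same pipeline in Python:

```python
import couchcorr as cc

res  = cc.simulate(cc.scenario_presets()["phantom_4dct_104kg"])
corr = cc.correct_streams(res.patient, res.table, xray_events=res.truth.events)
report = cc.fourd_report(corr.corrected)
print(report.amplitude_mean, report.baseline_shift)
```

Cohort aggregation reproduces study-style summary rows from per-subject
statistics (bundled example data in `couchcorr.datasets`), e.g. the
audio-feedback breath-hold amplitudes of the ten-volunteer example
cohort aggregate to `12.6 ± 6.5` mm with a mean per-subject SD of
`1.1 ± 0.7` mm.

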