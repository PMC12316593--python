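# pulsebp

Non-invasive beat-to-beat arterial blood-pressure (BP) estimation from
4-lead ECG and SpO2 (plethysmographic) waveforms, with intra-arterial ABP
as the gold standard. The package implements the full chain:

1. **Records & IO** (`pulsebp.records`) — six-channel waveform records
   (4 ECG leads, SpO2, ABP) with demographics, CSV read/write, polyphase
   resampling to 250 Hz.
2. **Synthetic data** (`pulsebp.simulate`) — a physiologically structured
   simulator whose pulse timing (PAT), pulse amplitude and heart rate
   co-vary with a programmed BP trajectory, with exact per-beat ground
   truth, four injectable noise classes (loose-lead artifacts, baseline
   wander, high-frequency jitter, flat/saturated segments) and optional
   pacing spikes.
3. **Quality screening** (`pulsebp.quality`, `pulsebp.quality_net`) —
   4 s windows with 0.5 s overlap, hard flat/range screens, six
   hand-engineered quality features (periodicity, QRS correlation,
   >12 Hz energy, sharpness, amplitude/peak stability), and a hybrid
   convolutional classifier (two conv blocks + hand-feature fusion,
   implemented in numpy). A segment is clean only if all six channels are.
4. **Delineation** (`pulsebp.delineate`) — median-filter baseline removal,
   51-tap 15 Hz FIR for paced subjects (delineation pass only),
   dyadic-wavelet ECG delineation (R, QRS bounds, T peak/end), and
   double slope-sum pulse valley/peak detection.
5. **Beat sequencing** (`pulsebp.beats`) — cross-channel beat extents
   (previous T end → current T end; valley → valley), contiguous
   L-beat windows (L in {1,5,10,20,30,50}, non-overlapping or sliding),
   median gold-standard BP with the systolic [80,220] / diastolic
   [40,120] mmHg acceptance rule.
6. **Features** (`pulsebp.features`) — the 48-entry vector (per-lead
   Hjorth mobility/complexity, Higuchi fractal dimension, amplitude
   entropy, autocorrelation, QTc, T amplitude; SpO2 Kaiser-Teager energy
   statistics, spectral entropy, AR(5) coefficients; heart rate, PAT,
   T2SpO2; demographics) and the default selection rule (34 features).
7. **Models** (`pulsebp.models`) — 400-tree general forest, 100-tree
   per-subject bank, augmented per-tree pooled predictor, OOB permutation
   importance, 5-fold CV with BP-range stratification per subject and the
   sliding-window 4-sequence exclusion buffer.
8. **Evaluation** (`pulsebp.evaluation`) — MAE ± SD of absolute errors,
   Bland-Altman limits, BHS grading, AAMI pass/fail, BP/demographic
   stratified reports, 20-sample windowed cross-correlation tracking lag.
9. **Pipeline & CLI** (`pulsebp.pipeline`, `pulsebp.cli`).

## CLI

```bash
pulsebp simulate --subjects 3 --duration 120 --out records/
pulsebp delineate records/sim0000.csv
pulsebp featurize records/*.csv --out features.csv
pulsebp cv --features features.csv --target systolic --mode general --mode subject
pulsebp evaluate --predictions cv_predictions.csv
pulsebp all --subjects 5 --duration 600 --out run/
```

## Notes

- All sample indexing is 0-based with half-open `[start, end)` extents at
  250 Hz.
- Feature values stay on their physical scales (no normalization);
  missing components carry NaN and are median-imputed at the model layer.
- The hybrid noise classifier and the wavelet delineator are
  self-contained (numpy/scipy only); no deep-learning framework needed.
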