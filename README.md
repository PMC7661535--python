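# ppgage

Smartphone-PPG vascular-aging pipeline: preprocess raw fingertip
photoplethysmography recordings, detect heartbeats, extract 38 waveform
features, rank them with a repeated ridge-regression procedure, and classify
healthy vascular aging (HVA) — plus a synthetic cohort simulator with known
ground truth so every stage is testable offline.

## Pipeline

1. **Preprocessing** (`ppgage.preprocess`) — estimate the average sampling
   frequency, resample onto a uniform grid, subtract a one-second centered
   moving average (detrending), and divide by the smoothed Hilbert envelope
   (demodulation / amplitude stabilisation).
2. **Beat detection** (`ppgage.beats`) — a voting peak detector: a sample is
   a partial peak under a moving-average window when it is the maximum of a
   run of samples strictly above the CMA; the six window widths
   `(0.5, 1, …, 3) × sf` must all agree, and peaks closer than 400 ms are
   merged by height. RR intervals (ms) and a quality score
   `Q = Var(peak heights) × (N_extrema − N_detected + 2) / N_points`
   follow; recordings with `Q ≥ 0.01` are discarded.
3. **Features** (`ppgage.features`) — 38 features: 9 RR statistics
   (ibi, medianRR, madRR, sdnn, cvRR, rangeRR, tpr, skewnessRR, kurtosisRR),
   7 successive-difference statistics (sdsd, rmssd, pnn20, pnn50, tpr_diff,
   skewness_diff, kurtosis_diff), and 22 second-derivative (SDPPG)
   quantities built from the a–e waves located per beat via
   fourth-derivative zero crossings (amplitudes, amplitude ratios incl. the
   aging index, slopes, time distances).
4. **Cohort ML** (`ppgage.cohort_ml`) — age dichotomization (18–38 vs
   60–79), age-decile-stratified train/test split, median/IQR
   standardization learned on train only, a 100-repetition linear+logistic
   ridge ranking (2/3 subsamples, 10-fold CV-tuned penalties, mean ranks
   summed), an RBF-SVM classifier tuned by 3-fold CV, ROC/AUC evaluation,
   and LOWESS sex-stratified predicted-age trends.
5. **Synthetic cohorts** (`ppgage.synthetic`) — two-lobe pulse templates
   whose sharpness is driven by a stiffness parameter (planted negative
   a-wave/age link), RR sequences whose irregularity is driven by a
   randomness parameter (planted positive tpr/age link), respiratory
   modulation, drift, noise, jittered ~30 Hz timestamps, and per-subject
   covariates.

## CLI

```bash
ppgage simulate --n 100 --seed 7 --effect strong --out-dir data/
ppgage ingest --input-dir data/ --quality-threshold 0.01 --out features.csv
ppgage preprocess --in data/subj0000.csv --out processed.csv --debug-stages
ppgage beats --in processed.csv --out peaks.csv
ppgage features --in processed.csv --peaks peaks.csv --out one_subject.csv
ppgage rank --features features.csv --reps 100 --seed 1 --out ranking.csv
ppgage classify --features features.csv --model iii --seed 1 --out report.json
```

Recording CSVs carry the header `time,red,green,blue,accX,accY,accZ`, with
subject metadata in leading `# key: value` comment lines (or a sidecar
`<id>.meta.csv`).

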