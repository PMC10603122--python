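# neurofatigue

A synthetic-biosignal pipeline for studying session fatigue. The package
generates multichannel EEG, ECG/RR series, oddball event streams and
mood/fatigue questionnaire tables with *known, injectable* fatigue
signatures, then runs the full analysis chain used to detect them:

- **`synth`** — generators with ground truth: 5-channel EEG (Fz, Cz, Pz,
  O1, O2 at 512 Hz) built from narrowband sinusoid mixtures whose
  normalized band power drifts linearly over the session, blink and 50 Hz
  contamination, stimulus-locked ERP components (N2/P3a/P300), RR series
  with linear heart-rate trends, controllable LF/HF balance and calibrated
  RMSSD/SDRR/pNN50 ramps, and thresholded latent-trait questionnaire
  responses (16-item mood scale scored 1–4, 18-item fatigue scale scored
  1–5).
- **`preprocess`** — zero-phase 1128-tap windowed-sinc high-pass at
  0.5 Hz, comb notch at 50 Hz and harmonics, wavelet-enhanced ICA
  (large wavelet coefficients of selected components are zeroed,
  sub-threshold structure retained), and the 0.5–30 Hz least-squares FIR
  band-pass for the ERP path.
- **`spectral`** — Welch PSD (eight Hamming segments, 50% overlap),
  normalized Delta/Theta/Alpha/Beta power in non-overlapping 3-min
  windows, frontal Theta/Beta ratio, and OLS trend tests on window
  series.
- **`erp`** — epoching (−0.2 to 0.8 s, pre-stimulus baseline), ±100 µV
  amplitude rejection, subject-then-grand averaging, onset-latency
  estimation, and time-point-wise random-intercept models (phase models
  and item-score models with BH correction across time).
- **`hrv`** — Pan–Tompkins QRS detection (band-pass, derivative, square,
  150 ms integration, adaptive dual thresholds with search-back), RR
  cleaning, cubic 4 Hz resampling, and windowed HR/RMSSD/pNN50/SDRR/
  LF_nu/HF_nu/ln[LF/HF].
- **`questionnaires`** — mood and fatigue scoring, Cronbach's alpha,
  paired Wilcoxon condition tests with Benjamini–Hochberg correction, and
  an order-effect mixed model.
- **`linkstats`** — index–item random-intercept models (standardized
  fixed effects), window-wise and time-averaged paired condition tests
  with per-panel BH families.
- **`pipeline` / `cli`** — stage orchestration with manifests,
  deterministic replay and miniature fixtures.

## Unit conventions

EEG band-power drifts are injected and recovered in **normalized power
per second**; HR/HRV drifts in **units per 3-min window**. Trend
regressions use window mid-points in seconds (EEG) or the window index
(HRV) accordingly.

## CLI

```sh
neurofatigue fixture --profile fatigue_injected --seed 1 --out config.json
neurofatigue run-all --config config.json --outdir runs/demo
# or stage by stage:
neurofatigue simulate   --config config.json --outdir runs/demo
neurofatigue preprocess --config config.json --outdir runs/demo
neurofatigue features   --config config.json --outdir runs/demo
neurofatigue hrv        --config config.json --outdir runs/demo
neurofatigue erp        --config config.json --outdir runs/demo
neurofatigue scores     --config config.json --outdir runs/demo
neurofatigue link       --config config.json --outdir runs/demo
neurofatigue report     --config config.json --outdir runs/demo
```

Fixture profiles: `null`, `fatigue_injected`, `erp_only`, `hrv_only`.
Recordings are stored as plain CSV with a JSON sidecar (sampling rate,
channels, units); events as TSV; all feature/effect tables as tidy CSV.
Exit codes distinguish config errors (2), missing/corrupt data (3) and
numerical failures (4).

## Notes

- pNN50 uses the total number of RR intervals as denominator by default
  (the documented instrument wording); pass
  `time_domain_indices(..., count_all_intervals=False)` for the
  conventional successive-difference denominator.
- The wavelet transform used by the ICA cleaning step is a small
  periodized orthogonal DWT (Haar / Daubechies-4) implemented in
  `neurofatigue._wavelet`, with perfect-reconstruction property tests.
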