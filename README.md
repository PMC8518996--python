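# wheezekit

Wheeze power band detection on pediatric lung-sound spectrograms, and
diagnostic evaluation of whether the pre-inhalation band count predicts
the response of wheezing to an inhaled β2-agonist (bronchodilator).

Wheezes — continuous musical adventitious lung sounds — appear on a
spectrogram as persistent sharp ridges of spectral power ("wheeze power
bands"). Counting and characterizing these bands before bronchodilator
inhalation gives an objective index of how likely the wheezing is to
resolve after treatment, which matters for home management of wheezy
infants and young children who cannot cooperate with spirometry.

`wheezekit` provides the full analysis chain for researchers in
respiratory acoustics and for anyone reproducing this class of study
without access to patient audio:

1. **Synthesis** (`wheezekit.synth`) — 30-s tidal-breathing chest
   recordings with injected tonal wheezes of known onset, duration,
   frequency glide and SNR, plus parametric two-group cohorts of wheeze
   indexes (truncated-normal models of a bronchodilator *disappear*
   group, n = 91, and a *non-disappear* group, n = 111).
2. **Spectrogram** (`wheezekit.spectro`) — 44.1 kHz resampling, 50 Hz
   high-pass, 4096-point Hann STFT (hop 1024), dB re file max.
3. **Detection** (`wheezekit.detect`) — per-frame spectral peak picking
   over a running-median background, greedy nearest-frequency ridge
   linking, and the CORSA acceptance rules for an adventitious musical
   sound: dominant frequency > 100 Hz, duration > 100 ms.
4. **Indexes** (`wheezekit.indexes`) — the five per-recording wheeze
   indexes: band count per 30 s, mean duration, mean lowest / highest /
   maximum-intensity frequency.
5. **Diagnostics** (`wheezekit.diagnostics`) — sensitivity, specificity,
   predictive values, likelihood ratios LR± , ROC curve, trapezoidal AUC
   (= the Mann–Whitney probability P(X_case > X_control) with
   half-credit ties), Hanley–McNeil SE(AUC), cutoff selection (Youden
   J = max(se + sp − 1), minimum-sensitivity, closest-to-(0,1)), and an
   ROC sample-size solve.
6. **Cohort statistics** (`wheezekit.cohort_stats`) — Welch/Student
   unpaired t-tests (raw samples or n/mean/SD summaries), Pearson
   correlations, and the standard two-table cohort report.

## Worked example

```python
import numpy as np
from wheezekit import (BreathModel, DetectorConfig, LabeledScores,
                       compute_indexes, detect, evaluate,
                       place_random_wheezes, reference_group_models,
                       simulate_cohort, synthesize_recording)

# five random non-overlapping wheezes in 30 s of breath noise
rng = np.random.default_rng(7)
specs = place_random_wheezes(5, rng)
rec = synthesize_recording(BreathModel(), specs, 30.0, 44100.0, seed=7)

bands = detect(rec)           # default DetectorConfig()
idx = compute_indexes(bands, 30.0)

cohort = simulate_cohort(reference_group_models(), seed=1)
data = LabeledScores(cohort["count_per_30s"].to_numpy(),
                     cohort["group"].to_numpy())
summary = evaluate(data)      # ROC + Youden cutoff + AUC with SE
```

This prints (via the obvious formatting):

```
detected 5 wheeze power bands:
    0.38-  0.82 s    441 ms    355-  377 Hz  maxint   366 Hz
   13.24- 13.78 s    541 ms    345-  355 Hz  maxint   345 Hz
   22.72- 23.21 s    492 ms    506-  506 Hz  maxint   506 Hz
   24.21- 24.44 s    236 ms    797-  797 Hz  maxint   797 Hz
   26.17- 26.45 s    273 ms    581-  624 Hz  maxint   603 Hz
indexes: {'count_per_30s': 5.0, 'duration_ms': 396.7, 'lowest_hz': 516.8,
          'highest_hz': 531.9, 'maxint_hz': 523.3, 'n_bands_raw': 5}
cohort AUC 0.721 +/- 0.035, youden cutoff 8.62, sens 0.60, spec 0.74
```

All five injected wheezes are recovered with their time extents and
dominant frequencies; on a simulated 202-subject cohort the band count
separates the two response groups with AUC ≈ 0.72 — higher counts
(polyphonic, multi-band wheezing) predict wheezing that does *not*
disappear after inhalation.

A CLI mirrors the stages
(`wheezekit synthesize|detect|indexes|simulate|roc|stats|run`); see
`wheezekit run --print-config` for every default.

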