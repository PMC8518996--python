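# Methods

## The analysis problem

Wheezing in young children is assessed by auscultation, but whether it
will resolve after an inhaled β2-agonist is hard to judge at home. On a
lung-sound spectrogram a wheeze appears as a persistent narrow ridge of
spectral power — a *wheeze power band*. Monophonic wheezing produces one
band; polyphonic wheezing, reflecting multiple narrowed airways,
produces several simultaneous bands. The working hypothesis encoded in
this package is that recordings with many bands per 30 s indicate
obstruction that is less likely to resolve after bronchodilator
inhalation, so the pre-inhalation band count can be evaluated as a
diagnostic test for non-response.

Because no patient audio or per-subject data are available, the package
pairs the analysis chain with generators that emulate the study
conditions: synthetic chest audio with known injected wheezes, and
parametric cohorts matching the published per-group index distributions.

## Signal chain

**Preprocessing.** Lung audio is resampled (polyphase, anti-aliased) to
44.1 kHz and high-pass filtered at 50 Hz (4th-order Butterworth,
zero-phase) to remove DC drift and heart-sound rumble. An optional
ambient channel is resampled but not filtered.

**Spectrogram.** 4096-point FFT of Hann-windowed frames (window 4096
samples ≈ 92.9 ms, hop 1024 ≈ 23.2 ms, 75 % overlap), giving a bin
spacing of 44100/4096 ≈ 10.77 Hz. Power is expressed in dB relative to
the file maximum and floored at −120 dB. The relative-dB convention
makes the whole chain invariant to recording gain, which is
uncalibrated on chest microphones. The overlap is chosen so a 100-ms
event spans ≥ 4 frames, making the duration criterion resolvable. The
window function, overlap and dB reference are configurable; only the
FFT length is dictated by the recording protocol.

**Peak picking.** Within the search band (100–2500 Hz), a bin is a
candidate peak if it is a local maximum and exceeds the running median
of its ±250 Hz neighbourhood by at least `prominence_db` (default
18 dB). The running-median background adapts to the colored
breath-noise floor, so prominence is a local tonality measure. Frames
whose spectral flatness over the search band exceeds 0.75 are treated
as broadband artifact (e.g. microphone–skin friction, which the
original protocol removed by human review) and contribute no peaks;
this automated guard is a documented behavioural substitution for that
manual step.

The 18 dB default was calibrated against two properties of the
generator, never against a published number: on breath-noise-only
fixtures the detector must average ≤ 0.5 false bands per 30 s (measured
0 over 30 fixtures), and on white noise fewer than 5 % of frames may
carry any peak (measured ≈ 0.9 %). Lower prominence fails these
audits: because successive analysis windows overlap by 75 %, a single
noise excursion is correlated across ~4 frames and at 8–16 dB such
excursions occasionally chain into pseudo-ridges longer than 100 ms.

**Ridge linking.** Peaks are linked frame-to-frame by greedy
nearest-frequency matching: a peak joins an open ridge iff
|Δf| ≤ 50 Hz (≈ 5 bins per 23 ms hop, enough for vibrato and glides),
closest pairs first; ridges survive up to one missing frame; unmatched
peaks open new ridges. Simultaneous ridges at distinct frequencies stay
distinct, which is what makes polyphonic wheezing countable. A ridge
re-emerging after a longer gap is a new band — band identity over time
is otherwise undefined.

**Extent estimation.** The analysis window smears a tone into
neighbouring frames, so raw ridge extent overestimates duration by up
to a window length. Track membership is trimmed to frames within 8 dB
of the track's peak power, and the band's start/end are then refined by
linearly interpolating the −6 dB crossing of track power: −6 dB is the
half-amplitude point, reached when the window half-covers the tone
edge, so the crossing estimates the true onset/offset with sub-frame
resolution. On synthetic tone batches (150–600 ms, 200–800 Hz) this
keeps duration error within one hop (≈ 23 ms).

**Acceptance rules.** A ridge is a wheeze power band iff its dominant
(maximum-intensity) frequency exceeds 100 Hz and its duration exceeds
100 ms — the CORSA acoustic definition of a wheeze — with both
inequalities strict. Two further guards reject non-wheeze ridges:
`min_track_occupancy` (default 0.7) requires peaks in ≥ 70 % of the
spanned frames, operationalizing "continuous" and eliminating sparse
gap-bridged noise chains; and, when an ambient channel is present and
`ambient_veto_db` is set, a band whose ambient power is within that
margin of its lung-channel power over the band footprint is rejected as
environmental sound.

Time intervals are half-open [start, end), frames are 0-based, and
frame times are window centers.

## Wheeze indexes

Per recording: band count normalized per 30 s (count × 30/duration —
counts are continuous, so a non-integer decision cutoff on the count
scale is meaningful), mean band duration, and means over bands of the
lowest, highest and maximum-intensity track frequencies. Frequency and
duration summaries are NaN when no bands exist. "Lowest frequency" is
aggregated as a mean across bands, mirroring the aggregation explicitly
stated for the other frequency indexes.

## Synthetic data

**Audio.** The breath floor is pink-weighted Gaussian noise band-passed
100–1000 Hz, amplitude-modulated by a raised-cosine respiratory cycle
at 30 breaths/min (matching the cohorts' reported respiratory rates of
≈ 31/min), RMS level −30 dBFS, modulation depth 0.7 — a plausible
tidal-breathing floor whose purpose is to exercise false-positive
control, not to model airway acoustics. Each injected wheeze is a
harmonic stack (harmonics roll off at −6 dB per harmonic; default one
harmonic) with a linear frequency glide and 10-ms raised-cosine ramps.
SNR is defined as fundamental tone power over breath-noise power in a
±50 Hz band around the fundamental, measured on the actual generated
floor over the wheeze interval — a bandwidth-independent, reproducible
definition. The default fixture SNR of 25 dB represents a clearly
audible wheeze. Recordings are soft-normalized to ≤ 0.98 full scale and
are bit-identical under a fixed seed.

What the audio generator does **not** emulate: crackles, stridor and
heart sounds, airway-physical wheeze generation, inspiratory/expiratory
phase structure of real wheezes, microphone friction transients, or
room noise. Passing the recovery tests therefore demonstrates correct
ridge extraction under controlled tonal conditions, not clinical-grade
performance on patient audio.

**Cohorts.** Each group's five indexes are drawn independently per
subject from a normal with the group's published (mean, SD), truncated
at 0 (renormalized, sampled by inverse CDF through a Gaussian copula; a
correlation-matrix hook exists but defaults to identity since no
cross-index correlations were reported). Truncation at 0 raises sample
means above the model means by the closed-form truncated-normal offset
σφ(α)/(1−Φ(α)); tests verify this bias. Only mean ± SD were published,
so the generator cannot recover the true (likely right-skewed) shape of
the count distribution; this is a documented limitation, not a guess.
Covariates (age, height, weight, SaO2, heart rate, respiratory rate)
are carried with the published group summaries and drawn the same way,
independent of the indexes.

## Diagnostic evaluation

The positive class defaults to *non-disappear* with higher band counts
predicting it (that group has the higher count mean), and subjects are
called positive at score ≥ cutoff. The published
sensitivity/specificity pair is more consistent with the reverse
orientation, which `LabeledScores.higher_is_positive` exposes; the
discrepancy is left open rather than resolved. PPV/NPV use the cohort's
own prevalence.

ROC thresholds are the midpoints between consecutive distinct scores
plus ±∞ anchors, so every achievable 2×2 table appears exactly once.
The trapezoidal AUC equals the tie-corrected Mann–Whitney probability;
tests assert this identity against an exhaustive pairwise oracle and
against scikit-learn. SE(AUC) uses Hanley–McNeil with Q1 = A/(2−A),
Q2 = 2A²/(1+A) (the original method is unstated; this is the
field-standard default). Cutoff selection offers Youden's J (ties
broken toward the lower, more sensitive cutoff), a minimum-sensitivity
rule (largest cutoff with sensitivity ≥ target, for rule-out use), and
closest-to-top-left. The ROC sample-size solve uses a
normal-approximation test with Hanley–McNeil variances under the null
(AUC 0.5) and alternative, equal group sizes — one of several published
conventions, stated as such.

Group comparisons default to Welch's t (the groups' variances plainly
differ; pooled Student is available), two-sided, accepting raw samples
or (n, mean, SD) summaries; p-values come from the t distribution on
Welch–Satterthwaite df. Pearson correlations use the t transform on
n−2 df. No multiple-testing correction is applied, matching the
original analysis style.

## Pipeline and problem sizes

`run_pipeline` executes cohort simulation → per-subject audio synthesis
(injected count drawn from the subject's group count model, rounded and
capped at 25, the most that physically fit with non-overlap margins) →
detection → indexes → diagnostics → group tables, with all randomness
derived from one `SeedSequence`; identical config + seed reproduces
every artifact byte for byte. Each artifact records the package version
and a hash of the resolved configuration (output location excluded).

Default verification sizes were chosen to give tight Monte-Carlo error
at interactive runtimes: 100 seeded 30-s fixtures for detector
recovery, 25 noise-only fixtures for the false-positive floor, 200
simulated cohorts (202 subjects each) for the AUC reproduction, and a
20-subject end-to-end audio run.

## Known limitations

* The detector is calibrated for tonal wheezes ≥ a few dB above the
  local noise band; faint wheezes near the prominence threshold will be
  missed, and no claim is made about crackle/rhonchus discrimination.
* Inspiratory vs expiratory attribution is not implemented: no index in
  the evaluated set is phase-specific.
* The cohort generator reproduces first and second moments only; all
  downstream "reproductions" of group-level statistics inherit the
  normality-with-truncation assumption.
* The published cutoff (11.1 bands/30 s), its exact
  sensitivity/specificity pair, and the covariate tables derive from
  the real 202-child cohort and are not recoverable from summary
  statistics; the package reproduces the statistical machinery and the
  simulation-level AUC, not those exact operating-point numbers.
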