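# Methods

This note documents the models, parameter defaults and numerical
choices behind `murisleep`, and what the synthetic benchmarks do and do
not demonstrate about real recordings.

## Signal processing and scoring

**Filter.** The 0.5–29 Hz analog band-pass of typical rodent EEG rigs
(≥ 48 dB/octave) is realized digitally as an 8th-order Butterworth
band-pass applied forward-backward (`sosfiltfilt`).  Zero-phase
filtering avoids smearing state boundaries across epochs; the
forward-backward pass doubles the effective roll-off, which only
sharpens the specified attenuation.  EMG is deliberately left
unfiltered — its per-epoch RMS is the movement feature.

**Epoching and spectra.** Consecutive non-overlapping 4-s windows (256
samples at 64 Hz) are Fourier transformed with a rectangular window —
the plain "FFT on consecutive intervals" convention — giving 0.25 Hz
resolution.  The DC bin is excluded.  Band powers integrate the
periodogram by the trapezoid rule over each band's interval, inclusive
of boundary bins; the 5–6 and 9–10 Hz inter-band gaps belong to no
band.  Windowing/overlap and bin-aggregation conventions are the main
free choices here; tapered windows would trade bias for variance
without changing the threshold logic, since thresholds are re-fit on
whatever features result.

**Composite features.** The δ′ and θ′ composites are taken as
δ′ = (δ·α)/(η·β) and θ′ = θ²/(δ·α).  The product notation they are
usually written in is operator-ambiguous; this grouping is the one
consistent with the classifier's direction (NREMS drives δ′ up through
δ and down through the high-frequency denominator; REMS drives θ′ up
quadratically in θ while suppressing the δ·α denominator).  Both ratios
are degree-0 homogeneous in signal gain: amplifier scale factors (or
unit conversions such as µV↔V on EDF import) cancel exactly, so only
the EMG threshold has to adapt to gain, and it is re-fit per recording
anyway.  Epochs with a zero denominator are flagged indeterminate
(features NaN), excluded from threshold fitting, and inherit the
previous epoch's label at classification time (the first epoch defaults
to NREMS); inheriting preserves architecture continuity without
inventing a fifth state.

**Thresholds.** The original workflow sets three cursors by hand and
proof-reads the result; for reproducibility the package places each
threshold automatically by Otsu's between-class-variance criterion on
the log-feature histogram (256 bins), with manual override of any
subset.  Log transformation matters: the features are ratio-scaled and
strongly right-skewed, and class separation is multiplicative.
Degenerate (effectively single-valued) distributions fall back to the
median with a warning.  Thresholds are fit per recording; a pooled
per-animal mode can be had by fitting on concatenated feature tables.

**Microarousals.** After 3-state classification, maximal WAKE runs of
1–2 epochs (< 12 s) are relabeled MA.  Runs touching the recording
boundary are eligible (no stated exception), and the output by
construction contains no WAKE run shorter than 3 epochs.  No other
smoothing or hysteresis is applied.

## Architecture metrics

Zeitgeber hour h maps to phase via half-open intervals [0,6), [6,12),
[12,18), [18,24); the conventional whole-hour labels ("1–6 h" etc.)
name these blocks.  Occupancy is epoch counting; the 3-state summary
merges MA into WAKE, while episode/transition analyses keep 4 states.
Episodes are maximal runs; runs truncated by a slice boundary count and
are flagged, so either convention can be recovered downstream.  On any
untruncated slice, total off-diagonal transitions equal episodes − 1 (a
run-boundary identity the tests enforce).  State-conditional band AUCs
average the per-epoch trapezoid areas over epochs-in-state rather than
pooling spectra, which is robust to unequal state durations.  Baseline
normalization is 100 × value / baseline-group-mean; non-positive
baselines yield NaN with a warning rather than a misleading number.
The conditioning-day convention drops phase I (animals are out of the
recording cage).

## Synthetic data

**Hypnogram model.** Within each 6-h phase the 3-state sequence is a
Markov chain at epoch resolution with geometric bout lengths
(memoryless at the 4-s scale).  Given per-phase target occupancies π
and mean dwell times m (epochs), per-state exit flows a = π/m must
balance entry flows; the off-diagonal flow matrix is the max-entropy
solution with row and column sums a (Sinkhorn scaling with a zero
diagonal), which exists iff no state's flow exceeds the combined flow
of the others — violations raise a parameterization error rather than
silently distorting occupancies.  Geometric dwell is the simplest law
reproducing both occupancy and episode-count structure; real bout-length
distributions are heavier-tailed, which matters for bout-duration
statistics but not for the occupancy and count recoveries tested here.

**Calibration.** Default per-phase occupancies are the pooled
(both-groups) baseline percentages, each phase renormalized to sum
to 1 (the printed phase-IV means sum to 97.1%).  Default dwell means
(4-s epochs) are per phase — a single per-state value across phases is
mathematically infeasible for a stationary zero-diagonal chain at these
occupancies:

| state | I (dark) | II | III | IV (light) |
| --- | --- | --- | --- | --- |
| WAKE | 165 | 60 | 12 | 10 |
| NREMS | 25 | 30 | 30 | 30 |
| REMS | 2 | 8 | 13 | 13 |

i.e. ~11-min consolidated dark-phase wake bouts, ~2-min NREMS bouts,
and ~50-s light-phase REMS bouts, giving ≈ 35 phase-IV REMS episodes
per day — the scale of the episode-count trait below.

**Signals.** Per epoch, EEG is built in the frequency domain:
independent complex-Gaussian rFFT coefficients whose per-bin variance
follows the state's relative band weights (WAKE 0.20/0.40/0.15/0.15/0.10,
NREMS 0.60/0.15/0.12/0.08/0.05, REMS 0.15/0.55/0.12/0.10/0.08 over
δ/θ/α/η/β), so measured band powers fluctuate with the natural
chi-squared statistics of noise periodograms.  EMG is white noise with
RMS 3.0 (WAKE), 0.5 (NREMS), 0.3 (REMS, atonia).  Epochs are
spectrally independent; there are no spindles, K-complexes, phasic REM
events, artifacts or hardware noise.  Consequently the ≥ 90% scoring
accuracies achieved on this ground truth demonstrate correctness of the
pipeline's mechanics and calibration, not expected performance on real
mouse EEG, where manual proof-reading exists for a reason.

**Cohort model.** Per animal, five standard-normal latent traits
(episode count, NREMS→REMS transitions, ASR, day-1 change, day-55
change) are drawn from a joint correlation matrix: episode/transition
traits correlate at 0.95 (they are mechanically near-identical
quantities; the matrix is verified positive semi-definite), ASR
correlates with them at 0.78/0.80 in the shocked group and 0 in
controls, and the two change traits correlate at √0.54.  Traits map
linearly to observables — episode count ≈ round(35 + 8z),
transitions ≈ round(32 + 7.5z), ASR@115 dB = 550 + 150z AU (controls
400 + 150z) — so sample correlations are unbiased for the configured
values up to integer rounding (attenuation < 0.001).  Post-shock
phase-IV REMS is multiplied by 1.5 ± 0.15 (shocked; the printed
sources show a clear elevation but no magnitude, so 50% is a
chosen-once realistic effect) and 1.0 ± 0.05 (controls), expressed as
% of baseline.  Freezing percentages are drawn independently of all
sleep traits in both groups (chamber 60 ± 15 vs 25 ± 10, etc.).  When
recordings are requested, each animal's phase-IV REMS dwell mean is
tuned so the expected ground-truth episode count matches its trait, and
post-shock occupancies carry the day's multiplier.

## Statistics

The multivariate group/day tests compute Wilks' Λ = |E| / |E + H| from
the error and hypothesis cross-product matrices of a general linear
model (group between subjects; day-vs-baseline difference transform
within subjects), with Rao's F approximation — exact for one-df
hypotheses and for ≤ 2 responses, and verified against an independent
MANOVA implementation in the tests.  Variables are tested in families
(occupancy | episodes | transitions | power, by name) to avoid the
collinearity of testing all architecture variables jointly; the
partition is configurable.  Univariate mixed-ANOVA follow-ups and
pairwise contrasts run only when a family's multivariate test reaches
α = 0.05, and are Bonferroni corrected: day-vs-baseline contrasts
(2 groups × 3 days, α′ = 0.05/6 ≈ 0.0083) and per-day group contrasts
(4 days, α′ = 0.0125).  No sphericity correction is applied to the
within-subject tests.  Correlations are reported without multiplicity
correction, matching the original small-n analysis; r² from the simple
OLS fit equals the squared Pearson r to machine precision.

Under null simulation (Gaussian noise, 2 variables × 4 days × 8 + 8
animals) the multivariate group test's rejection rate sits at the
nominal 5% within Monte-Carlo error (the test is exact under
normality); this is checked over 1000 simulations in the suite.

## Benchmark problem sizes

The recovery benchmarks use 8 animals × 24 h for the staging check
(matching the per-group cohort size) and 20 replicate cohorts of 2000
animals per group, Fisher-z averaged, for the correlation checks — the
replicate-averaged route keeps the Monte-Carlo standard error of r
below 0.003 so that recovered values reflect the generator's
calibration rather than sampling noise.

## Known limitations

* Geometric bout lengths and spectrally independent epochs are the
  simplest defensible choices; inter-epoch spectral continuity and
  heavy-tailed bouts are absent.
* The scorer has no artifact handling, referencing/montage logic or
  notch filtering; recordings are assumed clean and Zeitgeber-aligned.
* The EDF writer is minimal (16-bit, two channels, 1-s records) —
  sufficient for round trips with standard readers, not a general EDF+
  implementation.
* `rm_group_day_analysis` requires balanced complete cases, as the
  original repeated-measures design does; unbalanced data need a
  mixed-effects approach that is out of scope here.
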