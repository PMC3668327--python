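# murisleep

Mouse sleep-EEG staging, sleep-architecture quantification, and
trauma-cohort statistics — with a synthetic EEG/EMG/cohort generator so
the entire analysis chain is testable without animal recordings.

## Who this is for

Sleep neurophysiologists analyzing rodent EEG/EMG recordings in
fear-conditioning / PTSD-model designs: score vigilance states from raw
signals, quantify how sleep architecture changes across the light-dark
cycle and across experimental days, and test whether baseline REM-sleep
(REMS) continuity predicts post-trauma hyperarousal.

## The analysis

**Scoring.** EEG is band-pass filtered 0.5–29 Hz (zero-phase 8th-order
Butterworth, ≥ 48 dB/octave) and cut into consecutive 4-s epochs (256
samples at 64 Hz; rectangular-window FFT, 0.25 Hz resolution).  Band
powers are trapezoid-rule areas of the power spectrum over
δ (0.5–5 Hz), θ (6–9 Hz), α (10–15 Hz), η (16–22.5 Hz) and
β (23–31.75 Hz), and two composite ratios sharpen the NREMS/REMS
contrast:

```
δ′ = (δ·α) / (η·β)          θ′ = θ² / (δ·α)
```

Each epoch is classified in priority order: EMG RMS above the movement
threshold ⇒ WAKE; else δ′ below its threshold **and** θ′ above its
threshold ⇒ REMS; else NREMS.  WAKE runs shorter than 3 epochs (12 s)
are relabeled microarousals (MA).  Thresholds are placed automatically
on the bimodal log-feature histograms (Otsu criterion) with manual
override.

**Architecture.** The 24-h day is split into four 6-h Zeitgeber phases
(I–II dark/active, III–IV light/inactive).  Per phase and state the
package reports occupancy (% time), episode counts and mean durations
(maximal runs), the 4×4 transition-count matrix, state-conditional
band-power AUCs, and values normalized to a baseline group mean
(100% = baseline).

**Cohort statistics.** Group/day effects are tested per variable family
with Wilks'-lambda multivariate tests (between/within cross-product
matrices, Rao's F), followed — only when the multivariate test fires —
by univariate mixed ANOVAs and Bonferroni-corrected contrasts
(day-vs-baseline within group, α′ = 0.05/6 ≈ 0.008; group-per-day,
α′ = 0.05/4 = 0.0125).  Pearson/Spearman correlations (uncorrected) and
OLS r² link baseline phase-IV REMS continuity (episode counts,
NREMS→REMS transitions) to the 115-dB acoustic startle response (ASR).

**Synthesis.** Ground-truth hypnograms come from a phase-dependent
semi-Markov chain (geometric bouts, per-phase stationary occupancies
calibrated to pooled baseline values: ~77% dark-phase WAKE, ~65%/8.5%
light-phase NREMS/REMS).  Signals are state-conditional band-limited
Gaussian noise (delta-dominant NREMS, theta-dominant REMS, high-EMG
WAKE).  Cohorts embed a latent-trait correlation of ASR with baseline
REMS continuity in the shocked group only (r = 0.78 episodes, 0.80
transitions), a multiplicative post-shock phase-IV REMS elevation, and
correlated day-1/day-55 REMS changes (r² = 0.54).

## Worked example

```python
import numpy as np
from murisleep import (SimParams, simulate_recording, score_recording,
                       split_phases, state_occupancy)

params = SimParams(seed=1)
rec, truth = simulate_recording(params, n_days=1)   # 24 h EEG/EMG + ground truth
scored, thr, spectra = score_recording(rec)          # filter -> FFT -> thresholds -> MA

print(f"thresholds: EMG={thr.emg_thr:.3f}  delta'={thr.delta_thr:.2f}  theta'={thr.theta_thr:.2f}")
acc = np.mean(np.where(scored.states == "MA", "WAKE", scored.states) == truth.states)
print(f"epoch-wise accuracy vs ground truth: {acc:.1%}")
for phase, sl in split_phases(scored).items():
    occ = state_occupancy(sl, merge_ma=True)
    print(f"phase {phase:>3}: WAKE {occ['WAKE']:5.1f}%  NREMS {occ['NREMS']:5.1f}%  REMS {occ['REMS']:4.1f}%")
```

Output:

```
thresholds: EMG=0.581  delta'=8.23  theta'=1.28
epoch-wise accuracy vs ground truth: 99.9%
phase   I: WAKE  84.5%  NREMS  15.1%  REMS  0.4%
phase  II: WAKE  71.7%  NREMS  26.8%  REMS  1.5%
phase III: WAKE  28.7%  NREMS  64.8%  REMS  6.5%
phase  IV: WAKE  19.9%  NREMS  70.6%  REMS  9.6%
```

The thresholds were placed automatically on this recording's feature
histograms; the scored occupancies reproduce the dark/light sleep-wake
asymmetry the simulator was calibrated to (wake-dominated dark phases,
NREMS-dominated light phases with ~8–10% REMS).

A full study replica (two groups × four recording days, scoring,
architecture, normalization, statistics) runs from the shell:

```sh
murisleep run --out results/study --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `murisleep.core` | `Recording`, `Hypnogram`, state/phase/band conventions |
| `murisleep.preprocess` | band-pass filter, epoch FFT, band powers, δ′/θ′ |
| `murisleep.staging` | Otsu thresholds, rule classifier, MA relabeling |
| `murisleep.architecture` | phases, occupancy, episodes, transitions, AUC, normalization |
| `murisleep.behavior` | startle amplitudes, freezing fractions |
| `murisleep.stats` | Wilks RM analysis, t-tests, correlations, r² |
| `murisleep.synthetic` | hypnogram/signal/cohort generators |
| `murisleep.pipeline` | end-to-end study runs (`run_study`, `StudyConfig`) |
| `murisleep.benchmarks` | parameter-recovery experiments |
| `murisleep.io` | EDF/CSV recording and hypnogram I/O |
| `murisleep.cli` | `murisleep simulate / score / architecture / analyze / run` |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
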