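"""Synthetic ground truth: hypnograms, EEG/EMG signals, and trauma cohorts.

The hypnogram simulator is a phase-dependent semi-Markov chain on
{WAKE, NREMS, REMS}: within each 6-h Zeitgeber phase, bout lengths are
geometric with state-specific means and the between-state jump flows are
solved (max-entropy transportation) so the chain's stationary occupancy
matches the configured per-phase targets.  Signals are sums of
band-limited Gaussian noise whose per-band weights depend on the state
(delta-dominant NREMS, theta-dominant REMS, theta/mixed WAKE) plus a
per-state EMG noise floor (WAKE far above the sleep states, REM atonia
lowest).

The cohort simulator plants the study's statistical structure: a latent
Gaussian trait model couples baseline phase-IV REMS continuity (episode
count, NREMS-to-REMS transitions) to the post-trauma acoustic startle
response at 115 dB in the shocked group only, a multiplicative phase-IV
REMS elevation on post-shock days in shocked animals, and correlated
day-1/day-55 REMS changes (persistence).  Freezing is generated
independently of the sleep traits in both groups.

Default calibration follows the only printed quantitative description of
baseline mouse sleep in this design: per-phase WAKE/NREMS/REMS
percentages pooled over both experimental groups, ~77% dark-phase WAKE
and ~65%/8.5% light-phase NREMS/REMS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    BANDS,
    EPOCH_LEN_S,
    SAMPLING_RATE,
    Hypnogram,
    ParameterError,
    Recording,
    phase_of_hour,
)

PHASE_LABELS = ("I", "II", "III", "IV")
SIM_STATES = ("WAKE", "NREMS", "REMS")

# Pooled per-phase baseline occupancies (% of time; mean of the shocked and
# non-shocked group means), renormalized so each phase sums to 1.
_POOLED_OCCUPANCY_PCT = {
    "I": {"WAKE": (83.0 + 89.6) / 2, "NREMS": (16.4 + 10.3) / 2, "REMS": (0.6 + 0.2) / 2},
    "II": {"WAKE": (67.8 + 68.4) / 2, "NREMS": (30.0 + 30.0) / 2, "REMS": (2.3 + 1.6) / 2},
    "III": {"WAKE": (28.0 + 24.5) / 2, "NREMS": (63.6 + 66.4) / 2, "REMS": (8.5 + 9.1) / 2},
    "IV": {"WAKE": (22.2 + 24.1) / 2, "NREMS": (65.9 + 65.5) / 2, "REMS": (8.9 + 7.6) / 2},
}


def default_phase_occupancy() -> dict[str, dict[str, float]]:
    """Pooled baseline occupancy targets, normalized to sum to 1 per phase."""
    out = {}
    for phase, occ in _POOLED_OCCUPANCY_PCT.items():
        total = sum(occ.values())
        out[phase] = {s: v / total for s, v in occ.items()}
    return out


# Mean bout lengths in 4-s epochs, per state and phase.  Dark-phase WAKE is
# highly consolidated (many-minute bouts); light-phase REMS bouts run ~1 min.
# A single per-state value across all phases cannot satisfy the stationary
# flow balance at the target occupancies, hence the per-phase maps.
DEFAULT_DWELL_MEANS: dict[str, dict[str, float]] = {
    "WAKE": {"I": 165.0, "II": 60.0, "III": 12.0, "IV": 10.0},
    "NREMS": {"I": 25.0, "II": 30.0, "III": 30.0, "IV": 30.0},
    "REMS": {"I": 2.0, "II": 8.0, "III": 13.0, "IV": 13.0},
}

# Relative power weights over (delta, theta, alpha, eta, beta).
DEFAULT_BAND_PROFILES: dict[str, tuple[float, ...]] = {
    "WAKE": (0.20, 0.40, 0.15, 0.15, 0.10),
    "NREMS": (0.60, 0.15, 0.12, 0.08, 0.05),
    "REMS": (0.15, 0.55, 0.12, 0.10, 0.08),
}

# EMG RMS scales (arbitrary units): muscle tone awake >> NREMS > REM atonia.
DEFAULT_EMG_LEVELS: dict[str, float] = {"WAKE": 3.0, "NREMS": 0.5, "REMS": 0.3}


def _per_phase(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {p: float(value[p]) for p in PHASE_LABELS}
    return {p: float(value) for p in PHASE_LABELS}


@dataclass
class SimParams:
    """Parameters of the hypnogram/signal simulator.

    ``dwell_means`` values may be scalars (same mean bout length in every
    phase) or per-phase maps.
    """

    sampling_rate: float = SAMPLING_RATE
    epoch_len: float = EPOCH_LEN_S
    phase_occupancy: dict[str, dict[str, float]] = field(default_factory=default_phase_occupancy)
    dwell_means: dict[str, dict[str, float] | float] = field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_DWELL_MEANS.items()}
    )
    band_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PROFILES)
    )
    emg_levels: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMG_LEVELS))
    eeg_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for phase in PHASE_LABELS:
            occ = self.phase_occupancy.get(phase)
            if occ is None:
                raise ParameterError(f"phase_occupancy missing phase {phase}")
            vals = [occ.get(s, 0.0) for s in SIM_STATES]
            if any(v < 0 or v > 1 for v in vals):
                raise ParameterError(f"phase {phase}: occupancy fractions outside [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ParameterError(
                    f"phase {phase}: occupancy fractions sum to {sum(vals)!r}, not 1"
                )
        self.dwell_means = {s: _per_phase(self.dwell_means[s]) for s in SIM_STATES}
        for s, per_phase in self.dwell_means.items():
            if any(m < 1.0 for m in per_phase.values()):
                raise ParameterError(f"dwell mean for {s} below 1 epoch")
        if any(v <= 0 for v in self.emg_levels.values()):
            raise ParameterError("EMG levels must be strictly positive")
        if self.emg_levels["WAKE"] <= max(self.emg_levels["NREMS"], self.emg_levels["REMS"]):
            raise ParameterError("WAKE EMG level must exceed both sleep-state levels")
        for s, prof in self.band_profiles.items():
            if len(prof) != len(BAND_NAMES):
                raise ParameterError(f"band profile for {s} must have {len(BAND_NAMES)} weights")
            if any(w < 0 for w in prof):
                raise ParameterError(f"band profile for {s} has negative weights")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_len * self.sampling_rate))

    @property
    def epochs_per_phase(self) -> int:
        return int(round(6 * 3600 / self.epoch_len))

    def copy_with(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


def _solve_flows(exit_rates: np.ndarray, tol: float = 1e-13, max_iter: int = 50_000) -> np.ndarray:
    """Zero-diagonal nonnegative flow matrix with row sums = col sums = exit_rates.

    Max-entropy solution by Sinkhorn scaling.  Feasible iff the largest
    exit rate does not exceed the sum of the others.
    """
    a = np.asarray(exit_rates, dtype=float)
    k = a.size
    if k == 1:
        return np.zeros((1, 1))
    total = a.sum()
    if a.max() > total - a.max() + 1e-12 * total:
        raise ParameterError(
            "infeasible occupancy/dwell combination: one state's entry/exit flow "
            f"({a.max():.3g}) exceeds the combined flow of the others "
            f"({total - a.max():.3g}); shorten its dwell mean or lower its occupancy"
        )
    mask = 1.0 - np.eye(k)
    F = np.outer(a, a) / total * mask
    for _ in range(max_iter):
        F *= (a / np.maximum(F.sum(axis=1), 1e-300))[:, None]
        F *= a / np.maximum(F.sum(axis=0), 1e-300)
        if np.abs(F.sum(axis=1) - a).max() <= tol * max(total, 1e-300):
            return F
    raise ParameterError("flow solver failed to converge (near-infeasible parameters)")


def transition_matrix_for_phase(params: SimParams, phase: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-epoch transition matrix with the configured stationary occupancy.

    Returns ``(P, pi, states)`` restricted to states with nonzero occupancy
    in this phase.
    """
    occ = params.phase_occupancy[phase]
    states = [s for s in SIM_STATES if occ.get(s, 0.0) > 0.0]
    pi = np.array([occ[s] for s in states])
    pi = pi / pi.sum()
    m = np.array([params.dwell_means[s][phase] for s in states])
    exit_rates = pi / m
    F = _solve_flows(exit_rates)
    P = F / pi[:, None]
    np.fill_diagonal(P, 1.0 - 1.0 / m)
    return P, pi, states


def simulate_hypnogram(params: SimParams, n_days: int = 1, seed: int | None = None) -> Hypnogram:
    """Ground-truth 3-state hypnogram over ``n_days`` full 24-h days.

    A phase-dependent Markov chain with geometric bout lengths whose
    stationary occupancy per phase equals ``params.phase_occupancy``.
    """
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    per_phase = {p: transition_matrix_for_phase(params, p) for p in PHASE_LABELS}
    epp = params.epochs_per_phase
    n_epochs = 4 * epp * n_days
    phase_idx = (np.arange(n_epochs) // epp) % 4

    # map each phase's local state indices onto the global 3-state alphabet
    state_names = np.array(SIM_STATES)
    labels = np.empty(n_epochs, dtype="U5")
    u = rng.random(n_epochs)

    cum = {}
    local_of_global = {}
    for p, (P, pi, states) in per_phase.items():
        cum[p] = (np.cumsum(P, axis=1), np.cumsum(pi), states)
        local_of_global[p] = {s: i for i, s in enumerate(states)}

    current: str | None = None
    for i in range(n_epochs):
        p = PHASE_LABELS[phase_idx[i]]
        cumP, cum_pi, states = cum[p]
        if current is None or current not in local_of_global[p]:
            # recording start, or entering a phase where the current state
            # has zero occupancy: redraw from the phase's stationary law
            j = int(np.searchsorted(cum_pi, u[i], side="right"))
            j = min(j, len(states) - 1)
        else:
            row = cumP[local_of_global[p][current]]
            j = int(np.searchsorted(row, u[i], side="right"))
            j = min(j, len(states) - 1)
        current = states[j]
        labels[i] = current
    return Hypnogram(labels, epoch_len=params.epoch_len, zeitgeber_start=0.0, provenance="true")


def _band_bin_amplitudes(params: SimParams, freqs: np.ndarray) -> dict[str, np.ndarray]:
    """Per-rFFT-bin amplitude scale for each state's band profile."""
    amps = {}
    for state, prof in params.band_profiles.items():
        a = np.zeros_like(freqs)
        for w, name in zip(prof, BAND_NAMES):
            low, high = BANDS[name]
            m = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
            n_bins = int(m.sum())
            if n_bins and w > 0:
                a[m] = math.sqrt(w / n_bins)
        amps[state] = a
    return amps


def synthesize_signals(
    hypnogram: Hypnogram, params: SimParams, seed: int | None = None
) -> Recording:
    """EEG/EMG for a hypnogram: band-weighted Gaussian noise per epoch.

    Each 4-s epoch's EEG is built in the frequency domain — independent
    complex-Gaussian coefficients whose per-bin variance follows the
    state's band profile — so measured band powers fluctuate naturally
    around the configured weights.  EMG is white noise at the state's RMS
    scale.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    if abs(hypnogram.epoch_len - params.epoch_len) > 1e-9:
        raise ValueError(
            f"hypnogram epoch length {hypnogram.epoch_len} s does not match "
            f"params.epoch_len {params.epoch_len} s"
        )
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    win = params.epoch_samples
    n = hypnogram.n_epochs
    freqs = np.fft.rfftfreq(win, d=1.0 / params.sampling_rate)
    amps = _band_bin_amplitudes(params, freqs)

    # microarousals carry WAKE physiology
    states = np.where(hypnogram.states == "MA", "WAKE", hypnogram.states)
    amp_matrix = np.stack([amps.get(s, np.zeros_like(freqs)) for s in SIM_STATES])
    lookup = {s: i for i, s in enumerate(SIM_STATES)}
    idx = np.array([lookup[s] for s in states])

    coef = rng.standard_normal((n, freqs.size)) + 1j * rng.standard_normal((n, freqs.size))
    coef[:, 0] = 0.0  # no DC
    coef *= amp_matrix[idx]
    eeg = np.fft.irfft(coef, n=win, axis=1) * params.eeg_scale * math.sqrt(win)

    emg_scale = np.array([params.emg_levels[s] for s in SIM_STATES])[idx]
    emg = rng.standard_normal((n, win)) * emg_scale[:, None]

    return Recording(
        eeg=eeg.ravel(),
        emg=emg.ravel(),
        sampling_rate=params.sampling_rate,
        zeitgeber_offset=hypnogram.zeitgeber_start,
    )


def simulate_recording(
    params: SimParams, n_days: int = 1, seed: int | None = None
) -> tuple[Recording, Hypnogram]:
    """Convenience: hypnogram plus matching signals from one seed."""
    base = params.seed if seed is None else seed
    hyp = simulate_hypnogram(params, n_days=n_days, seed=base)
    rec = synthesize_signals(hyp, params, seed=base + 1)
    return rec, hyp


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_FREEZING_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    # context -> group -> (mean %, SD %)
    "cylinder": {"shocked": (30.0, 12.0), "non_shocked": (15.0, 8.0)},
    "tone": {"shocked": (30.0, 12.0), "non_shocked": (15.0, 8.0)},
    "hexagon": {"shocked": (35.0, 12.0), "non_shocked": (20.0, 10.0)},
    "chamber": {"shocked": (60.0, 15.0), "non_shocked": (25.0, 10.0)},
}

STARTLE_INTENSITIES = ("control", 75, 90, 105, 115)
# mean startle output (arbitrary units) per intensity, before the
# animal-specific hyperarousal scaling applied at 115 dB
_ASR_CURVE = {"control": 40.0, 75: 120.0, 90: 220.0, 105: 380.0}


@dataclass
class CohortParams:
    """Trauma-cohort generator settings.

    The trait correlations are the quantities the downstream correlation
    analysis is meant to recover: baseline phase-IV REMS episode count vs
    115-dB startle (``rho_rems_asr``), NREMS-to-REMS transitions vs
    startle (``rho_transitions_asr``), and day-1 vs day-55 REMS change
    (``persistence_rho``).  Controls use ``rho_controls`` for both sleep
    traits.
    """

    n_per_group: int = 8
    rho_rems_asr: float = 0.78
    rho_transitions_asr: float = 0.80
    rho_controls: float = 0.0
    rho_episode_transition: float = 0.95
    rems_shock_effect: float = 1.5
    rems_effect_sd: float = 0.15
    persistence_rho: float = math.sqrt(0.54)
    episode_mean: float = 35.0
    episode_sd: float = 8.0
    transition_mean: float = 32.0
    transition_sd: float = 7.5
    asr_mean_shocked: float = 550.0
    asr_mean_control: float = 400.0
    asr_noise_sd: float = 150.0
    freezing_params: dict = field(
        default_factory=lambda: {c: dict(g) for c, g in DEFAULT_FREEZING_PARAMS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_rems_asr", "rho_transitions_asr", "rho_controls",
                     "rho_episode_transition", "persistence_rho"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [-1, 1]")
        if self.rems_shock_effect < 1.0:
            raise ParameterError("rems_shock_effect must be >= 1 for the shocked group")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")


def _trait_correlation(cp: CohortParams, shocked: bool) -> np.ndarray:
    """Correlation over latent traits (episode, transition, ASR, day1, day55)."""
    r_e = cp.rho_rems_asr if shocked else cp.rho_controls
    r_t = cp.rho_transitions_asr if shocked else cp.rho_controls
    r_et = cp.rho_episode_transition
    r_p = cp.persistence_rho
    C = np.eye(5)
    C[0, 1] = C[1, 0] = r_et
    C[0, 2] = C[2, 0] = r_e
    C[1, 2] = C[2, 1] = r_t
    C[3, 4] = C[4, 3] = r_p
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ParameterError(
            "requested trait correlations do not form a positive semi-definite matrix"
        )
    return C


POST_SHOCK_DAYS = ("day0", "day1", "day55")


def simulate_cohort(
    cp: CohortParams,
    sp: SimParams | None = None,
    days: tuple[str, ...] = ("baseline",),
    make_recordings: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Cohort table and, optionally, per-animal recordings for each day.

    Returns ``(table, recordings)``; ``recordings`` maps
    ``(animal, day) -> (Recording, Hypnogram)`` and is empty unless
    ``make_recordings`` is set.  Valid day labels: ``baseline``, ``day0``,
    ``day1``, ``day55``.
    """
    sp = sp if sp is not None else SimParams(seed=cp.seed)
    bad_days = set(days) - ({"baseline"} | set(POST_SHOCK_DAYS))
    if bad_days:
        raise ParameterError(f"unknown day labels: {sorted(bad_days)}")
    ss = np.random.SeedSequence(cp.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    rows = []
    rec_seeds = {}
    for group, shocked in (("shocked", True), ("non_shocked", False)):
        C = _trait_correlation(cp, shocked)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(5))
        Z = rng.standard_normal((cp.n_per_group, 5)) @ L.T
        z0 = rng.standard_normal(cp.n_per_group)  # day-0 REMS response noise
        for i in range(cp.n_per_group):
            animal = f"{'s' if shocked else 'c'}{i + 1:03d}"
            episodes = max(1, round(cp.episode_mean + cp.episode_sd * Z[i, 0]))
            transitions = max(0, round(cp.transition_mean + cp.transition_sd * Z[i, 1]))
            asr_mean = cp.asr_mean_shocked if shocked else cp.asr_mean_control
            asr115 = asr_mean + cp.asr_noise_sd * Z[i, 2]
            if shocked:
                mult = {
                    "day0": cp.rems_shock_effect + cp.rems_effect_sd * z0[i],
                    "day1": cp.rems_shock_effect + cp.rems_effect_sd * Z[i, 3],
                    "day55": cp.rems_shock_effect + cp.rems_effect_sd * Z[i, 4],
                }
            else:
                mult = {
                    "day0": 1.0 + 0.05 * z0[i],
                    "day1": 1.0 + 0.05 * Z[i, 3],
                    "day55": 1.0 + 0.05 * Z[i, 4],
                }
            mult = {d: max(0.1, m) for d, m in mult.items()}
            row = {
                "animal": animal,
                "group": group,
                "rems_episodes_iv": episodes,
                "nrems_to_rems_transitions_iv": transitions,
                "asr_115": asr115,
            }
            scale = asr115 / (cp.asr_mean_shocked if shocked else cp.asr_mean_control)
            for inten, base in _ASR_CURVE.items():
                row[f"asr_{inten}"] = max(0.0, base * scale + 0.1 * base * rng.standard_normal())
            for context, by_group in cp.freezing_params.items():
                mu, sd = by_group[group]
                row[f"freezing_{context}"] = float(np.clip(mu + sd * rng.standard_normal(), 0.0, 100.0))
            for d in POST_SHOCK_DAYS:
                row[f"rems_change_{d}"] = 100.0 * mult[d]
            rows.append(row)
            rec_seeds[animal] = (mult, episodes)

    table = pd.DataFrame(rows)

    recordings: dict = {}
    if make_recordings:
        child = ss.spawn(len(table) * len(days))
        k = 0
        for _, row in table.iterrows():
            animal = row["animal"]
            mult, episodes = rec_seeds[animal]
            for day in days:
                sp_animal = _animal_params(sp, cp, episodes, mult.get(day, 1.0) if day != "baseline" else 1.0)
                seed_pair = int(child[k].generate_state(1)[0] % (2**31))
                hyp = simulate_hypnogram(sp_animal, n_days=1, seed=seed_pair)
                rec = synthesize_signals(hyp, sp_animal, seed=seed_pair + 1)
                recordings[(animal, day)] = (rec, hyp)
                k += 1
    return table, recordings


def _animal_params(sp: SimParams, cp: CohortParams, episodes: int, rems_mult: float) -> SimParams:
    """Per-animal SimParams: phase-IV REMS dwell tuned to the target episode
    count, and the phase-IV REMS occupancy scaled by the day's multiplier."""
    occ = {p: dict(o) for p, o in sp.phase_occupancy.items()}
    r = occ["IV"]["REMS"] * rems_mult
    r = min(r, 0.5)
    rest = 1.0 - r
    other = occ["IV"]["WAKE"] + occ["IV"]["NREMS"]
    occ["IV"] = {
        "WAKE": occ["IV"]["WAKE"] / other * rest,
        "NREMS": occ["IV"]["NREMS"] / other * rest,
        "REMS": r,
    }
    epochs_iv = sp.epochs_per_phase
    dwell = {s: dict(d) for s, d in sp.dwell_means.items()}
    dwell["REMS"]["IV"] = max(1.0, epochs_iv * r / max(episodes, 1))
    return sp.copy_with(phase_occupancy=occ, dwell_means=dwell)


def simulate_startle_session(
    asr_by_intensity: Mapping, seed: int = 0, fs: float = 1000.0,
    trial_s: float = 0.2, onset_s: float = 0.05,
) -> pd.DataFrame:
    """Trial-level startle session: 20 trials per intensity, 10 control trials.

    Each trial carries a response trace (sampled at ``fs``) whose peak in
    the 50 ms after stimulus onset is near the animal's mean amplitude for
    that intensity.  Returns a DataFrame with columns ``trial``,
    ``intensity``, ``onset_index``, ``trace``.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round(trial_s * fs))
    onset = int(round(onset_s * fs))
    trials = []
    for inten in STARTLE_INTENSITIES:
        n_trials = 10 if inten == "control" else 20
        mean_amp = float(asr_by_intensity[inten])
        for _ in range(n_trials):
            amp = max(0.0, mean_amp * (1.0 + 0.15 * rng.standard_normal()))
            trace = 0.02 * mean_amp * rng.standard_normal(n_samp)
            peak_at = onset + rng.integers(5, int(0.045 * fs))
            t = np.arange(n_samp)
            trace += amp * np.exp(-0.5 * ((t - peak_at) / (0.008 * fs)) ** 2)
            trials.append({"intensity": inten, "onset_index": onset, "trace": trace})
    order = rng.permutation(len(trials))
    out = pd.DataFrame([trials[i] for i in order])
    out.insert(0, "trial", np.arange(len(out)))
    return out


def simulate_freezing_log(freezing_pct: float, seed: int = 0, window_s: float = 180.0) -> list[tuple[float, float]]:
    """Freezing intervals totalling ~``freezing_pct`` % of the observation window."""
    rng = np.random.default_rng(seed)
    target = window_s * np.clip(freezing_pct, 0.0, 100.0) / 100.0
    intervals: list[tuple[float, float]] = []
    t = float(rng.uniform(0, 5))
    remaining = target
    while remaining > 0.5 and t < window_s - 0.5:
        bout = min(remaining, float(rng.gamma(2.0, 4.0)) + 0.5)
        end = min(t + bout, window_s)
        intervals.append((t, end))
        remaining -= end - t
        t = end + float(rng.uniform(1.0, 10.0))
    return intervals
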