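"""Sleep composition and architecture per Zeitgeber phase.

Occupancy (% time per state), episodes (maximal runs: counts and mean
durations), transition counts, state-conditional band-power AUCs
(trapezoid rule over each band's frequency interval), and normalization
of any metric to a baseline group mean (100% = baseline).

The 24-h day is tiled by the four half-open 6-h phases I: [0, 6),
II: [6, 12), III: [12, 18), IV: [18, 24) Zeitgeber hours; I-II are the
dark (active) phases, III-IV the light (inactive) phases.  On the
conditioning day the animals are out of the cage during phase I, so that
slice can be flagged excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BAND_NAMES, PHASES, STATES4, Hypnogram
from .preprocess import EpochSpectra, band_power
from .staging import _run_lengths


@dataclass(frozen=True)
class Episode:
    """Maximal run of one state: start epoch, length in epochs."""

    state: str
    start_epoch: int
    length_epochs: int
    truncated: bool = False  # clipped by a slice boundary

    @property
    def duration_s(self) -> float:
        return self.length_epochs * 4.0


def split_phases(h: Hypnogram, exclude_phase_I: bool = False) -> dict[str, Hypnogram]:
    """Slice a 24-h Zeitgeber-aligned hypnogram into the four 6-h phases.

    ``exclude_phase_I`` (conditioning day) drops phase I from the result.
    """
    if abs(h.zeitgeber_start) > 1e-9:
        raise ValueError(f"hypnogram must start at Zeitgeber 0, starts at {h.zeitgeber_start} h")
    if abs(h.duration_h - 24.0) > 1e-9:
        raise ValueError(
            f"hypnogram must span exactly 24 h, covers {h.duration_h:.3f} h "
            f"({h.n_epochs} epochs of {h.epoch_len:.0f} s)"
        )
    epp = h.n_epochs // 4
    out = {}
    for i, label in enumerate(PHASES):
        if label == "I" and exclude_phase_I:
            continue
        out[label] = h.slice_epochs(i * epp, (i + 1) * epp)
    return out


def state_occupancy(h_slice: Hypnogram, merge_ma: bool = False) -> dict[str, float]:
    """Percent of epochs per state; ``merge_ma`` folds MA into WAKE
    (the 3-state circle-diagram convention)."""
    if h_slice.n_epochs == 0:
        raise ValueError("empty hypnogram slice")
    states = h_slice.states
    if merge_ma:
        states = np.where(states == "MA", "WAKE", states)
        keys = ("WAKE", "NREMS", "REMS")
    else:
        keys = STATES4
    return {s: 100.0 * float(np.sum(states == s)) / states.size for s in keys}


def find_episodes(h_slice: Hypnogram) -> list[Episode]:
    """Maximal runs; the first and last runs are flagged as boundary-truncated."""
    starts, lengths, labels = _run_lengths(h_slice.states)
    n_runs = starts.size
    return [
        Episode(
            state=str(lab),
            start_epoch=int(s),
            length_epochs=int(ln),
            truncated=(i == 0 or i == n_runs - 1),
        )
        for i, (s, ln, lab) in enumerate(zip(starts, lengths, labels))
    ]


def episode_stats(h_slice: Hypnogram) -> pd.DataFrame:
    """Per-state episode count and mean duration (s)."""
    eps = find_episodes(h_slice)
    rows = []
    for state in STATES4:
        mine = [e for e in eps if e.state == state]
        rows.append(
            {
                "state": state,
                "episode_count": len(mine),
                "mean_duration_s": float(np.mean([e.duration_s for e in mine])) if mine else np.nan,
            }
        )
    return pd.DataFrame(rows)


def transition_counts(h_slice: Hypnogram) -> pd.DataFrame:
    """4x4 matrix of adjacent-epoch state changes (diagonal is zero)."""
    if h_slice.n_epochs < 2:
        raise ValueError("need at least 2 epochs to count transitions")
    a, b = h_slice.states[:-1], h_slice.states[1:]
    mat = pd.DataFrame(0, index=list(STATES4), columns=list(STATES4))
    changed = a != b
    for x, y in zip(a[changed], b[changed]):
        mat.loc[x, y] += 1
    return mat


def state_band_auc(
    spectra: EpochSpectra, h_slice: Hypnogram, state: str, band: str,
    epoch_offset: int = 0,
) -> float:
    """Mean over epochs-in-state of the band's trapezoid-rule spectral area.

    ``epoch_offset`` locates the slice's first epoch inside ``spectra``.
    Returns NaN when the state is absent from the slice.
    """
    if band not in BAND_NAMES:
        raise KeyError(f"unknown band {band!r}")
    sel = np.flatnonzero(h_slice.states == state) + epoch_offset
    if sel.size == 0:
        return float("nan")
    if sel.max() >= spectra.psd.shape[0]:
        raise ValueError("hypnogram slice extends past the available spectra")
    areas = band_power(spectra.psd[sel], spectra.freqs, band)
    return float(np.mean(areas))


def normalize_to_baseline(value: float, baseline_group_mean: float) -> float:
    """Express a metric as % of its baseline group mean (100 = baseline)."""
    if not np.isfinite(baseline_group_mean) or baseline_group_mean <= 0:
        warnings.warn(
            f"baseline group mean {baseline_group_mean!r} is not positive; "
            "normalized value undefined",
            stacklevel=2,
        )
        return float("nan")
    return 100.0 * value / baseline_group_mean


def summarize_architecture(
    h: Hypnogram,
    spectra: EpochSpectra | None = None,
    exclude_phase_I: bool = False,
) -> pd.DataFrame:
    """Tidy per-phase architecture table for one 24-h hypnogram.

    One row per (phase, state, metric): occupancy %, episode count, mean
    episode duration, per-partner transition counts, and (when spectra
    are given) band-power AUCs.
    """
    epp = h.n_epochs // 4
    rows = []
    for phase, h_slice in split_phases(h, exclude_phase_I=exclude_phase_I).items():
        offset = list(PHASES).index(phase) * epp
        occ = state_occupancy(h_slice)
        stats = episode_stats(h_slice).set_index("state")
        trans = transition_counts(h_slice)
        for state in STATES4:
            rows.append({"phase": phase, "state": state, "metric": "occupancy_pct",
                         "value": occ[state]})
            rows.append({"phase": phase, "state": state, "metric": "episode_count",
                         "value": float(stats.loc[state, "episode_count"])})
            rows.append({"phase": phase, "state": state, "metric": "mean_episode_duration_s",
                         "value": float(stats.loc[state, "mean_duration_s"])})
            for target in STATES4:
                if target != state:
                    rows.append({"phase": phase, "state": state,
                                 "metric": f"transitions_to_{target}",
                                 "value": float(trans.loc[state, target])})
            if spectra is not None:
                for band in BAND_NAMES:
                    rows.append({"phase": phase, "state": state,
                                 "metric": f"auc_{band}",
                                 "value": state_band_auc(spectra, h_slice, state, band,
                                                         epoch_offset=offset)})
    return pd.DataFrame(rows)
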