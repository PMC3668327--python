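"""Behavioral endpoints: acoustic startle amplitudes and freezing fractions.

Startle amplitude is the peak voltage output within the first 50 ms after
stimulus onset (signed maximum by default, the printed definition; an
absolute-value switch is provided).  Freezing is the percentage of a
3-min context exposure covered by immobility intervals, merged before
summation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STARTLE_WINDOW_S = 0.050
OBSERVATION_WINDOW_S = 180.0
TRIALS_PER_INTENSITY = 20
CONTROL_TRIALS = 10


def startle_amplitude(
    trace: np.ndarray, onset_index: int, fs: float, absolute: bool = False
) -> float:
    """Peak response in the half-open window [onset, onset + 50 ms)."""
    trace = np.asarray(trace, dtype=float)
    n_win = int(round(STARTLE_WINDOW_S * fs))
    if onset_index < 0 or onset_index + n_win > trace.size:
        raise ValueError(
            f"trace ({trace.size} samples) does not cover 50 ms after onset "
            f"index {onset_index} at {fs} Hz"
        )
    window = trace[onset_index : onset_index + n_win]
    return float(np.max(np.abs(window) if absolute else window))


def asr_summary(session: pd.DataFrame, fs: float, absolute: bool = False) -> dict:
    """Per-intensity mean startle amplitude for one animal's session.

    ``session`` needs columns ``intensity``, ``onset_index``, ``trace``;
    exactly 20 trials per startle intensity and 10 control trials are
    required.
    """
    out = {}
    for inten, grp in session.groupby("intensity", sort=False):
        expected = CONTROL_TRIALS if inten == "control" else TRIALS_PER_INTENSITY
        if len(grp) != expected:
            raise ValueError(
                f"intensity {inten!r}: expected {expected} trials, found {len(grp)}"
            )
        amps = [
            startle_amplitude(row["trace"], int(row["onset_index"]), fs, absolute=absolute)
            for _, row in grp.iterrows()
        ]
        out[inten] = float(np.mean(amps))
    return out


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Union of possibly overlapping (start, end) intervals."""
    ordered = sorted((float(a), float(b)) for a, b in intervals)
    merged: list[list[float]] = []
    for a, b in ordered:
        if b < a:
            raise ValueError(f"interval ({a}, {b}) ends before it starts")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def freezing_fraction(intervals, window_s: float = OBSERVATION_WINDOW_S) -> float:
    """Percent of the observation window spent freezing."""
    total = 0.0
    for a, b in merge_intervals(intervals):
        if a < -1e-9 or b > window_s + 1e-9:
            raise ValueError(f"interval ({a}, {b}) outside [0, {window_s}] s")
        total += b - a
    return 100.0 * total / window_s
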