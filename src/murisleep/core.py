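"""Core containers: recordings, hypnograms, state and phase conventions.

Vigilance states follow the rodent convention: WAKE, microarousal (MA,
a WAKE run shorter than 3 epochs = 12 s), non-REM sleep (NREMS) and REM
sleep (REMS).  The 24-h day is split into four 6-h Zeitgeber phases:
I and II cover the dark (active) period, III and IV the light (inactive)
period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: default scoring-epoch length in seconds
EPOCH_LEN_S = 4.0
#: default sampling rate in Hz
SAMPLING_RATE = 64.0
#: samples per scoring epoch at the default rate
EPOCH_SAMPLES = int(EPOCH_LEN_S * SAMPLING_RATE)

#: three-state alphabet used by the simulator and the raw classifier
STATES3 = ("WAKE", "NREMS", "REMS")
#: four-state alphabet after microarousal relabeling
STATES4 = ("WAKE", "MA", "NREMS", "REMS")

#: Zeitgeber phases as half-open hour intervals.  The printed whole-hour
#: labels (phase I = "Zeitgeber time 1-6 h", etc.) name these 6-h blocks.
PHASES = {"I": (0.0, 6.0), "II": (6.0, 12.0), "III": (12.0, 18.0), "IV": (18.0, 24.0)}
#: dark (active) and light (inactive) halves of the day
DARK_PHASES = ("I", "II")
LIGHT_PHASES = ("III", "IV")

#: EEG analysis bands in Hz: delta, theta, alpha, eta, beta.  The 5-6 and
#: 9-10 Hz gaps belong to no band.
BANDS = {
    "delta": (0.5, 5.0),
    "theta": (6.0, 9.0),
    "alpha": (10.0, 15.0),
    "eta": (16.0, 22.5),
    "beta": (23.0, 31.75),
}
BAND_NAMES = tuple(BANDS)


class ParameterError(ValueError):
    """Invalid or infeasible simulation/analysis parameters."""


@dataclass
class Recording:
    """Synchronized EEG/EMG time series on a Zeitgeber-aligned clock.

    Amplitudes are in arbitrary units (nominally microvolts for EEG).
    ``zeitgeber_offset`` maps sample 0 to Zeitgeber time in hours.
    """

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float = SAMPLING_RATE
    zeitgeber_offset: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("EEG and EMG must be 1-D arrays")
        if self.eeg.size != self.emg.size:
            raise ValueError(
                f"EEG and EMG lengths differ ({self.eeg.size} vs {self.emg.size})"
            )
        if self.sampling_rate <= 2 * BANDS["beta"][1]:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz below Nyquist for the "
                f"{BANDS['beta'][1]} Hz analysis band edge"
            )
        if not 0.0 <= self.zeitgeber_offset < 24.0:
            raise ValueError("zeitgeber_offset must be in [0, 24) hours")

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels.

    ``provenance`` distinguishes simulator ground truth (``"true"``) from
    classifier output (``"scored"``).
    """

    states: np.ndarray
    epoch_len: float = EPOCH_LEN_S
    zeitgeber_start: float = 0.0
    provenance: str = "true"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U5")
        bad = set(np.unique(self.states)) - set(STATES4)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def n_states(self) -> int:
        """3 before microarousal relabeling, 4 after."""
        return 4 if "MA" in self.states else 3

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_len / 3600.0

    @property
    def zeitgeber_hours(self) -> np.ndarray:
        """Zeitgeber hour (mod 24) at the start of each epoch."""
        hours = self.zeitgeber_start + np.arange(self.n_epochs) * self.epoch_len / 3600.0
        return np.mod(hours, 24.0)

    def slice_epochs(self, start: int, stop: int) -> "Hypnogram":
        zt = np.mod(self.zeitgeber_start + start * self.epoch_len / 3600.0, 24.0)
        return Hypnogram(
            self.states[start:stop],
            epoch_len=self.epoch_len,
            zeitgeber_start=zt,
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_index": np.arange(self.n_epochs),
                "zeitgeber_hour": self.zeitgeber_hours,
                "state": self.states,
            }
        )


def phase_of_hour(hour: float | np.ndarray) -> np.ndarray:
    """Map Zeitgeber hour(s) in [0, 24) to phase labels I-IV."""
    h = np.mod(np.asarray(hour, dtype=float), 24.0)
    idx = np.minimum((h // 6).astype(int), 3)
    return np.array(["I", "II", "III", "IV"])[idx]
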