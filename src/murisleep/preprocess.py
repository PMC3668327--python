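"""Filtering, epoching and per-epoch spectral features.

The EEG is zero-phase band-pass filtered 0.5-29 Hz (8th-order Butterworth,
>= 48 dB/octave roll-off), cut into consecutive 4-s epochs and Fourier
transformed with a plain rectangular window (256 samples at 64 Hz,
0.25 Hz resolution, no overlap, DC bin excluded).  Band powers are
trapezoid-rule areas of the power spectrum over the five analysis bands;
EMG root-mean-square is taken per epoch on the unfiltered EMG.

Two composite ratio features sharpen the NREMS/REMS contrast:

    delta' = (delta * alpha) / (eta * beta)
    theta' = theta**2 / (delta * alpha)

Both are degree-2 homogeneous in the signal amplitude's square, so an
overall gain change moves them by a common factor and leaves threshold
ordering intact.  Epochs with a zero denominator are flagged
``indeterminate`` (features NaN) rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import BANDS, BAND_NAMES, EPOCH_LEN_S, Recording

log = logging.getLogger(__name__)

#: band-pass edges in Hz and filter order (8 poles ~ 48 dB/octave)
BANDPASS = (0.5, 29.0)
FILTER_ORDER = 8

FEATURE_COLUMNS = (
    "epoch_index",
    "zeitgeber_hour",
    *BAND_NAMES,
    "emg_rms",
    "delta_comp",
    "theta_comp",
    "indeterminate",
)


@dataclass
class EpochSpectra:
    """Per-epoch features plus the underlying power spectra.

    ``frame`` has one row per epoch (columns ``FEATURE_COLUMNS``); ``psd``
    is the (n_epochs, n_freqs) periodogram matrix and ``freqs`` its
    frequency axis in Hz, kept so state-conditional band AUCs can be
    recomputed on any hypnogram slice.
    """

    frame: pd.DataFrame
    psd: np.ndarray
    freqs: np.ndarray

    @property
    def n_epochs(self) -> int:
        return len(self.frame)


def _butter_sos(fs: float):
    return signal.butter(FILTER_ORDER, BANDPASS, btype="bandpass", fs=fs, output="sos")


def bandpass_eeg(rec: Recording) -> Recording:
    """Zero-phase band-pass filter the EEG channel; the EMG is untouched."""
    sos = _butter_sos(rec.sampling_rate)
    # sosfiltfilt needs a minimum signal length for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording too short to filter ({rec.n_samples} samples, "
            f"need > {padlen})"
        )
    eeg = signal.sosfiltfilt(sos, rec.eeg)
    return rec.copy_with(eeg=eeg)


def band_power(psd: np.ndarray, freqs: np.ndarray, band: str) -> np.ndarray:
    """Trapezoid-rule area of the power spectrum over one band.

    Bins at the band's boundary frequencies are included; the 5-6 and
    9-10 Hz gaps belong to no band.  ``psd`` may be 1-D or (n_epochs, n_freqs).
    """
    low, high = BANDS[band]
    mask = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
    return np.trapezoid(np.atleast_2d(psd)[:, mask], freqs[mask], axis=1)


def epoch_spectra(rec: Recording) -> EpochSpectra:
    """Per-epoch periodograms, band powers and EMG RMS.

    A trailing partial epoch is dropped (logged).  The DC bin is excluded
    from the spectrum.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    win = int(round(EPOCH_LEN_S * rec.sampling_rate))
    n_epochs = rec.n_samples // win
    if n_epochs == 0:
        raise ValueError(f"recording shorter than one {EPOCH_LEN_S:.0f}-s epoch")
    dropped = rec.n_samples - n_epochs * win
    if dropped:
        log.info("dropping trailing partial epoch (%d samples)", dropped)

    eeg = rec.eeg[: n_epochs * win].reshape(n_epochs, win)
    emg = rec.emg[: n_epochs * win].reshape(n_epochs, win)

    freqs, psd = signal.periodogram(
        eeg, fs=rec.sampling_rate, window="boxcar", detrend=False, axis=1
    )
    freqs, psd = freqs[1:], psd[:, 1:]  # drop DC

    frame = pd.DataFrame({"epoch_index": np.arange(n_epochs)})
    frame["zeitgeber_hour"] = np.mod(
        rec.zeitgeber_offset + np.arange(n_epochs) * EPOCH_LEN_S / 3600.0, 24.0
    )
    for name in BAND_NAMES:
        frame[name] = band_power(psd, freqs, name)
    frame["emg_rms"] = np.sqrt(np.mean(emg**2, axis=1))
    frame["delta_comp"] = np.nan
    frame["theta_comp"] = np.nan
    frame["indeterminate"] = False
    return EpochSpectra(frame=frame, psd=psd, freqs=freqs)


def composite_features(spectra: EpochSpectra) -> EpochSpectra:
    """Fill the delta'/theta' composites; zero denominators flag the epoch."""
    f = spectra.frame
    denom_d = f["eta"].to_numpy() * f["beta"].to_numpy()
    denom_t = f["delta"].to_numpy() * f["alpha"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_comp = np.where(denom_d > 0, f["delta"].to_numpy() * f["alpha"].to_numpy() / denom_d, np.nan)
        theta_comp = np.where(denom_t > 0, f["theta"].to_numpy() ** 2 / denom_t, np.nan)
    f["delta_comp"] = delta_comp
    f["theta_comp"] = theta_comp
    f["indeterminate"] = ~(np.isfinite(delta_comp) & np.isfinite(theta_comp))
    n_bad = int(f["indeterminate"].sum())
    if n_bad:
        log.warning("%d epochs with zero-denominator composites flagged indeterminate", n_bad)
    return spectra
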