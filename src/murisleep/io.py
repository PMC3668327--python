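"""Reading and writing recordings, hypnograms and feature tables.

Recordings travel as two-channel EDF ("EEG", "EMG") or as plain CSV
(columns ``time_s``, ``eeg``, ``emg``).  EDF reading goes through MNE;
writing uses a minimal 16-bit EDF writer (one 1-s data record per
second, both channels).  Inputs not at the 64 Hz analysis rate are
polyphase-resampled on read (logged).
"""

from __future__ import annotations

import logging
import struct
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import SAMPLING_RATE, Hypnogram, Recording

log = logging.getLogger(__name__)


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def read_recording(
    path, format: str | None = None, zeitgeber_offset: float = 0.0,
    target_rate: float = SAMPLING_RATE,
) -> Recording:
    """Load a two-channel recording, resampling to the analysis rate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        eeg, emg, fs = _read_edf(path)
    elif fmt == "csv":
        eeg, emg, fs = _read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'edf' or 'csv')")
    if abs(fs - target_rate) > 1e-6:
        log.info("resampling %s from %g Hz to %g Hz (polyphase)", path.name, fs, target_rate)
        eeg = _resample(eeg, fs, target_rate)
        emg = _resample(emg, fs, target_rate)
        fs = target_rate
    return Recording(eeg=eeg, emg=emg, sampling_rate=fs, zeitgeber_offset=zeitgeber_offset)


def _read_edf(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {ch.upper(): ch for ch in raw.ch_names}
    missing = [want for want in ("EEG", "EMG") if want not in names]
    if missing:
        raise ValueError(f"{path.name}: missing {' and '.join(missing)} channel(s); "
                         f"found {raw.ch_names}")
    data = raw.get_data(picks=[names["EEG"], names["EMG"]])
    return data[0], data[1], float(raw.info["sfreq"])


def _read_csv(path: Path) -> tuple[np.ndarray, np.ndarray, float]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for want in ("time_s", "eeg", "emg"):
        if want not in cols:
            raise ValueError(f"{path.name}: missing {want.upper().replace('_S', '')} "
                             f"channel (need columns time_s, eeg, emg)")
    t = df[cols["time_s"]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: too few samples")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError(f"{path.name}: non-increasing time axis")
    return df[cols["eeg"]].to_numpy(float), df[cols["emg"]].to_numpy(float), 1.0 / dt


def write_recording_csv(rec: Recording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    pd.DataFrame({"time_s": t, "eeg": rec.eeg, "emg": rec.emg}).to_csv(path, index=False)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a two-channel 16-bit EDF file (channels "EEG", "EMG").

    One data record per second; a trailing partial second is dropped.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    channels = [("EEG", rec.eeg[: n_rec * spr]), ("EMG", rec.emg[: n_rec * spr])]
    ns = len(channels)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])

    phys = []
    digitized = []
    for _, x in channels:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys.append((lo, hi))
        scaled = (x - lo) / (hi - lo) * 65535.0 - 32768.0
        digitized.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))

    def per_signal(fmt_values, width):
        return b"".join(_edf_field(v, width) for v in fmt_values)

    header += per_signal([name for name, _ in channels], 16)
    header += per_signal(["" for _ in channels], 80)      # transducer
    header += per_signal(["uV" for _ in channels], 8)     # physical dimension
    header += per_signal([f"{lo:.6g}"[:8] for lo, _ in phys], 8)
    header += per_signal([f"{hi:.6g}"[:8] for _, hi in phys], 8)
    header += per_signal([-32768 for _ in channels], 8)
    header += per_signal([32767 for _ in channels], 8)
    header += per_signal(["" for _ in channels], 80)      # prefiltering
    header += per_signal([spr for _ in channels], 8)
    header += per_signal(["" for _ in channels], 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for d in digitized:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    h.to_frame().to_csv(path, index=False)


def read_hypnogram_csv(path, provenance: str = "scored") -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "zeitgeber_hour", "state"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    return Hypnogram(
        df["state"].to_numpy(dtype="U5"),
        zeitgeber_start=float(df["zeitgeber_hour"].iloc[0]),
        provenance=provenance,
    )
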