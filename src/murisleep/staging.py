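"""Threshold-based vigilance-state scoring.

Each 4-s epoch is classified from three features, in priority order:

1. EMG RMS above the movement threshold  -> WAKE
2. delta' below its threshold AND theta' above its threshold -> REMS
3. otherwise -> NREMS

WAKE runs shorter than 3 epochs (12 s) are then relabeled as
microarousals (MA).  Thresholds separating the bimodal log-feature
histograms are set automatically by Otsu's between-class-variance
criterion (with per-threshold manual override), replacing the original
workflow's manually placed cursors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import Hypnogram, Recording
from .preprocess import EpochSpectra, bandpass_eeg, composite_features, epoch_spectra

log = logging.getLogger(__name__)

MIN_EPOCHS_FOR_AUTO = 100


@dataclass(frozen=True)
class Thresholds:
    """Feature cut points separating the scoring classes.

    ``emg_thr`` splits movement from no movement, ``delta_thr`` high from
    low delta' (slow-wave) power, ``theta_thr`` high from low theta'
    power.  All are on the raw (not log) feature scale.
    """

    emg_thr: float
    delta_thr: float
    theta_thr: float
    method: str = "auto"

    def __post_init__(self) -> None:
        for name in ("emg_thr", "delta_thr", "theta_thr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")


def _otsu_log(values: np.ndarray, name: str) -> float:
    """Otsu split of log-feature values; quantile fallback when degenerate."""
    x = np.log(values[np.isfinite(values) & (values > 0)])
    if x.size == 0:
        raise ValueError(f"no positive finite values for {name}")
    if np.ptp(x) < 1e-12:
        warnings.warn(
            f"{name}: degenerate (single-valued) distribution; falling back to the median",
            stacklevel=3,
        )
        return float(np.exp(np.median(x)))
    return float(np.exp(threshold_otsu(x, nbins=256)))


def fit_thresholds(
    features: EpochSpectra | pd.DataFrame,
    emg_thr: float | None = None,
    delta_thr: float | None = None,
    theta_thr: float | None = None,
) -> Thresholds:
    """Automatic thresholds from the empirical log-feature histograms.

    Manual values override any subset; the result is marked ``manual``
    only if all three were supplied.
    """
    frame = features.frame if isinstance(features, EpochSpectra) else features
    usable = frame.loc[~frame["indeterminate"].astype(bool)]
    if len(usable) < MIN_EPOCHS_FOR_AUTO and None in (emg_thr, delta_thr, theta_thr):
        raise ValueError(
            f"need >= {MIN_EPOCHS_FOR_AUTO} epochs with finite features for automatic "
            f"thresholding, got {len(usable)}"
        )
    emg = emg_thr if emg_thr is not None else _otsu_log(usable["emg_rms"].to_numpy(), "emg_rms")
    delta = delta_thr if delta_thr is not None else _otsu_log(usable["delta_comp"].to_numpy(), "delta_comp")
    theta = theta_thr if theta_thr is not None else _otsu_log(usable["theta_comp"].to_numpy(), "theta_comp")
    method = "manual" if None not in (emg_thr, delta_thr, theta_thr) else "auto"
    return Thresholds(emg_thr=emg, delta_thr=delta, theta_thr=theta, method=method)


def classify_epochs(features: EpochSpectra | pd.DataFrame, thr: Thresholds) -> Hypnogram:
    """Rule-based 3-state classification of every epoch.

    Indeterminate epochs inherit the previous epoch's label (a leading
    indeterminate epoch defaults to NREMS, logged).
    """
    frame = features.frame if isinstance(features, EpochSpectra) else features
    emg = frame["emg_rms"].to_numpy(dtype=float)
    dc = frame["delta_comp"].to_numpy(dtype=float)
    tc = frame["theta_comp"].to_numpy(dtype=float)
    bad = frame["indeterminate"].to_numpy(dtype=bool)

    with np.errstate(invalid="ignore"):
        labels = np.where(
            emg > thr.emg_thr,
            "WAKE",
            np.where((dc < thr.delta_thr) & (tc > thr.theta_thr), "REMS", "NREMS"),
        ).astype("U5")
    if bad.any():
        if bad[0]:
            labels[0] = "NREMS"
            log.info("first epoch indeterminate; defaulting to NREMS")
        idx = np.where(bad)[0]
        for i in idx:
            if i > 0:
                labels[i] = labels[i - 1]
        log.info("%d indeterminate epochs inherited the previous label", bad.sum())

    zt = float(frame["zeitgeber_hour"].iloc[0]) if "zeitgeber_hour" in frame else 0.0
    return Hypnogram(labels, zeitgeber_start=zt, provenance="scored")


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start, length, label) of maximal constant runs."""
    n = states.size
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return starts, lengths, states[starts]


def mark_microarousals(h: Hypnogram) -> Hypnogram:
    """Relabel WAKE runs of 1-2 epochs as microarousals (MA).

    Runs of 3 or more epochs stay WAKE; runs truncated by the recording
    boundary are eligible.  The input must be 3-state.
    """
    if "MA" in h.states:
        raise ValueError("hypnogram already contains MA labels; expected 3-state input")
    states = h.states.copy()
    starts, lengths, labels = _run_lengths(states)
    for s, ln, lab in zip(starts, lengths, labels):
        if lab == "WAKE" and ln < 3:
            states[s : s + ln] = "MA"
    return Hypnogram(
        states, epoch_len=h.epoch_len, zeitgeber_start=h.zeitgeber_start, provenance=h.provenance
    )


def score_recording(
    rec: Recording, thr: Thresholds | None = None
) -> tuple[Hypnogram, Thresholds, EpochSpectra]:
    """Full scoring chain: filter, features, thresholds, classify, MA.

    Returns the 4-state hypnogram plus the thresholds used and the epoch
    features (for downstream band-power analyses).
    """
    filtered = bandpass_eeg(rec)
    spectra = composite_features(epoch_spectra(filtered))
    if thr is None:
        thr = fit_thresholds(spectra)
    log.info(
        "thresholds (%s): emg=%.4g delta'=%.4g theta'=%.4g; %d indeterminate epochs",
        thr.method, thr.emg_thr, thr.delta_thr, thr.theta_thr,
        int(spectra.frame["indeterminate"].sum()),
    )
    hyp = mark_microarousals(classify_epochs(spectra, thr))
    return hyp, thr, spectra
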