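import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from murisleep import SimParams, score_recording, simulate_recording
from murisleep.preprocess import EpochSpectra

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_features(emg_rms, delta_comp, theta_comp, indeterminate=None) -> EpochSpectra:
    """Hand-built feature table for classifier tests (no real spectra needed)."""
    n = len(emg_rms)
    frame = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "zeitgeber_hour": np.zeros(n),
            "delta": np.ones(n),
            "theta": np.ones(n),
            "alpha": np.ones(n),
            "eta": np.ones(n),
            "beta": np.ones(n),
            "emg_rms": np.asarray(emg_rms, dtype=float),
            "delta_comp": np.asarray(delta_comp, dtype=float),
            "theta_comp": np.asarray(theta_comp, dtype=float),
            "indeterminate": np.zeros(n, bool) if indeterminate is None else np.asarray(indeterminate, bool),
        }
    )
    return EpochSpectra(frame=frame, psd=np.zeros((n, 1)), freqs=np.array([1.0]))


@pytest.fixture(scope="session")
def baseline_day():
    """One simulated 24-h baseline recording, scored with auto thresholds."""
    params = SimParams(seed=42)
    rec, truth = simulate_recording(params, n_days=1)
    scored, thr, spectra = score_recording(rec)
    return {"params": params, "rec": rec, "truth": truth, "scored": scored,
            "thresholds": thr, "spectra": spectra}
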