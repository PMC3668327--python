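"""Threshold fitting, the scoring rule table, and microarousal relabeling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_features
from murisleep import (
    Recording,
    SimParams,
    Thresholds,
    classify_epochs,
    fit_thresholds,
    mark_microarousals,
    score_recording,
    synthesize_signals,
)
from murisleep.core import Hypnogram


def brute_force_otsu(x):
    """Exact minimum-within-class-variance split over all candidate cuts."""
    x = np.sort(x)
    best, best_cut = np.inf, None
    for i in range(1, x.size):
        lo, hi = x[:i], x[i:]
        wcv = lo.size * np.var(lo) + hi.size * np.var(hi)
        if wcv < best:
            best, best_cut = wcv, (x[i - 1] + x[i]) / 2
    return best_cut


class TestFitThresholds:
    def test_bimodal_emg_split_matches_brute_force(self):
        rng = np.random.default_rng(0)
        log_emg = np.concatenate([rng.normal(-0.7, 0.3, 400), rng.normal(1.1, 0.3, 300)])
        emg = np.exp(log_emg)
        spec = make_features(emg, np.full(700, 5.0), np.full(700, 5.0))
        thr = fit_thresholds(spec, delta_thr=1.0, theta_thr=1.0)
        cut = np.log(thr.emg_thr)
        assert -0.7 < cut < 1.1
        assert abs(cut - brute_force_otsu(log_emg)) < 0.15

    def test_degenerate_distribution_falls_back_with_warning(self):
        spec = make_features(np.full(200, 2.0), np.full(200, 3.0), np.full(200, 4.0))
        with pytest.warns(UserWarning, match="degenerate"):
            thr = fit_thresholds(spec)
        assert thr.emg_thr == pytest.approx(2.0)

    def test_manual_override_of_single_threshold(self):
        rng = np.random.default_rng(1)
        vals = np.exp(np.concatenate([rng.normal(0, 0.3, 200), rng.normal(3, 0.3, 200)]))
        spec = make_features(vals, vals, vals)
        thr = fit_thresholds(spec, emg_thr=123.0)
        assert thr.emg_thr == 123.0
        assert thr.method == "auto"  # not fully manual
        assert 1.0 < thr.delta_thr < np.exp(3)

    def test_too_few_epochs_raises(self):
        spec = make_features(np.ones(10), np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="epochs"):
            fit_thresholds(spec)


RULE_TABLE = {
    # (emg_high, delta_high, theta_high) -> state
    (True, True, True): "WAKE",
    (True, True, False): "WAKE",
    (True, False, True): "WAKE",
    (True, False, False): "WAKE",
    (False, True, True): "NREMS",
    (False, True, False): "NREMS",
    (False, False, True): "REMS",
    (False, False, False): "NREMS",
}


class TestClassify:
    def test_all_eight_threshold_side_combinations(self):
        thr = Thresholds(emg_thr=1.0, delta_thr=1.0, theta_thr=1.0, method="manual")
        combos = list(RULE_TABLE)
        emg = [2.0 if c[0] else 0.5 for c in combos]
        dc = [2.0 if c[1] else 0.5 for c in combos]
        tc = [2.0 if c[2] else 0.5 for c in combos]
        hyp = classify_epochs(make_features(emg, dc, tc), thr)
        assert list(hyp.states) == [RULE_TABLE[c] for c in combos]

    def test_indeterminate_epochs_inherit_previous_label(self):
        thr = Thresholds(emg_thr=1.0, delta_thr=1.0, theta_thr=1.0)
        spec = make_features(
            [np.nan, 2.0, np.nan, 0.5],
            [np.nan, 0.5, np.nan, 0.5],
            [np.nan, 2.0, np.nan, 2.0],
            indeterminate=[True, False, True, False],
        )
        hyp = classify_epochs(spec, thr)
        # first defaults NREMS; third inherits WAKE from second
        assert list(hyp.states) == ["NREMS", "WAKE", "WAKE", "REMS"]

    def test_determinism(self):
        rng = np.random.default_rng(2)
        spec = make_features(rng.gamma(2, 1, 500), rng.gamma(2, 1, 500), rng.gamma(2, 1, 500))
        thr = Thresholds(emg_thr=2.0, delta_thr=2.0, theta_thr=2.0)
        assert np.array_equal(classify_epochs(spec, thr).states,
                              classify_epochs(spec, thr).states)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        spec = make_features(rng.gamma(2, 1, 800), rng.gamma(2, 1, 800), rng.gamma(2, 1, 800))

        def counts(emg_thr=2.0, theta_thr=2.0):
            thr = Thresholds(emg_thr=emg_thr, delta_thr=2.0, theta_thr=theta_thr)
            s = classify_epochs(spec, thr).states
            return np.sum(s == "WAKE"), np.sum(s == "REMS")

        w_lo, _ = counts(emg_thr=1.0)
        w_hi, _ = counts(emg_thr=4.0)
        assert w_hi <= w_lo
        _, r_lo = counts(theta_thr=1.0)
        _, r_hi = counts(theta_thr=4.0)
        assert r_hi <= r_lo


class TestMicroarousals:
    @pytest.mark.parametrize(
        "before, after",
        [
            ("N W W N", "N MA MA N"),
            ("N W W W N", "N W W W N"),
            ("W W N", "MA MA N"),
            ("N N W", "N N MA"),
        ],
    )
    def test_short_wake_runs_become_ma(self, before, after):
        expand = {"N": "NREMS", "W": "WAKE", "R": "REMS", "MA": "MA"}
        hyp = Hypnogram([expand[s] for s in before.split()])
        out = mark_microarousals(hyp)
        assert list(out.states) == [expand[s] for s in after.split()]

    def test_four_state_input_rejected(self):
        with pytest.raises(ValueError, match="MA"):
            mark_microarousals(Hypnogram(["NREMS", "MA", "NREMS"]))

    @given(st.lists(st.sampled_from(["WAKE", "NREMS", "REMS"]), min_size=1, max_size=60))
    def test_output_never_contains_short_wake_runs(self, labels):
        out = mark_microarousals(Hypnogram(labels)).states
        run = 0
        for s in list(out) + ["END"]:
            if s == "WAKE":
                run += 1
            else:
                assert run == 0 or run >= 3
                run = 0

    @given(st.lists(st.sampled_from(["WAKE", "NREMS", "REMS"]), min_size=1, max_size=60))
    def test_sleep_epochs_untouched_and_ma_was_wake(self, labels):
        states = np.asarray(labels)
        out = mark_microarousals(Hypnogram(states)).states
        changed = states != out
        assert np.all(states[changed] == "WAKE")
        assert np.all(out[changed] == "MA")


class TestScoreRecording:
    def test_nrems_only_recording_scored_nrems(self, baseline_day):
        params = SimParams(seed=21)
        hyp = Hypnogram(np.repeat("NREMS", 1000))
        rec = synthesize_signals(hyp, params)
        scored, _, _ = score_recording(rec, baseline_day["thresholds"])
        assert np.mean(scored.states == "NREMS") >= 0.95

    def test_full_day_accuracy_against_ground_truth(self, baseline_day):
        truth = baseline_day["truth"].states
        pred = np.where(baseline_day["scored"].states == "MA", "WAKE",
                        baseline_day["scored"].states)
        assert np.mean(truth == pred) >= 0.90

    def test_empty_recording_raises(self):
        rec = Recording(eeg=np.array([]), emg=np.array([]))
        with pytest.raises(ValueError):
            score_recording(rec)

    def test_rems_nrems_confusion_shrinks_with_spectral_contrast(self):
        """Sharper theta/delta separation between REMS and NREMS lowers
        their mutual confusion."""
        base = dict(SimParams().band_profiles)
        confusions = []
        for contrast in (0.0, 0.5, 1.0):
            profiles = dict(base)
            # interpolate REMS profile between the NREMS profile (no
            # contrast) and the default REMS profile (full contrast)
            profiles["REMS"] = tuple(
                (1 - contrast) * n + contrast * r
                for n, r in zip(base["NREMS"], base["REMS"])
            )
            params = SimParams(band_profiles=profiles, seed=33)
            states = np.where(np.arange(2000) % 10 < 2, "REMS", "NREMS")
            hyp = Hypnogram(states)
            rec = synthesize_signals(hyp, params)
            scored, _, _ = score_recording(rec)
            confused = np.mean(scored.states[states == "REMS"] != "REMS")
            confusions.append(confused)
        assert confusions[2] <= confusions[1] <= confusions[0]
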