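"""Phase splitting, occupancy, episodes, transitions, band AUC, normalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from murisleep import (
    Hypnogram,
    find_episodes,
    episode_stats,
    normalize_to_baseline,
    phase_of_hour,
    split_phases,
    state_band_auc,
    state_occupancy,
    summarize_architecture,
    transition_counts,
)
from murisleep.preprocess import EpochSpectra

import pandas as pd


def hyp(*short):
    expand = {"N": "NREMS", "W": "WAKE", "R": "REMS", "M": "MA"}
    return Hypnogram([expand[s] for s in short])


def day_hypnogram(seed=0):
    rng = np.random.default_rng(seed)
    return Hypnogram(rng.choice(["WAKE", "NREMS", "REMS"], size=21600))


random_states = st.lists(
    st.sampled_from(["WAKE", "MA", "NREMS", "REMS"]), min_size=2, max_size=80
)


class TestPhases:
    def test_hour_to_phase_mapping(self):
        assert phase_of_hour(5.0) == "I"
        assert phase_of_hour(13.0) == "III"
        assert list(phase_of_hour([0.0, 6.0, 12.0, 18.0, 23.99])) == ["I", "II", "III", "IV", "IV"]

    def test_split_yields_four_six_hour_slices(self):
        phases = split_phases(day_hypnogram())
        assert set(phases) == {"I", "II", "III", "IV"}
        for label, sl in phases.items():
            assert sl.n_epochs == 5400
        assert phases["III"].zeitgeber_start == pytest.approx(12.0)

    def test_conditioning_day_phase_one_excluded(self):
        phases = split_phases(day_hypnogram(), exclude_phase_I=True)
        assert set(phases) == {"II", "III", "IV"}

    def test_short_recording_rejected(self):
        h = Hypnogram(np.repeat("WAKE", 23 * 900))  # 23 h
        with pytest.raises(ValueError, match="24 h"):
            split_phases(h)

    def test_misaligned_recording_rejected(self):
        h = Hypnogram(np.repeat("WAKE", 21600), zeitgeber_start=2.0)
        with pytest.raises(ValueError, match="Zeitgeber 0"):
            split_phases(h)


class TestOccupancy:
    def test_simple_counting(self):
        occ = state_occupancy(hyp("N", "N", "N", "R", "W", "W"))
        assert occ["NREMS"] == pytest.approx(50.0)
        assert occ["REMS"] == pytest.approx(100 / 6)
        assert occ["WAKE"] == pytest.approx(100 / 3)

    def test_single_state(self):
        assert state_occupancy(hyp("R", "R"))["REMS"] == 100.0

    def test_ma_merges_into_wake_for_three_state_summary(self):
        occ = state_occupancy(hyp("W", "M", "N", "N"), merge_ma=True)
        assert occ["WAKE"] == pytest.approx(50.0)
        assert "MA" not in occ

    @given(random_states)
    def test_fractions_sum_to_100(self, labels):
        occ = state_occupancy(Hypnogram(labels))
        assert sum(occ.values()) == pytest.approx(100.0)


class TestEpisodes:
    def test_counting_example(self):
        stats = episode_stats(hyp("R", "R", "N", "R")).set_index("state")
        assert stats.loc["REMS", "episode_count"] == 2
        assert stats.loc["REMS", "mean_duration_s"] == pytest.approx(6.0)

    def test_single_state_slice(self):
        stats = episode_stats(Hypnogram(np.repeat("NREMS", 7))).set_index("state")
        assert stats.loc["NREMS", "episode_count"] == 1
        assert stats.loc["NREMS", "mean_duration_s"] == pytest.approx(28.0)

    def test_boundary_runs_flagged_truncated(self):
        eps = find_episodes(hyp("W", "W", "N", "R"))
        assert eps[0].truncated and eps[-1].truncated
        assert not eps[1].truncated

    @given(random_states)
    def test_agreement_with_groupby_run_length_encoder(self, labels):
        eps = find_episodes(Hypnogram(labels))
        oracle = [(k, len(list(g))) for k, g in itertools.groupby(labels)]
        assert [(e.state, e.length_epochs) for e in eps] == oracle

    @given(random_states)
    def test_episode_time_equals_occupancy_time(self, labels):
        h = Hypnogram(labels)
        eps = find_episodes(h)
        for state in ("WAKE", "MA", "NREMS", "REMS"):
            ep_time = sum(e.length_epochs for e in eps if e.state == state)
            occ_epochs = int(np.sum(h.states == state))
            assert ep_time == occ_epochs


class TestTransitions:
    def test_simple_example(self):
        mat = transition_counts(hyp("N", "R", "W"))
        assert mat.loc["NREMS", "REMS"] == 1
        assert mat.loc["REMS", "WAKE"] == 1
        assert mat.to_numpy().sum() == 2

    def test_constant_slice_zero_matrix(self):
        assert transition_counts(Hypnogram(np.repeat("WAKE", 5))).to_numpy().sum() == 0

    @given(random_states)
    def test_total_transitions_equal_episodes_minus_one(self, labels):
        h = Hypnogram(labels)
        total = transition_counts(h).to_numpy().sum()
        assert total == len(find_episodes(h)) - 1

    def test_diagonal_is_zero(self):
        mat = transition_counts(day_hypnogram(3))
        assert np.all(np.diag(mat.to_numpy()) == 0)


def spectra_from_psd(psd, freqs):
    n = psd.shape[0]
    frame = pd.DataFrame({"epoch_index": np.arange(n)})
    return EpochSpectra(frame=frame, psd=np.asarray(psd, float), freqs=np.asarray(freqs, float))


class TestBandAuc:
    def test_flat_spectrum_area(self):
        freqs = np.arange(0.25, 32.0, 0.25)
        psd = np.full((1, freqs.size), 2.0)
        spec = spectra_from_psd(psd, freqs)
        auc = state_band_auc(spec, Hypnogram(["NREMS"]), "NREMS", "delta")
        assert auc == pytest.approx(2.0 * 4.5)  # flat p times 0.5..5 width

    def test_matches_fine_grid_integration_on_smooth_spectrum(self):
        f_coarse = np.arange(0.25, 32.0, 0.25)
        f_fine = np.arange(0.25, 31.751, 0.025)
        g = lambda f: np.exp(-f / 10.0)
        coarse = state_band_auc(
            spectra_from_psd(g(f_coarse)[None, :], f_coarse), Hypnogram(["REMS"]), "REMS", "theta"
        )
        mask = (f_fine >= 6.0) & (f_fine <= 9.0)
        fine = np.trapezoid(g(f_fine)[mask], f_fine[mask])
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_absent_state_gives_nan_marker(self):
        spec = spectra_from_psd(np.ones((2, 4)), np.array([1.0, 1.25, 1.5, 1.75]))
        auc = state_band_auc(spec, hyp("N", "N"), "REMS", "delta")
        assert np.isnan(auc)


class TestNormalization:
    def test_percent_of_baseline(self):
        assert normalize_to_baseline(12.0, 10.0) == pytest.approx(120.0)
        assert normalize_to_baseline(10.0, 10.0) == pytest.approx(100.0)

    def test_zero_baseline_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="baseline"):
            assert np.isnan(normalize_to_baseline(5.0, 0.0))


class TestSummary:
    def test_daily_metrics_aggregate_from_phases(self):
        h = day_hypnogram(9)
        df = summarize_architecture(h)
        occ = df[df.metric == "occupancy_pct"]
        for state in ("WAKE", "NREMS", "REMS"):
            day_frac = 100 * np.mean(h.states == state)
            phase_mean = occ[occ.state == state]["value"].mean()  # equal-size phases
            assert phase_mean == pytest.approx(day_frac)
        ep = df[df.metric == "episode_count"]
        total_eps = ep["value"].sum()
        assert total_eps == len(find_episodes(h)) + sum(
            1 for i in (5400, 10800, 16200) if h.states[i] == h.states[i - 1]
        )
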