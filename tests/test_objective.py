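"""Histogram construction and weighted-KL loss tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimddm import (DDMParameters, EventSeries, SimulationConfig,
                     StimulusProtocol, dkl, dkl_star, isi_histograms,
                     pair_distance, simulate, total_loss)
from swimddm.objective import (BIN_EDGES, BIN_WIDTH, LabeledISIHistograms,
                               simulate_histograms)


def series_from_isis(isis, label="correct", coherence=1.0, total_time=100.0,
                     protocol=None):
    """Build a minimal EventSeries carrying given stimulus-phase ISIs."""
    protocol = protocol or StimulusProtocol(mode="continuous",
                                            coherence_levels=(coherence,))
    t = 3.0 + np.cumsum(np.asarray(isis, float))
    df = pd.DataFrame({
        "time_s": t,
        "isi_s": isis,
        "label": label,
        "coherence": coherence,
        "trial_id": 0,
        "phase": "stimulus",
        "t_in_segment_s": t,
        "first_in_session": False,
    })
    return EventSeries(events=df, protocol=protocol,
                       stim_time={coherence: total_time})


class TestHistogramConstruction:
    def test_hand_binned_densities(self):
        ev = series_from_isis([0.12, 0.12, 1.99, 2.5], total_time=100.0)
        h = isi_histograms(ev)
        heights = h.heights[(1.0, "correct")]
        bin_10_15 = int(np.digitize(0.12, BIN_EDGES)) - 1
        assert heights[bin_10_15] == pytest.approx(2 / (0.05 * 100))
        assert heights[-1] == pytest.approx(1 / (0.05 * 100))  # [1.95, 2.00)
        assert h.n_excluded == 1  # the 2.5 s interval
        assert heights.sum() * BIN_WIDTH == pytest.approx(3 / 100)

    def test_half_open_binning(self):
        ev = series_from_isis([0.05] * 5)
        h = isi_histograms(ev).heights[(1.0, "correct")]
        assert h[0] == 0.0
        assert h[1] > 0.0

    def test_zero_events_all_zero(self):
        ev = series_from_isis([])
        h = isi_histograms(ev)
        assert all(not v.any() for v in h.heights.values())
        assert h.n_excluded == 0

    def test_mass_conservation_from_simulation(self, example_series):
        h = isi_histograms(example_series)
        for key in h.pairs():
            T = h.total_time[key[0]]
            mass = h.heights[key].sum() * BIN_WIDTH * T
            assert mass == pytest.approx(h.n_retained[key], abs=1e-6)

    def test_onset_exclusion_window(self, example_params):
        """Events within 2 s of stimulus onset never enter histograms."""
        prot = StimulusProtocol(mode="trial")
        ev = simulate(example_params, prot,
                      SimulationConfig(seed=2, n_trials=30))
        h = isi_histograms(ev)
        df = ev.events
        early = df[(df["phase"] == "stimulus") & (df["t_in_segment_s"] < 2.0)
                   & (df["isi_s"] < 2.0)]
        assert len(early) > 0  # the window actually bites
        total = sum(h.n_retained.values())
        eligible = df[(df["phase"] == "stimulus")
                      & (df["t_in_segment_s"] >= 2.0)
                      & (df["isi_s"] < 2.0)
                      & (~df["first_in_session"])]
        assert total == len(eligible)

    @pytest.mark.parametrize("mode,kw", [("continuous", {"duration": 300.0}),
                                         ("trial", {"n_trials": 8})])
    def test_fast_path_matches_event_table_path(self, example_params, mode, kw):
        """simulate_histograms (array path) is bit-identical to binning
        the full event table, in both protocol modes."""
        prot = StimulusProtocol(mode=mode)
        config = SimulationConfig(seed=17, **kw)
        via_events = isi_histograms(simulate(example_params, prot, config),
                                    prot)
        direct = simulate_histograms(example_params, prot, config)
        assert via_events.total_time == direct.total_time
        assert via_events.n_retained == direct.n_retained
        assert via_events.n_excluded == direct.n_excluded
        for key in via_events.pairs():
            np.testing.assert_array_equal(via_events.heights[key],
                                          direct.heights[key])

    def test_unknown_coherence_raises(self):
        ev = series_from_isis([0.5], coherence=0.33)
        with pytest.raises(ValueError):
            isi_histograms(ev, StimulusProtocol(mode="continuous"))

    def test_per_bin_convention_rescales_heights_only(self):
        ev = series_from_isis([0.12, 0.5, 0.5])
        dens = isi_histograms(ev, convention="density")
        per_bin = isi_histograms(ev, convention="per_bin")
        np.testing.assert_allclose(
            dens.heights[(1.0, "correct")] * BIN_WIDTH,
            per_bin.heights[(1.0, "correct")])
        assert dens.area(1.0, "correct") == pytest.approx(
            per_bin.area(1.0, "correct"))


class TestDivergences:
    def test_dkl_identity(self):
        p = np.array([0.2, 0.3, 0.0, 0.5])
        assert dkl(p, p) == 0.0

    def test_dkl_hand_value(self):
        assert dkl([0.2, 0.1], [0.1, 0.2]) == pytest.approx(0.1 * math.log(2))

    def test_dkl_zero_numerator_convention(self):
        assert dkl([0.3, 0.0], [0.3, 0.1]) == 0.0

    def test_dkl_star_hand_value(self):
        expected = 0.04 * math.log(2) + 0.01 * math.log(0.5)
        assert dkl_star([0.2, 0.1], [0.2, 0.1], [0.1, 0.2]) == pytest.approx(expected)
        assert expected == pytest.approx(0.03 * math.log(2))

    def test_dkl_star_zero_weights(self):
        assert dkl_star([0.0, 0.0], [0.5, 0.5], [0.1, 0.9]) == 0.0

    def test_negative_bins_rejected(self):
        with pytest.raises(ValueError):
            dkl([-0.1, 1.0], [0.5, 0.5])

    def test_pair_distance_brute_force_max(self):
        pt, pm = np.array([0.2, 0.1]), np.array([0.1, 0.2])
        d0 = dkl_star(pt, pt, pm)
        d1 = dkl_star(pt, pm, pt)
        assert pair_distance(pt, pm) == max(d0, d1)

    def test_pair_distance_smoothed_zero_bin_preserves_equality(self):
        pt = np.array([0.2, 0.1, 0.0])
        assert pair_distance(pt, pt.copy()) == 0.0

    @given(st.lists(st.floats(0.0, 5.0), min_size=3, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_dkl_self_distance_always_zero(self, heights):
        p = np.asarray(heights)
        assert dkl(p, p) == 0.0
        assert dkl_star(p, p, p) == 0.0

    def test_peak_weighted_error_dominance(self):
        """A fixed-size model error at the target's peak bin costs more
        DKL* than the same error in a flat tail bin."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            peak = rng.uniform(1.0, 3.0)
            tail = rng.uniform(0.01, 0.1)
            n = 20
            target = np.full(n, tail)
            target[3] = peak
            err = tail * 0.5
            at_peak = target.copy()
            at_peak[3] -= err
            at_tail = target.copy()
            at_tail[10] -= err
            assert pair_distance(target, at_peak) > pair_distance(target, at_tail)


class TestTotalLoss:
    def test_identity_of_indiscernibles(self, example_series):
        h = isi_histograms(example_series)
        assert total_loss(h, h) == 0.0

    def test_averaging_over_eight_pairs(self, example_series):
        h = isi_histograms(example_series)
        hb = isi_histograms(example_series)
        key = (1.0, "correct")
        hb.heights[key] = hb.heights[key] * 1.5 + 0.01
        v = pair_distance(h.heights[key], hb.heights[key])
        assert total_loss(h, hb) == pytest.approx(v / 8)

    def test_mismatched_coherences_rejected(self, example_series):
        h = isi_histograms(example_series)
        other = series_from_isis([0.5])
        h2 = isi_histograms(other)
        with pytest.raises(ValueError):
            total_loss(h, h2)

    def test_json_round_trip(self, example_series, tmp_path):
        h = isi_histograms(example_series)
        path = tmp_path / "h.json"
        h.to_json(path)
        h2 = LabeledISIHistograms.from_json(path)
        assert total_loss(h, h2) == 0.0
        assert h2.total_time == h.total_time
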