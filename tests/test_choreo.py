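"""Transition detection, event alignment, onset estimation, ratio statistic."""

import numpy as np
import pytest

from cgtwist.choreo import (
    EventAlignedProfile,
    detect_transitions,
    event_aligned_average,
    ion_influence_ratio,
    onset_time,
)
from cgtwist.synthgen import simulate_conditional_bii_series


class TestDetectTransitions:
    def test_single_path_through_intermediate(self):
        labels = np.array(["g-g-", "tg-", "tt"])
        events = detect_transitions(labels, "g-g-", "tt")
        assert len(events) == 1
        assert events[0].index == 2
        assert events[0].path == "tg-"
        assert not events[0].direct

    def test_direct_jump_flagged(self):
        labels = np.array(["g-g-", "tt", "tt"])
        events = detect_transitions(labels, "g-g-", "tt")
        assert len(events) == 1 and events[0].direct and events[0].path == "direct"

    def test_long_intermediate_dwell_excluded(self):
        labels = np.array(["g-g-"] + ["tg-"] * 150 + ["tt"])
        assert detect_transitions(labels, "g-g-", "tt", max_path_len=100) == []
        assert len(detect_transitions(labels, "g-g-", "tt", max_path_len=200)) == 1

    def test_source_equals_target_rejected(self):
        with pytest.raises(ValueError):
            detect_transitions(np.array(["g-g-"]), "g-g-", "g-g-")

    def test_matches_generator_ground_truth(self, tcga_run):
        """Every detected event index is a snapshot where the hidden chain
        first reaches tt from g-g- via one intermediate."""
        _, _, _, truth = tcga_run
        z = truth.zeta_state
        events = detect_transitions(z, "g-g-", "tt")
        assert len(events) > 0
        for ev in events[:200]:
            i = ev.index
            assert z[i] == "tt" and z[i - 1] != "tt"
            j = i - 1
            while z[j] == ev.path:
                j -= 1
            assert z[j] == "g-g-"


class TestEventAligned:
    def _events(self, indices):
        return detect_transitions(
            self._series_with_flips(indices), "g-g-", "tt"
        )

    @staticmethod
    def _series_with_flips(indices, n=2000):
        labels = np.full(n, "g-g-", dtype="U4")
        for i in indices:
            labels[i - 1] = "tg-"
            labels[i] = "tt"
        return labels

    def test_constant_observable_gives_constant_profile(self):
        events = self._events([500, 900, 1500])
        prof = event_aligned_average(events, {"c": np.full(2000, 3.5)}, window_ps=250)
        np.testing.assert_allclose(prof.means["c"], 3.5)
        assert prof.n_events == 3

    def test_events_without_full_window_dropped_and_counted(self):
        events = self._events([100, 900])
        prof = event_aligned_average(events, {"c": np.ones(2000)}, window_ps=250)
        assert prof.n_events == 1 and prof.n_dropped == 1

    def test_zero_usable_events_raises(self):
        events = self._events([100])
        with pytest.raises(ValueError, match="events"):
            event_aligned_average(events, {"c": np.ones(2000)}, window_ps=250)

    def test_time_reversal_identity(self):
        """The before-profile on the reversed series with reversed event
        indices equals the after-profile of the forward run."""
        rng = np.random.default_rng(70)
        obs = rng.normal(size=2000)
        events = self._events([500, 900, 1500])
        fwd = event_aligned_average(events, {"x": obs}, window_ps=100,
                                    direction="after")
        rev_obs = obs[::-1]

        class E:
            def __init__(self, index):
                self.index = index

        rev_events = [E(len(obs) - 1 - ev.index) for ev in events]
        bwd = event_aligned_average(rev_events, {"x": rev_obs}, window_ps=100,
                                    direction="before")
        np.testing.assert_allclose(bwd.means["x"][::-1], fwd.means["x"])

    def test_white_noise_profile_flat(self):
        rng = np.random.default_rng(71)
        n = 200_000
        labels = np.full(n, "g-g-", dtype="U4")
        idx = np.arange(1000, n - 1000, 400)
        for i in idx:
            labels[i - 1] = "tg-"
            labels[i] = "tt"
        events = detect_transitions(labels, "g-g-", "tt")
        noise = rng.normal(size=n)
        prof = event_aligned_average(events, {"w": noise}, window_ps=250)
        assert onset_time(prof, "w", baseline_window=(-250, -150)) is None


class TestOnset:
    def _step_profile(self, step_at=-45.0, noise=0.002, seed=72):
        rng = np.random.default_rng(seed)
        tau = np.arange(-250.0, 1.0)
        y = np.where(tau >= step_at, 1.0, 0.3) + rng.normal(0, noise, tau.size)
        return EventAlignedProfile(tau, {"ion": y}, {"ion": np.full(tau.size, noise)},
                                   n_events=1000, n_dropped=0)

    def test_step_function_onset(self):
        assert onset_time(self._step_profile(-45.0), "ion") == pytest.approx(45.0)

    def test_flat_profile_has_no_onset(self):
        rng = np.random.default_rng(73)
        tau = np.arange(-250.0, 1.0)
        y = 0.3 + rng.normal(0, 0.002, tau.size)
        prof = EventAlignedProfile(tau, {"ion": y}, {"ion": np.full(tau.size, 0.002)},
                                   1000, 0)
        assert onset_time(prof, "ion") is None


class TestRatio:
    def test_programmed_conditional_probabilities_recovered(self):
        presence, labels = simulate_conditional_bii_series(
            0.80, 0.27, mean_run_ps=60.0, n_steps=200_000, seed=80
        )
        res = ion_influence_ratio({"inner_minor": presence}, labels)
        r = res["inner_minor"]
        assert r.defined
        assert r.p_with == pytest.approx(0.80, abs=0.03)
        assert r.p_without == pytest.approx(0.27, abs=0.03)
        assert r.ratio == pytest.approx(0.80 / 0.27, rel=0.15)

    def test_independent_presence_gives_unit_ratio(self):
        presence, labels = simulate_conditional_bii_series(
            0.27, 0.27, mean_run_ps=60.0, n_steps=200_000, seed=81
        )
        r = ion_influence_ratio({"r": presence}, labels)["r"]
        assert r.ratio == pytest.approx(1.0, abs=0.1)

    def test_all_runs_too_short_flagged_undefined(self):
        presence = np.tile([1, 0], 100).astype(bool)
        labels = np.full(200, "tt", dtype="U4")
        r = ion_influence_ratio({"r": presence}, labels, min_state_ps=40)["r"]
        assert not r.defined and np.isnan(r.ratio)

    def test_null_calibration_median_near_one(self):
        """Over 200 uncoupled replicates the ratio's median lies in
        [0.9, 1.1]."""
        ratios = []
        for rep in range(200):
            presence, labels = simulate_conditional_bii_series(
                0.27, 0.27, mean_run_ps=60.0, n_steps=20_000, seed=1000 + rep
            )
            r = ion_influence_ratio({"r": presence}, labels)["r"]
            if r.defined:
                ratios.append(r.ratio)
        assert len(ratios) > 180
        assert 0.9 <= float(np.median(ratios)) <= 1.1

    def test_per_state_mode_close_to_per_ps_on_iid_series(self):
        presence, labels = simulate_conditional_bii_series(
            0.6, 0.2, mean_run_ps=60.0, n_steps=100_000, seed=82
        )
        a = ion_influence_ratio({"r": presence}, labels, mode="per_ps")["r"]
        b = ion_influence_ratio({"r": presence}, labels, mode="per_state")["r"]
        assert a.p_with == pytest.approx(b.p_with, abs=0.02)


class TestLeadTimeRecovery:
    def test_programmed_lead_recovered(self):
        """Event-aligned ion profiles recover programmed mean leads; the
        threshold-crossing estimator has a ~5 ps resolution floor set by
        the duration of the two-flip path."""
        from cgtwist.presets import get_preset
        from cgtwist.synthgen import simulate_coupled_dynamics

        # longer programmed leads give rarer ion-driven events, so the
        # series length is scaled to keep >= 5e3 events in each case
        for lead, seed, n_steps in (
            (10.0, 90, 1_000_000), (45.0, 91, 2_000_000), (100.0, 92, 3_600_000)
        ):
            params = get_preset("CHOREO", ion_lead_time_ps=lead)
            _, _, truth = simulate_coupled_dynamics(params, n_steps, seed=seed)
            events = detect_transitions(truth.zeta_state, "g-g-", "tt")
            prof = event_aligned_average(
                events, {"ion": truth.ion_present.astype(float)}, window_ps=250
            )
            assert prof.n_events >= 5000
            onset = onset_time(prof, "ion")
            assert onset is not None
            assert abs(onset - lead) <= max(0.25 * lead, 6.0)
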