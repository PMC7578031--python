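"""Spike-triggered phases, PPC estimators, WPLI, condition statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from riskcoh.connectivity import (condition_stats, directional_contrast, ppc,
                                  ppc_bruteforce, ppc_by_condition, ppc_pooled,
                                  session_sfc, spike_triggered_phase, wpli)
from riskcoh.task_synth import SessionConfig, UnitRecord, simulate_session

FS = 1000.0
T = np.arange(-1200, 2000) / 1000.0


class TestSpikeTriggeredPhase:
    def test_peak_convention_is_zero(self):
        lfp = np.cos(2 * np.pi * 10 * T)
        spikes = np.arange(0.0, 800.0, 100.0)  # all at peaks
        ps = spike_triggered_phase(UnitRecord(0, "a", [spikes]), lfp[None, :],
                                   FS, -1200.0, np.array([10.0]))
        assert np.abs(ps.phases).max() < 1e-6

    def test_trough_is_pi(self):
        lfp = np.cos(2 * np.pi * 10 * T)
        spikes = np.arange(50.0, 800.0, 100.0)
        ps = spike_triggered_phase(UnitRecord(0, "a", [spikes]), lfp[None, :],
                                   FS, -1200.0, np.array([10.0]))
        assert np.abs(np.abs(ps.phases) - np.pi).max() < 1e-6

    def test_generator_round_trip(self, rng):
        # phases measured on generator output follow the generating von Mises law
        from riskcoh.task_synth import generate_phase_locked_spikes
        lfp = np.cos(2 * np.pi * 10 * T) + 0.1 * rng.standard_normal(T.size)
        st = generate_phase_locked_spikes(lfp, FS, -1200.0, (8, 12), 2.0, 1.0,
                                          400, rng, window=(0.0, 800.0))
        ps = spike_triggered_phase(UnitRecord(0, "a", [st]), lfp[None, :],
                                   FS, -1200.0, np.array([10.0]))
        z = np.exp(1j * ps.phases[:, 0]).mean()
        assert np.abs(np.angle(z) - 1.0) < 0.15
        assert np.abs(np.abs(z) - i1(2) / i0(2)) < 0.1

    def test_edge_spikes_dropped(self):
        lfp = np.cos(2 * np.pi * 10 * T)
        # spike with full window inside the trace is kept ...
        ps = spike_triggered_phase(UnitRecord(0, "a", [np.array([0.0])]),
                                   lfp[None, :], FS, -1200.0,
                                   np.array([10.0]), bins=((-1300.0, 100.0),))
        assert ps.n_dropped_edge == 0 and ps.phases.shape[0] == 1
        # ... one whose window crosses the trace start is dropped with a count
        ps2 = spike_triggered_phase(UnitRecord(0, "a", [np.array([-1150.0])]),
                                    lfp[None, :], FS, -1200.0,
                                    np.array([10.0]), bins=((-1300.0, 100.0),))
        assert ps2.n_dropped_edge == 1 and ps2.phases.shape[0] == 0


class TestPPC:
    def test_identical_phases_give_one(self):
        assert ppc(np.zeros(10), np.repeat([0, 1], 5)) == pytest.approx(1.0)

    def test_two_opposite_single_spike_trials(self):
        assert ppc(np.array([0.0, np.pi]), np.array([0, 1])) == pytest.approx(-1.0)

    def test_matches_bruteforce_exactly(self, rng):
        for _ in range(20):
            n_trials = rng.integers(2, 20)
            counts = rng.integers(1, 20, n_trials)
            tid = np.repeat(np.arange(n_trials), counts)
            phases = rng.uniform(-np.pi, np.pi, tid.size)
            assert ppc(phases, tid) == pytest.approx(
                ppc_bruteforce(phases, tid), abs=1e-10)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0, 2.0, 4.0])
    def test_closed_form_limit(self, kappa, rng):
        # E[PPC] = (I1(kappa)/I0(kappa))^2 for i.i.d. von Mises phases
        vals = []
        for _ in range(300):
            tid = np.repeat(np.arange(50), 10)
            phases = (rng.uniform(-np.pi, np.pi, tid.size) if kappa == 0
                      else rng.vonmises(0.0, kappa, tid.size))
            vals.append(ppc(phases, tid))
        expected = (i1(kappa) / i0(kappa)) ** 2
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-4

    def test_spike_count_bias_controlled(self, rng):
        # mean PPC at 10 vs 100 spikes/trial differs by < 2 MC SEs
        means = {}
        for n_spk in (10, 100):
            vals = [ppc(rng.vonmises(0.0, 1.0, 20 * n_spk),
                        np.repeat(np.arange(20), n_spk)) for _ in range(150)]
            means[n_spk] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        diff = abs(means[10][0] - means[100][0])
        se = np.hypot(means[10][1], means[100][1])
        assert diff < 2 * se + 1e-3

    def test_pooled_variant_biased_upward_at_low_counts(self, rng):
        # contrast property: the naive all-pairs estimator inflates when a
        # few spikes per trial share within-trial dependence
        tid = np.repeat(np.arange(5), 2)
        trial_offsets = rng.uniform(-np.pi, np.pi, 5)
        phases = trial_offsets[tid] + 0.05 * rng.standard_normal(10)
        assert ppc_pooled(phases) > ppc(phases, tid) + 0.05

    def test_single_trial_undefined(self):
        assert np.isnan(ppc(np.zeros(5), np.zeros(5)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 2**16 - 1))
    def test_bounds_and_oracle_property(self, n_trials, seed):
        # PPC of any phase set lies in [-1, 1] and equals the brute force
        rng = np.random.default_rng(seed)
        tid = np.repeat(np.arange(n_trials), rng.integers(1, 6, n_trials))
        phases = rng.uniform(-np.pi, np.pi, tid.size)
        v = ppc(phases, tid)
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(ppc_bruteforce(phases, tid), abs=1e-10)


class TestWPLI:
    def test_constant_quarter_lag_approaches_one(self, rng):
        a = np.array([np.cos(2 * np.pi * 10 * T) + 0.5 * rng.standard_normal(T.size)
                      for _ in range(50)])
        b = np.array([np.sin(2 * np.pi * 10 * T) + 0.5 * rng.standard_normal(T.size)
                      for _ in range(50)])
        w = wpli(a, b, FS, np.array([10.0]))
        assert np.nanmean(w.values) > 0.95

    def test_identical_signals_flagged_undefined(self, rng):
        a = np.array([np.cos(2 * np.pi * 10 * T) + 0.1 * rng.standard_normal(T.size)
                      for _ in range(20)])
        w = wpli(a, a, FS, np.array([10.0]))
        assert np.all(np.isnan(w.values))

    def test_common_source_mixing_gives_low_wpli_high_coherence(self, rng):
        # zero-lag mixtures of one common source: coherent but WPLI-silent
        n = 60
        ws, cohs = [], []
        for _ in range(n):
            s = np.cos(2 * np.pi * 10 * T + rng.uniform(0, 2 * np.pi))
            a = 1.0 * s + 0.4 * rng.standard_normal(T.size)
            b = 0.7 * s + 0.4 * rng.standard_normal(T.size)
            ws.append((a, b))
        a = np.array([w[0] for w in ws])
        b = np.array([w[1] for w in ws])
        w = wpli(a, b, FS, np.array([10.0]))
        # magnitude coherence via cross-spectrum at 10 Hz
        fa = np.fft.rfft(a, axis=-1)
        fb = np.fft.rfft(b, axis=-1)
        k = np.argmin(np.abs(np.fft.rfftfreq(T.size, 1 / FS) - 10.0))
        coh = (np.abs(np.mean(fa[:, k] * np.conj(fb[:, k]))) /
               np.sqrt(np.mean(np.abs(fa[:, k])**2) * np.mean(np.abs(fb[:, k])**2)))
        assert coh > 0.7
        assert np.nanmean(w.values) < 0.3

    def test_bounds_and_amplitude_invariance(self, rng):
        a = rng.standard_normal((30, 1600))
        b = rng.standard_normal((30, 1600))
        w1 = wpli(a, b, FS, np.array([8.0, 15.0]))
        vals = w1.values[np.isfinite(w1.values)]
        assert np.all((vals >= 0) & (vals <= 1))
        w2 = wpli(3.5 * a, 0.2 * b, FS, np.array([8.0, 15.0]))
        np.testing.assert_allclose(w1.values, w2.values, atol=1e-10)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            wpli(np.zeros((1, 100)), np.zeros((1, 100)), FS, np.array([10.0]))


def _phase_table(rng, kappas_by_level, n_pairs=25, n_trials=30, freqs=(10.0, 20.0)):
    """Tidy PPC table built directly from von Mises phase draws."""
    rows = []
    for pair in range(n_pairs):
        for lvl, kappa in kappas_by_level.items():
            for f in freqs:
                tid = np.repeat(np.arange(n_trials), 8)
                ph = (rng.uniform(-np.pi, np.pi, tid.size) if kappa == 0
                      else rng.vonmises(0.0, kappa, tid.size))
                rows.append({"unit_id": pair, "electrode_id": 0, "condition": lvl,
                             "bin": -1, "freq": f, "ppc": ppc(ph, tid),
                             "n_spikes": tid.size, "n_trials": n_trials})
    return pd.DataFrame(rows)


class TestConditionStats:
    def test_flat_schedule_rarely_significant(self, rng):
        empties = 0
        for _ in range(20):
            table = _phase_table(rng, {0: 0.5, 1: 0.5, 4: 0.5})
            st = condition_stats(table)
            if not st["significant"].any():
                empties += 1
        assert empties >= 18

    def test_increasing_kappa_flags_increase(self, rng):
        table = _phase_table(rng, {0: 0.1, 1: 0.5, 4: 1.2})
        st = condition_stats(table)
        assert st["significant"].all()
        assert (st["direction"] == "increase").all()

    def test_symmetric_injection_flags_both(self, rng):
        t1 = _phase_table(rng, {0: 0.1, 4: 1.2})
        t2 = _phase_table(rng, {0: 0.1, 4: 1.2})
        s1, s2 = condition_stats(t1), condition_stats(t2)
        assert s1["significant"].all() and s2["significant"].all()
        assert (s1["slope"] > 0).all() and (s2["slope"] > 0).all()


@pytest.fixture(scope="module")
def asymmetric_session():
    cfg = SessionConfig(
        n_trials=135, n_units=6, n_electrodes=3, coding_mixture={},
        base_rate_mean=15.0, gain_latent_sd=0.0,
        coupling={
            "parietal->frontal": {"band": (8.0, 18.0),
                                  "kappa": {0: 0.1, 1: 0.5, 4: 1.2},
                                  "preferred_phase": 0.0, "fraction": 1.0},
            "frontal->parietal": {"band": (8.0, 18.0),
                                  "kappa": {0: 1.2, 1: 0.5, 4: 0.1},
                                  "preferred_phase": 0.0, "fraction": 1.0},
        })
    b = simulate_session(cfg, seed=21)
    freqs = np.arange(6.0, 44.0, 2.0)
    pf = session_sfc(b, "parietal", "frontal", freqs=freqs)
    fp = session_sfc(b, "frontal", "parietal", freqs=freqs)
    return pf, fp


class TestDirectionalContrast:
    def test_opposite_kappa_slopes_recovered(self, asymmetric_session):
        pf, fp = asymmetric_session
        c = directional_contrast(pf, fp, band=(8.0, 18.0))
        assert c["slope_ab"] > 0 > c["slope_ba"]
        assert c["ci"][0] > 0

    def test_fdr_significant_in_band_both_directions(self, asymmetric_session):
        pf, fp = asymmetric_session
        for df, sign in ((pf, 1), (fp, -1)):
            st = condition_stats(df)
            band = st[(st["freq"] >= 8) & (st["freq"] <= 18)]
            assert band["significant"].all()
            assert (np.sign(band["slope"]) == sign).all()

    def test_symmetric_generator_ci_contains_zero(self):
        cfg = SessionConfig(
            n_trials=108, n_units=4, n_electrodes=2, coding_mixture={},
            min_trials_per_condition=2,
            base_rate_mean=15.0, gain_latent_sd=0.0,
            coupling={
                "parietal->frontal": {"band": (8.0, 18.0),
                                      "kappa": {0: 0.5, 1: 0.5, 4: 0.5},
                                      "preferred_phase": 0.0, "fraction": 1.0},
                "frontal->parietal": {"band": (8.0, 18.0),
                                      "kappa": {0: 0.5, 1: 0.5, 4: 0.5},
                                      "preferred_phase": 0.0, "fraction": 1.0},
            })
        b = simulate_session(cfg, seed=23)
        freqs = np.arange(8.0, 20.0, 2.0)
        pf = session_sfc(b, "parietal", "frontal", freqs=freqs)
        fp = session_sfc(b, "frontal", "parietal", freqs=freqs)
        c = directional_contrast(pf, fp, band=(8.0, 18.0))
        assert c["ci"][0] <= 0 <= c["ci"][1]

    def test_mismatched_grids_rejected(self, asymmetric_session):
        pf, _ = asymmetric_session
        other = pf.copy()
        other["freq"] += 1.0
        with pytest.raises(ValueError):
            directional_contrast(pf, other)
        with pytest.raises(ValueError):
            directional_contrast(pf, pf.iloc[:0])


class TestSessionSFC:
    def test_silent_units_excluded(self, small_bundle):
        import copy
        b = copy.deepcopy(small_bundle)
        for u in b.units[:2]:
            if u.area == "parietal":
                u.spike_times = [np.empty(0)] * len(b.trials)
        df = session_sfc(b, "parietal", "frontal", freqs=np.array([10.0]),
                         max_electrodes=1)
        silent = {u.unit_id for u in b.units[:2] if u.area == "parietal"}
        assert silent.isdisjoint(set(df["unit_id"]))
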