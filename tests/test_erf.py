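import numpy as np
import pytest

from acmodes import (
    StimulusTrain,
    adapted_state_waveform,
    decompose_by_connection,
    extract_peaks,
    meg_signal,
    mode_contributions,
    run_stimulus_train,
)
from acmodes.erf import DISPLAY_SHIFT, state_efficacy
from acmodes.slowfast import evolve_interval


@pytest.fixture(scope="module")
def adapt(def_top, params):
    return run_stimulus_train(def_top, params, StimulusTrain(soi=0.5, n_stimuli=40))


@pytest.fixture(scope="module")
def interval(adapt):
    time = np.arange(0.0, 0.5, 1e-3)
    u, v = evolve_interval(adapt, adapt.adapted, time)
    return time, u, v


class TestMegSignal:
    def test_zero_trajectory_gives_zero(self, def_top):
        t = np.arange(0, 0.1, 1e-3)
        wave = meg_signal(def_top, t, np.zeros((100, 5)), np.zeros((100, 5)))
        assert np.all(wave.R == 0)

    def test_null_sensor(self, def_top, interval):
        from dataclasses import replace

        t, u, v = interval
        silent = replace(def_top, K1=np.zeros((5, 5)), K2=np.zeros((5, 5)))
        assert np.all(meg_signal(silent, t, u, v).R == 0)

    def test_display_shift_only_moves_timestamps(self, def_top, interval):
        t, u, v = interval
        wave = meg_signal(def_top, t, u, v)
        plain = wave.to_frame()
        shifted = wave.to_frame(display_shift=DISPLAY_SHIFT)
        assert np.allclose(shifted["R"], plain["R"])
        assert np.allclose(shifted["time_ms"] - plain["time_ms"], 30.0)

    def test_depressed_weights_change_signal(self, def_top, adapt, interval):
        t, u, v = interval
        q = adapt.q[adapt.adapted]
        static = meg_signal(def_top, t, u, v)
        depressed = meg_signal(def_top, t, u, v, q=q)
        assert not np.allclose(static.R, depressed.R)


class TestModeContributions:
    def test_mode_sum_reconstructs_signal(self, def_top, adapt, interval):
        """Eq-by-trajectory and mode-sum routes agree pointwise."""
        t, u, v = interval
        s = adapt.adapted
        q = adapt.q[s]
        wave = meg_signal(def_top, t, u, v, q=q)
        contrib = mode_contributions(
            adapt.decompositions[s], adapt.coefficients[s], def_top, q=q
        )
        scale = np.abs(wave.R).max()
        assert np.abs(contrib.signal(t) - wave.R).max() < 1e-9 * scale
        # completeness at onset and conjugate-pair reality
        assert contrib.trajectories(t)[0].sum().real == pytest.approx(
            wave.R[0], abs=1e-9 * max(scale, 1)
        )
        pair_sum = contrib.pair_waveforms(t).sum(axis=1)
        assert np.abs(pair_sum - wave.R).max() < 1e-9 * scale

    def test_low_frequency_modes_dominate_n1m(self, def_top, adapt, interval):
        """The N1m is carried by the two lowest-frequency mode pairs."""
        t, u, v = interval
        s = adapt.adapted
        wave = meg_signal(def_top, t, u, v, q=adapt.q[s])
        n1 = extract_peaks(wave).require("N1m")
        contrib = mode_contributions(
            adapt.decompositions[s], adapt.coefficients[s], def_top, q=adapt.q[s]
        )
        i_n1 = int(round(n1.latency / 1e-3))
        pair_waves = np.abs(contrib.pair_waveforms(t)[i_n1])
        dec = adapt.decompositions[s]
        pos = dec.omega > 0
        # pairs ordered by |omega| ascending in the decomposition
        assert pair_waves[:2].min() > pair_waves[2:].max()

    def test_leading_modes_destructive_at_onset(self, def_top, adapt):
        """At stimulus onset the two dominant modes nearly cancel."""
        s = adapt.adapted
        dec = adapt.decompositions[s]
        contrib = mode_contributions(
            dec, adapt.coefficients[s], def_top, q=adapt.q[s]
        )
        r0 = contrib.trajectories(np.array([0.0]))[0]
        # representative member of each conjugate pair (positive frequency)
        lead = [n for n in range(10) if dec.omega[n] > 0][:2]
        phase_gap = np.abs(np.angle(r0[lead[0]]) - np.angle(r0[lead[1]]))
        phase_gap = min(phase_gap, 2 * np.pi - phase_gap)
        assert abs(phase_gap - np.pi) < 0.5
        # the interference is fully destructive over all modes: the afferent
        # impulse sits in MEG-silent subcortex, so R(0) vanishes
        assert abs(r0.sum().real) < 1e-9 * np.abs(r0.real).max()

    def test_total_contribution_invariant_under_rescaling(self, def_top, adapt):
        """|c_n| kappa_n products survive any eigenvector scale convention."""
        s = adapt.adapted
        dec = adapt.decompositions[s]
        contrib = mode_contributions(dec, adapt.coefficients[s], def_top, q=adapt.q[s])
        rng = np.random.default_rng(7)
        scales = rng.uniform(0.5, 2.0, 10) * np.exp(
            1j * rng.uniform(-np.pi, np.pi, 10)
        )
        from dataclasses import replace as drep

        dec2 = drep(dec, right=dec.right * scales, left=dec.left / scales[:, None])
        u0 = dec.right @ adapt.coefficients[s]
        from acmodes import mode_coefficients

        c2 = mode_coefficients(dec2, u0[:5].real, u0[5:].real)
        contrib2 = mode_contributions(dec2, c2, def_top, q=adapt.q[s])
        assert np.allclose(
            contrib.total_contribution, contrib2.total_contribution, rtol=1e-9
        )


class TestConnectionDecomposition:
    @pytest.mark.parametrize("scheme", ["incoming", "outgoing", "type"])
    def test_groups_sum_to_total(self, def_top, adapt, interval, scheme):
        t, u, v = interval
        q = adapt.q[adapt.adapted]
        wave = meg_signal(def_top, t, u, v, q=q)
        table = decompose_by_connection(def_top, t, u, v, scheme, q=q)
        groups = table.drop(columns=["time_s", "total"])
        assert np.abs(groups.sum(axis=1) - wave.R).max() < 1e-12

    def test_unknown_scheme(self, def_top, interval):
        t, u, v = interval
        with pytest.raises(ValueError, match="unknown scheme"):
            decompose_by_connection(def_top, t, u, v, "sideways")

    def test_core_generates_p1m(self, def_top, adapt, interval):
        """At the P1m latency the core's incoming input is the whole signal."""
        t, u, v = interval
        q = adapt.q[adapt.adapted]
        wave = meg_signal(def_top, t, u, v, q=q)
        p1 = extract_peaks(wave).require("P1m")
        i = int(round(p1.latency / 1e-3))
        table = decompose_by_connection(def_top, t, u, v, "incoming", q=q)
        core = abs(table["core"].iloc[i])
        assert abs(table["belt"].iloc[i]) < 0.15 * core
        assert abs(table["parabelt"].iloc[i]) < 0.15 * core

    def test_subcortex_silent_in_incoming(self, def_top, adapt, interval):
        t, u, v = interval
        table = decompose_by_connection(def_top, t, u, v, "incoming")
        assert "IC" not in table.columns and "thalamus" not in table.columns


class TestAdaptedWaveform:
    def test_window_capped_by_soi(self, def_top, adapt):
        wave = adapted_state_waveform(def_top, adapt)
        assert wave.time[-1] < 0.5
        assert wave.state == "adapted"

    def test_initial_state_uses_unit_efficacy(self, def_top, adapt):
        assert state_efficacy(adapt, "initial", "depressed").tolist() == [1.0] * 5
        assert state_efficacy(adapt, "adapted", "static") is None
        with pytest.raises(ValueError):
            state_efficacy(adapt, "adapted", "wobbly")

    def test_n1m_grows_with_soi(self, def_top, params):
        mags = []
        for soi in (0.5, 2.5):
            a = run_stimulus_train(def_top, params, StimulusTrain(soi=soi, n_stimuli=60))
            wave = adapted_state_waveform(def_top, a)
            mags.append(extract_peaks(wave).require("N1m").magnitude)
        assert mags[1] > mags[0]
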