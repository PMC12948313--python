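"""Integrator accuracy, periodic-steady-state detection, and cycle
extraction."""

import numpy as np
import pytest

import hepacirc as hc
from hepacirc.model import STATE_LAYOUT, _Network, total_stressed_volume
from hepacirc.simulate import SimulationSettings, WaveformSet


class TestIntegratorOracles:
    def test_rc_discharge_matches_closed_form(self):
        """Five time constants of RC decay land within 0.1% of P0·e^-5."""
        fx = hc.make_fixture("rc_discharge", R=1.0, C=1.0, P0=1.0)
        t, p = fx.simulate(dt=1e-3, n_steps=5000)
        assert p[-1] == pytest.approx(np.exp(-5.0), rel=1e-3)

    def test_windkessel_impedance_amplitude_and_phase(self):
        """Sinusoidally driven 2-element Windkessel matches the analytic
        impedance solution within 0.5% after transients."""
        fx = hc.make_fixture("windkessel2", R=1.3, C=0.8, Q0=2.0, omega=2 * np.pi)
        dt = 1e-3
        t, p = fx.simulate(dt=dt, n_steps=12000)
        tail = slice(-2000, None)  # two periods, transient long gone
        assert np.max(np.abs(p[tail] - fx.analytic(t[tail]))) < 5e-3 * fx.analytic_amplitude

    def test_grid_convergence_of_cardiac_output(self, model, baseline_metrics):
        """Halving dt changes final-cycle CO by < 0.2% (order >= 2 scheme)."""
        w2 = hc.run_simulation(model, SimulationSettings(dt=0.0005, n_steps=16000))
        co_half = hc.compute_cardiac_metrics(w2).CO
        assert abs(co_half - baseline_metrics.CO) / baseline_metrics.CO < 0.002


class TestFullModelSimulation:
    def test_reaches_periodic_steady_state(self, baseline_wave, settings):
        """The shipped run settles below 1% cycle-to-cycle variation of
        cycle-averaged aortic flow and pressure."""
        conv = hc.cycle_convergence(baseline_wave, settings.convergence_threshold)
        assert conv["converged"]
        assert conv["flow_change"][-1] < 0.01
        assert conv["pressure_change"][-1] < 0.01

    def test_volume_conserved_over_final_cycles(self, model, baseline_wave):
        """Total stressed volume drifts < 0.1% over the last two cycles."""
        c = hc.extract_final_cycles(baseline_wave, 2)
        net = _Network.from_models([model])
        w = net.volume_weights()[0]
        states = np.stack([c[ch] for ch in STATE_LAYOUT], axis=1)
        vols = states @ w
        assert np.ptp(vols) / np.mean(vols) < 1e-3

    def test_steady_cycle_independent_of_initial_distribution(self, model, baseline_metrics):
        """Two initial states with the same total stressed volume but a
        different pressure/volume distribution converge to the same cycle
        within 1%.  (The closed loop conserves total volume, so only
        volume-preserving redistributions are admissible here.)"""
        x0 = hc.default_initial_state(m=model, node_pressure_mmhg=14.0)
        ref = hc.default_initial_state(model)
        excess = total_stressed_volume(model, x0) - total_stressed_volume(model, ref)
        x0[0] -= excess / 2
        x0[1] -= excess / 2
        w = hc.run_simulation(model, init=x0)
        m2 = hc.compute_cycle_metrics(w)
        for name in ("CO", "SV", "SBP", "DBP", "P_pv_mean"):
            a, b = getattr(baseline_metrics, name), getattr(m2, name)
            assert abs(a - b) / abs(a) < 0.01, name

    def test_divergence_reports_variable_and_time(self, model):
        bad = hc.default_initial_state(model)
        bad[0] = 1e15  # absurd LV volume
        with pytest.raises(hc.IntegrationError, match="state variable"):
            hc.run_simulation(model, init=bad)

    def test_settings_validation(self, model):
        with pytest.raises(ValueError):
            SimulationSettings(dt=-1e-3)
        with pytest.raises(ValueError):
            # 1 s span < 4 cardiac periods
            hc.run_simulation(model, SimulationSettings(dt=0.001, n_steps=1000))


class TestCycleConvergence:
    def _synthetic(self, per_cycle):
        period, dt = 0.5, 0.001
        n_cyc = len(per_cycle)
        t = np.arange(int(n_cyc * period / dt) + 1) * dt
        level = np.repeat(per_cycle, int(period / dt))
        level = np.append(level, level[-1])
        return WaveformSet(time=t, channels={"Q_aortic": level, "P_aorta": level + 3.0},
                           period=period)

    def test_perfectly_periodic_channel_has_zero_change(self):
        w = self._synthetic(np.ones(5))
        conv = hc.cycle_convergence(w)
        assert np.allclose(conv["flow_change"], 0.0)
        assert conv["converged"]

    def test_geometric_decay_yields_five_percent_changes(self):
        w = self._synthetic(10.0 * 0.95 ** np.arange(6))
        conv = hc.cycle_convergence(w)
        assert conv["flow_change"][0] == pytest.approx(0.05, rel=1e-6)
        assert not conv["converged"]

    def test_requires_two_cycles(self):
        t = np.arange(100) * 0.001
        w = WaveformSet(time=t, channels={"Q_aortic": np.ones(100),
                                          "P_aorta": np.ones(100)}, period=0.5)
        with pytest.raises(ValueError):
            hc.cycle_convergence(w)


class TestExtractFinalCycles:
    def test_window_length_is_n_periods(self, baseline_wave, model):
        c = hc.extract_final_cycles(baseline_wave, 2)
        assert c.time[-1] - c.time[0] == pytest.approx(2 * model.period, abs=1e-9)

    def test_sawtooth_single_tooth(self):
        w = hc.make_fixture("sawtooth", period=0.5, dt=0.001, n_periods=6)
        one = hc.extract_final_cycles(w, 1)
        assert one.time[-1] - one.time[0] == pytest.approx(0.5, abs=1e-12)
        saw = one["Q_aortic"]
        # exactly one rising tooth: strictly increasing except the wrap
        assert np.all(np.diff(saw[:-1]) > 0)

    def test_identity_on_whole_periodic_part(self):
        w = hc.make_fixture("sawtooth", period=0.5, dt=0.001, n_periods=4)
        all_cycles = hc.extract_final_cycles(w, 4)
        assert len(all_cycles.time) == len(w.time)
        assert np.array_equal(all_cycles["Q_aortic"], w["Q_aortic"])

    def test_insufficient_span_errors(self, baseline_wave):
        with pytest.raises(ValueError):
            hc.extract_final_cycles(baseline_wave, 100)


class TestWaveformSet:
    def test_rejects_nan_channels(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ValueError):
            WaveformSet(time=t, channels={"P_x": np.full(10, np.nan)}, period=0.5)

    def test_rejects_mismatched_grid(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ValueError):
            WaveformSet(time=t, channels={"P_x": np.ones(9)}, period=0.5)

    def test_report_unit_frame(self, baseline_wave):
        df = baseline_wave.to_frame()
        assert "P_aorta_mmHg" in df.columns
        assert "V_lv_mL" in df.columns
        assert df["P_aorta_mmHg"].max() == pytest.approx(
            baseline_wave["P_aorta"].max() / 133.322)
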