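"""Unit and property tests for the circuit elements and the assembled ODE
right-hand side."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import hepacirc as hc
from hepacirc.model import (
    MMHG_TO_PA,
    NSTATE,
    STATE_LAYOUT,
    ElastanceParams,
    HepaticParams,
    RcrParams,
    ValveParams,
    _Network,
    assemble_rhs,
    chamber_pressure,
    default_initial_state,
    elastance_at,
    valve_openness,
)


@pytest.fixture(scope="module")
def lv_elastance():
    return ElastanceParams(E_max=0.394, E_min=9e-5, T=0.684, t_max=0.377,
                           t_toRelax=0.104, V0=10_000.0)


class TestElastance:
    def test_key_points(self, lv_elastance):
        p = lv_elastance
        assert elastance_at(p.t_max, p) == pytest.approx(p.E_max)
        assert elastance_at(1e-12, p) == pytest.approx(p.E_min, abs=1e-12)
        assert elastance_at(p.t_max / 2, p) == pytest.approx((p.E_max + p.E_min) / 2)
        # peak elastance of the shipped left ventricle
        assert elastance_at(0.377, p) == pytest.approx(0.394)

    def test_diastasis_is_flat_minimum(self, lv_elastance):
        p = lv_elastance
        t = np.linspace(p.t_max + p.t_toRelax + 1e-6, p.T - 1e-9, 50)
        assert np.allclose(elastance_at(t, p), p.E_min)

    def test_domain_error_outside_cycle(self, lv_elastance):
        with pytest.raises(ValueError):
            elastance_at(lv_elastance.T, lv_elastance)
        with pytest.raises(ValueError):
            elastance_at(-0.01, lv_elastance)

    @given(
        E_max=st.floats(0.01, 1.0),
        E_min=st.floats(1e-5, 5e-3),
        t_max=st.floats(0.1, 0.5),
        t_toRelax=st.floats(0.05, 0.2),
    )
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_continuity_at_breakpoints(self, E_max, E_min, t_max, t_toRelax):
        """E(t) is continuous at the contraction peak and at the end of
        relaxation for any admissible parameter set."""
        p = ElastanceParams(E_max=E_max, E_min=E_min, T=t_max + t_toRelax + 0.2,
                            t_max=t_max, t_toRelax=t_toRelax, V0=0.0)
        eps = 1e-9
        assert abs(elastance_at(t_max - eps, p) - elastance_at(t_max + eps, p)) < 1e-10
        t_end = t_max + t_toRelax
        assert abs(elastance_at(t_end - eps, p) - p.E_min) < 1e-10

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ElastanceParams(E_max=0.1, E_min=0.2, T=1.0, t_max=0.3, t_toRelax=0.1, V0=0)
        with pytest.raises(ValueError):
            ElastanceParams(E_max=0.2, E_min=0.1, T=0.3, t_max=0.3, t_toRelax=0.1, V0=0)
        with pytest.raises(ValueError):
            ElastanceParams(E_max=0.2, E_min=0.1, T=1.0, t_max=0.3, t_toRelax=0.1, V0=-1)


class TestChamberPressure:
    def test_examples(self):
        assert chamber_pressure(10_000.0, 0.394, 10_000.0) == 0.0
        assert chamber_pressure(60_000.0, 0.394, 10_000.0) == pytest.approx(19_700.0)
        assert chamber_pressure(110_000.0, 9e-5, 10_000.0) == pytest.approx(9.0)

    def test_negative_below_unstressed_volume(self):
        assert chamber_pressure(5_000.0, 0.1, 10_000.0) < 0.0


class TestValveOpenness:
    def test_symmetry_and_saturation(self):
        v = ValveParams(R=1e-5, L=1e-5)
        assert valve_openness(0.0, v) == pytest.approx(0.5)
        assert valve_openness(10 * v.steepness, v) == pytest.approx(1.0, abs=1e-8)
        assert valve_openness(-10 * v.steepness, v) == pytest.approx(0.0, abs=1e-8)

    @given(dp=st.floats(-1e4, 1e4), dp2=st.floats(-1e4, 1e4))
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_pressure_drop(self, dp, dp2):
        v = ValveParams(R=1e-5, L=1e-5)
        lo, hi = sorted([dp, dp2])
        assert valve_openness(lo, v) <= valve_openness(hi, v) + 1e-15

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ValveParams(R=0.0, L=1e-5)
        with pytest.raises(ValueError):
            ValveParams(R=1e-5, L=1e-5, closed_resistance_factor=100.0)


class TestContainers:
    def test_rcr_invariants(self):
        with pytest.raises(ValueError):
            RcrParams(R_p=0.1, C=0.0, R_d=0.1)
        with pytest.raises(ValueError):
            RcrParams(R_p=-0.1, C=1.0, R_d=0.1)

    def test_hepatic_invariants(self):
        good = hc.default_model().hepatic
        with pytest.raises(ValueError):
            dataclasses.replace(good, R_hs=0.0)
        with pytest.raises(ValueError):
            dataclasses.replace(good, C_pv=-1.0)

    def test_hepatic_vein_parallel(self):
        h = hc.default_model().hepatic
        assert h.R_hv_parallel == pytest.approx(1e-5 / 3)

    def test_state_layout_unique_and_complete(self, model):
        assert len(set(STATE_LAYOUT)) == NSTATE
        assert model.state_layout == STATE_LAYOUT
        # two chambers, four inductor branches, eight capacitor nodes
        assert sum(n.startswith("V_") for n in STATE_LAYOUT) == 2
        assert sum(n.startswith("Q_") for n in STATE_LAYOUT) == 4
        assert sum(n.startswith("P_") for n in STATE_LAYOUT) == 8

    def test_mismatched_timing_rejected(self, model):
        bad_rv = dataclasses.replace(model.right_ventricle, T=0.7)
        with pytest.raises(ValueError):
            model.replace(right_ventricle=bad_rv)


class TestAssembleRhs:
    def test_volume_conservation_random_states(self, model, rng):
        """The weighted sum of all volume rates (chambers + C·dP/dt) vanishes
        at any state: the closed loop conserves blood volume."""
        net = _Network.from_models([model])
        w = net.volume_weights()[0]
        for _ in range(20):
            x = default_initial_state(model) * rng.uniform(0.2, 3.0, NSTATE)
            t = rng.uniform(0.0, model.period)
            f = assemble_rhs(t, x, model)
            scale = np.sum(np.abs(w * f)) + 1e-30
            assert abs(w @ f) / scale < 1e-10

    def test_equilibrium_state(self, model):
        """With all node pressures equal and zero flows, only the valve
        branches (driven by chamber-node pressure differences) and chamber
        terms may move."""
        p0 = 10.0 * MMHG_TO_PA
        x = default_initial_state(model)
        # chamber volumes chosen so that P_chamber = p0 at t in diastasis
        e_min = model.left_ventricle.E_min
        x[0] = x[1] = model.left_ventricle.V0 + p0 / e_min
        t = model.period - 1e-4  # diastasis: E = E_min in both chambers
        f = assemble_rhs(t, x, model)
        # all capacitor-node derivatives vanish except those fed by valves
        names = dict(zip(STATE_LAYOUT, f))
        for n in ("P_ha", "P_digestive", "P_other", "P_pv", "P_sinusoid"):
            assert abs(names[n]) < 1e-9, n

    def test_rc_discharge_subcircuit(self):
        fx = hc.make_fixture("rc_discharge", R=2.0, C=3.0, P0=5.0)
        # dP/dt at t=0 equals -P0/(R C)
        t, p = fx.simulate(dt=1e-3, n_steps=10)
        dpdt = (p[1] - p[0]) / 1e-3
        assert dpdt == pytest.approx(-5.0 / 6.0, rel=1e-3)

    def test_nonfinite_state_faults(self, model):
        x = default_initial_state(model)
        x[3] = np.nan
        with pytest.raises(hc.IntegrationError):
            assemble_rhs(0.0, x, model)

    def test_shape_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            assemble_rhs(0.0, np.zeros(NSTATE - 1), model)
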