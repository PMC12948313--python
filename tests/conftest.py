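"""Shared fixtures: the heavy steady-state simulations are session-scoped
so the baseline and severe-injury runs are computed once."""

from __future__ import annotations

import numpy as np
import pytest

import hepacirc as hc
from hepacirc.scenarios import apply_injury


@pytest.fixture(scope="session")
def model():
    return hc.default_model()


@pytest.fixture(scope="session")
def settings():
    return hc.SimulationSettings()


@pytest.fixture(scope="session")
def baseline_wave(model, settings):
    """Healthy baseline (M1) simulated to periodic steady state."""
    return hc.run_simulation(model, settings)


@pytest.fixture(scope="session")
def m20_wave(model, settings):
    """Severe-injury scenario (M20): hepatic microvascular resistances x20."""
    m20 = apply_injury(model, 20.0)
    return hc.run_simulation(m20, settings, init=hc.default_initial_state(m20))


@pytest.fixture(scope="session")
def baseline_metrics(baseline_wave):
    return hc.compute_cycle_metrics(baseline_wave)


@pytest.fixture(scope="session")
def m20_metrics(m20_wave):
    return hc.compute_cycle_metrics(m20_wave)


@pytest.fixture(scope="session")
def injury_sweep_table(model, settings):
    """Full M1..M20 graded-injury sweep (five steady-state simulations)."""
    return hc.run_injury_sweep(model, (1, 5, 10, 15, 20), settings)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
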