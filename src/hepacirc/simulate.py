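"""Fixed-step time integration of the closed-loop model and steady-cycle
extraction.

The system is stiff (closed valves have branch time constants of order
L/R_closed ~ 1e-6 s, far below the 1 ms step), so the integrator is TR-BDF2:
a one-step, L-stable, second-order composite of a trapezoidal half-stage and
a BDF2 stage.  Because the circuit equations are linear in the state once
the valve resistances (tanh of a pressure difference) and elastances are
frozen, each stage reduces to a small linear solve; the valve nonlinearity
is handled by two fixed-point iterations per stage.  The integrator carries
a batch dimension so that large parameter sweeps (e.g. the Saltelli design)
integrate simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    IP_CV,
    IP_DIG,
    IP_HA,
    IP_HS,
    IP_LA,
    IP_LUNG,
    IP_OTH,
    IP_PV,
    IQ_AV,
    IQ_MV,
    IQ_PV,
    IQ_TV,
    IV_LV,
    IV_RV,
    MM3_TO_ML,
    MM3S_TO_LMIN,
    NSTATE,
    PA_TO_MMHG,
    CirculationModel,
    IntegrationError,
    STATE_LAYOUT,
    _Network,
    default_initial_state,
)

__all__ = [
    "SimulationSettings",
    "WaveformSet",
    "run_simulation",
    "cycle_convergence",
    "extract_final_cycles",
]

logger = logging.getLogger("hepacirc")

_GAMMA = 2.0 - np.sqrt(2.0)  # TR-BDF2 stage fraction
_DIVERGENCE_LIMIT = 1.0e12
_PICARD_ITERS = 2


@dataclass(frozen=True)
class SimulationSettings:
    """Fixed-grid integration settings.

    dt: time step (s); n_steps: number of steps; convergence_threshold:
    maximum relative change of cycle-averaged aortic flow/pressure between
    consecutive cycles for the run to count as periodic;
    n_report_cycles: how many final cycles are extracted for analysis.
    """

    dt: float = 0.001
    n_steps: int = 8000
    convergence_threshold: float = 0.01
    n_report_cycles: int = 2

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 < self.convergence_threshold < 1.0):
            raise ValueError("convergence_threshold must be in (0, 1)")

    def validate_span(self, period: float) -> None:
        if self.n_steps * self.dt < 4.0 * period:
            raise ValueError(
                f"simulation span {self.n_steps * self.dt:.3f} s must cover "
                f">= 4 cardiac periods ({4 * period:.3f} s)"
            )


@dataclass
class WaveformSet:
    """Time-indexed pressures (Pa), flows (mm^3/s) and volumes (mm^3).

    All channels share the ``time`` grid; ``period`` is the cardiac period.
    Channel names: P_* pressures, Q_* flows, V_* chamber volumes.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    period: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name} does not share the time grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name} contains NaN/Inf")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def n_cycles(self) -> int:
        """Number of complete cardiac periods spanned."""
        span = float(self.time[-1] - self.time[0])
        return int(np.floor(span / self.period + 1e-9))

    def to_frame(self) -> pd.DataFrame:
        """Report-unit table: pressures mmHg, flows mL/s, volumes mL."""
        data: dict[str, np.ndarray] = {"time": self.time}
        for name, arr in self.channels.items():
            if name.startswith("P_"):
                data[f"{name}_mmHg"] = arr * PA_TO_MMHG
            elif name.startswith("Q_"):
                data[f"{name}_mL_s"] = arr * MM3_TO_ML
            else:
                data[f"{name}_mL"] = arr * MM3_TO_ML
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Core batched TR-BDF2 integrator
# ---------------------------------------------------------------------------


def _solve_stage(net: _Network, t_stage: float, h: float, rhs_const: np.ndarray,
                 x_guess: np.ndarray) -> np.ndarray:
    """Solve x = rhs_const + h·(A(t,x)·x + c(t,x)) by fixed-point iteration
    on the valve resistances (the only state dependence of A, c)."""
    eye = np.eye(x_guess.shape[-1])
    x = x_guess
    for _ in range(_PICARD_ITERS):
        A, c = net.system(t_stage, x)
        M = eye[None, :, :] - h * A
        b = rhs_const + h * c
        x = np.linalg.solve(M, b[..., None])[..., 0]
    return x


def _integrate(
    net: _Network,
    x0: np.ndarray,
    dt: float,
    n_steps: int,
    record_from: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the batch from x0 over n_steps; record states from step
    ``record_from`` on (inclusive, counting the initial state as step 0).

    Returns (traj, ok): traj has shape (B, n_rec, NSTATE); ok is a boolean
    mask of batch elements that stayed finite and bounded.
    """
    B = net.B
    x = np.array(x0, dtype=float)
    if x.ndim != 2 or x.shape[0] != B:
        raise ValueError("x0 shape must be (B, n_states)")
    nstate = x.shape[1]
    names = getattr(net, "state_names", STATE_LAYOUT)

    n_rec = n_steps + 1 - record_from
    traj = np.full((B, n_rec, nstate), np.nan)
    ok = np.ones(B, dtype=bool)
    if record_from == 0:
        traj[:, 0] = x

    g, dt_ = _GAMMA, dt
    w1 = 1.0 / (g * (2.0 - g))
    w2 = (1.0 - g) ** 2 / (g * (2.0 - g))
    w3 = (1.0 - g) / (2.0 - g)

    for n in range(n_steps):
        t = n * dt_
        A_n, c_n = net.system(t, x)
        f_n = (A_n @ x[..., None])[..., 0] + c_n

        # trapezoidal half-stage to t + γ·dt
        t_g = t + g * dt_
        xg = _solve_stage(net, t_g, 0.5 * g * dt_, x + 0.5 * g * dt_ * f_n,
                          x + g * dt_ * f_n)
        # BDF2 stage to t + dt
        x_new = _solve_stage(net, t + dt_, w3 * dt_, w1 * xg - w2 * x,
                             xg + (1.0 - g) * dt_ * f_n)

        bad = ~np.all(np.isfinite(x_new), axis=1) | (
            np.nanmax(np.abs(x_new), axis=1) > _DIVERGENCE_LIMIT
        )
        newly_bad = bad & ok
        if np.any(newly_bad):
            if B == 1:
                j = int(np.argmax(~np.isfinite(x_new[0]) | (np.abs(x_new[0]) > _DIVERGENCE_LIMIT)))
                raise IntegrationError(
                    f"integration diverged at t={t + dt_:.4f} s "
                    f"(state variable '{names[j]}')"
                )
            ok &= ~bad
            x_new[newly_bad] = np.nan
        # freeze failed elements so they stop contaminating the solve
        x_new[~ok] = 0.0
        x = x_new
        if n + 1 >= record_from:
            traj[:, n + 1 - record_from] = x

    traj[~ok] = np.nan
    return traj, ok


def _derived_channels(net: _Network, traj: np.ndarray, time: np.ndarray,
                      b: int = 0) -> dict[str, np.ndarray]:
    """All named waveform channels for batch element ``b``."""
    x = traj[b]  # (n, NSTATE)
    eL, eR = net.elastances(time)
    eL = eL[..., b] if eL.ndim > 1 else eL
    eR = eR[..., b] if eR.ndim > 1 else eR
    p_lv = eL * (x[:, IV_LV] - net.V0L[b])
    p_rv = eR * (x[:, IV_RV] - net.V0R[b])
    p_sa = net.Rsa[b] * (
        x[:, IQ_AV]
        + net.G_ha[b] * x[:, IP_HA]
        + net.G_dig[b] * x[:, IP_DIG]
        + net.G_oth[b] * x[:, IP_OTH]
    )
    p_cvj = net.Rcj[b] * (
        net.G_od[b] * x[:, IP_OTH]
        + net.G_lo[b] * x[:, IP_HS]
        + net.G_cp[b] * x[:, IP_CV]
    )
    q_liver_out = (x[:, IP_HS] - p_cvj) / net.R_lo[b]
    p_hv = x[:, IP_HS] - q_liver_out * net.R_hs[b]  # hepatic-vein junction
    return {
        "V_lv": x[:, IV_LV],
        "V_rv": x[:, IV_RV],
        "Q_mitral": x[:, IQ_MV],
        "Q_aortic": x[:, IQ_AV],
        "Q_tricuspid": x[:, IQ_TV],
        "Q_pulmonary": x[:, IQ_PV],
        "P_lv": p_lv,
        "P_rv": p_rv,
        "P_aorta": p_sa,
        "P_ha": x[:, IP_HA],
        "P_digestive": x[:, IP_DIG],
        "P_other": x[:, IP_OTH],
        "P_pv": x[:, IP_PV],
        "P_sinusoid": x[:, IP_HS],
        "P_hepatic_vein": p_hv,
        "P_cv": x[:, IP_CV],
        "P_lung": x[:, IP_LUNG],
        "P_la": x[:, IP_LA],
        "Q_portal": (x[:, IP_PV] - x[:, IP_HS]) / net.R_pv_d[b],
        "Q_hepatic_artery": (x[:, IP_HA] - x[:, IP_HS]) / net.R_ha_d[b],
        "Q_hepatic_vein": q_liver_out,
    }


def run_simulation(
    m: CirculationModel,
    settings: SimulationSettings | None = None,
    init: np.ndarray | None = None,
) -> WaveformSet:
    """Integrate the closed-loop model on the fixed grid and return the full
    trajectory as a :class:`WaveformSet`.

    ``init`` follows :data:`hepacirc.model.STATE_LAYOUT`; by default the
    shipped initial state is used.  Raises :class:`IntegrationError` (naming
    the first offending state variable and time) on divergence.
    """
    settings = settings or SimulationSettings()
    settings.validate_span(m.period)
    if init is None:
        init = default_initial_state(m)
    init = np.asarray(init, dtype=float)
    if init.shape != (NSTATE,):
        raise ValueError(f"init must have shape ({NSTATE},)")

    net = _Network.from_models([m])
    traj, _ = _integrate(net, init[None, :], settings.dt, settings.n_steps)
    time = np.arange(settings.n_steps + 1) * settings.dt
    w = WaveformSet(time=time, channels=_derived_channels(net, traj, time),
                    period=m.period)

    conv = cycle_convergence(w, settings.convergence_threshold)
    logger.info(
        "simulated %d cycles; periodic=%s (last cycle-to-cycle change: "
        "flow %.4f, pressure %.4f)",
        w.n_cycles(), conv["converged"],
        conv["flow_change"][-1] if len(conv["flow_change"]) else np.nan,
        conv["pressure_change"][-1] if len(conv["pressure_change"]) else np.nan,
    )
    return w


# ---------------------------------------------------------------------------
# Periodic steady state
# ---------------------------------------------------------------------------


def _cycle_means(w: WaveformSet, name: str) -> np.ndarray:
    steps_per_cycle = w.period / w.dt
    n_cyc = w.n_cycles()
    arr = w[name]
    means = np.empty(n_cyc)
    for k in range(n_cyc):
        i0 = int(round(k * steps_per_cycle))
        i1 = int(round((k + 1) * steps_per_cycle))
        means[k] = np.mean(arr[i0:i1])
    return means


def cycle_convergence(w: WaveformSet, threshold: float = 0.01) -> dict:
    """Per-cycle relative change of cycle-averaged aortic flow and pressure.

    Returns {"flow_change", "pressure_change", "converged"}; the run is
    periodic when the final change of both channels is below ``threshold``.
    """
    if w.n_cycles() < 2:
        raise ValueError("waveform must span at least 2 full periods")
    dq = _rel_changes(_cycle_means(w, "Q_aortic"))
    dp = _rel_changes(_cycle_means(w, "P_aorta"))
    converged = bool(dq[-1] < threshold and dp[-1] < threshold)
    return {"flow_change": dq, "pressure_change": dp, "converged": converged}


def _rel_changes(means: np.ndarray) -> np.ndarray:
    denom = np.maximum(np.abs(means[:-1]), 1e-300)
    return np.abs(np.diff(means)) / denom


def extract_final_cycles(w: WaveformSet, n: int) -> WaveformSet:
    """Restrict ``w`` to its last ``n`` complete cardiac periods.

    The window is aligned to period boundaries (cycle start = onset of the
    elastance rise, i.e. t mod T = 0).
    """
    n_cyc = w.n_cycles()
    if n < 1 or n > n_cyc:
        raise ValueError(f"waveform spans {n_cyc} complete cycles; cannot extract {n}")
    steps_per_cycle = w.period / w.dt
    i0 = int(round((n_cyc - n) * steps_per_cycle))
    i1 = int(round(n_cyc * steps_per_cycle))
    sl = slice(i0, i1 + 1)
    return WaveformSet(
        time=w.time[sl],
        channels={k: v[sl] for k, v in w.channels.items()},
        period=w.period,
    )


# ---------------------------------------------------------------------------
# Batched steady-state evaluation (used by the sensitivity module)
# ---------------------------------------------------------------------------


def run_batch_final_cycle(
    net: _Network,
    settings: SimulationSettings,
    init: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a parameter batch and return only the final complete cycle.

    Returns (time, traj, ok): traj has shape (B, n_cycle_steps + 1, NSTATE),
    time is the absolute time grid of that window, ok flags batch elements
    that integrated without divergence.
    """
    period = float(net.T[0])
    steps_per_cycle = period / settings.dt
    n_cyc = int(np.floor(settings.n_steps * settings.dt / period + 1e-9))
    if n_cyc < 2:
        raise ValueError("batch run must span >= 2 cycles")
    i0 = int(round((n_cyc - 1) * steps_per_cycle))
    i1 = int(round(n_cyc * steps_per_cycle))
    traj, ok = _integrate(net, init, settings.dt, settings.n_steps, record_from=i0)
    time = np.arange(i0, settings.n_steps + 1) * settings.dt
    keep = i1 - i0 + 1
    return time[:keep], traj[:, :keep], ok
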