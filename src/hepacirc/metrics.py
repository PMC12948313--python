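"""Scalar hemodynamic indices computed from a periodic steady cycle.

Cardiac indices: cardiac output CO (cycle-mean aortic flow), peak aortic
flow, SBP/DBP/MAP, end-diastolic and end-systolic volume, stroke volume
SV = EDV − ESV, stroke work SW (area of the left-ventricular pressure–volume
loop), end-systolic pressure ESP (LV pressure at aortic-valve closure),
effective arterial elastance Ea = ESP/SV, and ejection fraction
LVEF = SV/EDV·100.

Hepatic indices: cycle-mean portal and hepatic-arterial inflow to the
sinusoid, total hepatic venous outflow, the arterial fraction of hepatic
inflow, and mean portal / hepatic-vein pressures.  Portal pressure is
measured at the sinusoidal inlet node where portal blood enters the liver
(the presinusoidal convergence point, analogous to a wedged portal pressure
reading); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .model import MM3_TO_ML, MM3S_TO_LMIN, PA_TO_MMHG
from .simulate import WaveformSet, extract_final_cycles

__all__ = [
    "CycleMetrics",
    "compute_cardiac_metrics",
    "compute_hepatic_metrics",
    "compute_cycle_metrics",
    "loop_area",
    "metrics_table",
]

# Aortic-valve closure proxy: first instant after peak flow where forward
# flow has fallen below this fraction of the cycle peak.
_VALVE_CLOSURE_FRACTION = 0.005


@dataclass
class CycleMetrics:
    """Per-steady-cycle summary in report units (mmHg, mL, L/min)."""

    CO: float = np.nan              # L/min
    Q_aorta_max: float = np.nan     # L/min
    SBP: float = np.nan             # mmHg
    DBP: float = np.nan             # mmHg
    MAP: float = np.nan             # mmHg (time-averaged aortic pressure)
    EDV: float = np.nan             # mL
    ESV: float = np.nan             # mL
    SV: float = np.nan              # mL
    SW: float = np.nan              # mmHg·mL
    ESP: float = np.nan             # mmHg
    Ea: float = np.nan              # mmHg/mL
    LVEF: float = np.nan            # %
    P_pv_mean: float = np.nan       # mmHg, portal pressure at sinusoidal inlet
    P_hv_mean: float = np.nan       # mmHg, hepatic-vein junction
    Q_pv: float = np.nan            # L/min, portal inflow to sinusoid
    Q_ha: float = np.nan            # L/min, arterial inflow to sinusoid
    Q_hv_total: float = np.nan      # L/min, hepatic venous outflow
    arterial_fraction: float = np.nan  # % of hepatic inflow that is arterial

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _final_cycle(w: WaveformSet) -> WaveformSet:
    if w.n_cycles() < 1:
        raise ValueError("waveform does not span a complete cycle")
    return extract_final_cycles(w, 1)


def loop_area(pv) -> float:
    """Signed shoelace area of a closed polygon of (V, P) points.

    Positive for the physiologic counter-clockwise traversal of the
    pressure–volume loop in the (V, P) plane.  The sequence must close
    (first point ~ last point; a duplicated closing point is accepted).
    """
    pts = np.asarray(pv, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("pv must be an (n >= 3, 2) sequence of (V, P) points")
    v, p = pts[:, 0], pts[:, 1]
    scale_v = max(np.ptp(v), 1e-300)
    scale_p = max(np.ptp(p), 1e-300)
    if (abs(v[0] - v[-1]) > 1e-6 * scale_v) or (abs(p[0] - p[-1]) > 1e-6 * scale_p):
        raise ValueError("pv polygon is not closed (first point != last point)")
    # drop the duplicated closing vertex; shoelace wraps around
    v, p = v[:-1], p[:-1]
    if len(v) < 3:
        raise ValueError("degenerate polygon (< 3 distinct points)")
    return float(0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def _esp(q_av: np.ndarray, p_lv: np.ndarray) -> float:
    """LV pressure (Pa) at aortic-valve closure (flow < 0.5% of cycle peak
    after the peak)."""
    peak = int(np.argmax(q_av))
    q_peak = q_av[peak]
    if q_peak <= 0.0:
        raise ValueError("no forward aortic flow in cycle; cannot locate end-systole")
    after = q_av[peak:]
    below = np.nonzero(after < _VALVE_CLOSURE_FRACTION * q_peak)[0]
    if len(below) == 0:
        raise ValueError("aortic valve never closes within the cycle")
    return float(p_lv[peak + below[0]])


def compute_cardiac_metrics(w: WaveformSet, out: CycleMetrics | None = None) -> CycleMetrics:
    """Cardiac fields of :class:`CycleMetrics` from the final steady cycle."""
    c = _final_cycle(w)
    m = out or CycleMetrics()

    q_av = c["Q_aortic"]
    p_ao = c["P_aorta"]
    v_lv = c["V_lv"]
    p_lv = c["P_lv"]

    m.CO = float(np.mean(q_av)) * MM3S_TO_LMIN
    m.Q_aorta_max = float(np.max(q_av)) * MM3S_TO_LMIN
    m.SBP = float(np.max(p_ao)) * PA_TO_MMHG
    m.DBP = float(np.min(p_ao)) * PA_TO_MMHG
    m.MAP = float(np.mean(p_ao)) * PA_TO_MMHG
    m.EDV = float(np.max(v_lv)) * MM3_TO_ML
    m.ESV = float(np.min(v_lv)) * MM3_TO_ML
    m.SV = m.EDV - m.ESV
    # PV loop traversed over one period; close it explicitly
    pts = np.column_stack([
        np.append(v_lv, v_lv[0]) * MM3_TO_ML,
        np.append(p_lv, p_lv[0]) * PA_TO_MMHG,
    ])
    m.SW = loop_area(pts)
    m.ESP = _esp(q_av, p_lv) * PA_TO_MMHG
    m.Ea = m.ESP / m.SV
    m.LVEF = m.SV / m.EDV * 100.0
    return m


def compute_hepatic_metrics(w: WaveformSet, out: CycleMetrics | None = None) -> CycleMetrics:
    """Hepatic fields of :class:`CycleMetrics` from the final steady cycle."""
    c = _final_cycle(w)
    m = out or CycleMetrics()

    m.Q_pv = float(np.mean(c["Q_portal"])) * MM3S_TO_LMIN
    m.Q_ha = float(np.mean(c["Q_hepatic_artery"])) * MM3S_TO_LMIN
    m.Q_hv_total = float(np.mean(c["Q_hepatic_vein"])) * MM3S_TO_LMIN
    total_in = m.Q_pv + m.Q_ha
    m.arterial_fraction = 0.0 if total_in <= 0.0 else m.Q_ha / total_in * 100.0
    m.P_pv_mean = float(np.mean(c["P_sinusoid"])) * PA_TO_MMHG
    m.P_hv_mean = float(np.mean(c["P_hepatic_vein"])) * PA_TO_MMHG
    return m


def compute_cycle_metrics(w: WaveformSet) -> CycleMetrics:
    """All cardiac and hepatic indices from the final steady cycle of ``w``."""
    m = compute_cardiac_metrics(w)
    return compute_hepatic_metrics(w, out=m)


def metrics_table(rows: dict[str, CycleMetrics]) -> pd.DataFrame:
    """One row per scenario; columns are the CycleMetrics fields."""
    return pd.DataFrame({label: m.to_dict() for label, m in rows.items()}).T
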