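"""Configuration loading/validation, result serialization, fixtures, and
run manifests.

The model configuration file (YAML) mirrors the parameter tables
field-for-field in their original units (R: Pa·s·mm^-3, L: Pa·s^2·mm^-3,
C: mm^3·Pa^-1, E: Pa·mm^-3, times: s, V0: mL).  The loader is strict:
unknown keys, missing fields, or invariant violations raise a descriptive
schema error.  User-facing tables (waveforms, metrics, Sobol indices) are
written as CSV in report units with >= 10 significant digits so they parse
back losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    ML_TO_MM3,
    MM3_TO_ML,
    CirculationModel,
    ElastanceParams,
    HepaticParams,
    RcrParams,
    ValveParams,
)
from .simulate import WaveformSet

__all__ = [
    "load_model_config",
    "save_model_config",
    "default_config_path",
    "make_fixture",
    "write_manifest",
    "waveform_to_csv",
    "frame_to_csv",
]

logger = logging.getLogger("hepacirc")

_CSV_FLOAT_FORMAT = "%.12g"


class ConfigError(ValueError):
    """Schema violation in a model configuration file."""


# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------

_VALVE_KEYS = {"R", "L", "steepness", "closed_resistance_factor"}
_RCR_KEYS = {"R_p", "C", "R_d"}
_ELASTANCE_KEYS = {"E_maxL", "E_minL", "E_maxR", "E_minR", "T", "t_max",
                   "t_toRelax", "V0_mL"}
_HEPATIC_SECTIONS = {"portal_vein", "hepatic_artery", "sinusoid", "hepatic_veins"}


def _check_keys(section: str, d: dict, allowed: set, required: set | None = None) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    missing = (required if required is not None else allowed) - set(d)
    if missing:
        raise ConfigError(f"missing key(s) in '{section}': {sorted(missing)}")


def _valve(section: str, d: dict) -> ValveParams:
    _check_keys(section, d, _VALVE_KEYS, required={"R", "L"})
    try:
        return ValveParams(**{k: float(v) for k, v in d.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid valve parameters in '{section}': {exc}") from exc


def _rcr(section: str, d: dict) -> RcrParams:
    _check_keys(section, d, _RCR_KEYS)
    try:
        return RcrParams(R_p=float(d["R_p"]), C=float(d["C"]), R_d=float(d["R_d"]))
    except ValueError as exc:
        raise ConfigError(f"invalid RCR parameters in '{section}': {exc}") from exc


def load_model_config(path) -> CirculationModel:
    """Build a :class:`CirculationModel` from a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return model_from_dict(raw)


def model_from_dict(raw: dict) -> CirculationModel:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys("<root>", raw, {"valves", "elastance", "compartments", "hepatic"})

    valves = raw["valves"]
    _check_keys("valves", valves, {"mitral", "aortic", "tricuspid", "pulmonary"})
    mitral = _valve("valves.mitral", valves["mitral"])
    aortic = _valve("valves.aortic", valves["aortic"])
    tricuspid = _valve("valves.tricuspid", valves["tricuspid"])
    pulmonary = _valve("valves.pulmonary", valves["pulmonary"])

    el = raw["elastance"]
    _check_keys("elastance", el, _ELASTANCE_KEYS)
    try:
        v0 = float(el["V0_mL"]) * ML_TO_MM3
        lv = ElastanceParams(E_max=float(el["E_maxL"]), E_min=float(el["E_minL"]),
                             T=float(el["T"]), t_max=float(el["t_max"]),
                             t_toRelax=float(el["t_toRelax"]), V0=v0)
        rv = ElastanceParams(E_max=float(el["E_maxR"]), E_min=float(el["E_minR"]),
                             T=float(el["T"]), t_max=float(el["t_max"]),
                             t_toRelax=float(el["t_toRelax"]), V0=v0)
    except ValueError as exc:
        raise ConfigError(f"invalid elastance parameters: {exc}") from exc

    comp = raw["compartments"]
    _check_keys("compartments", comp,
                {"lung", "digestive", "other_organs", "central_venous",
                 "pulmonary_venous_compliance"})
    lung = _rcr("compartments.lung", comp["lung"])
    digestive = _rcr("compartments.digestive", comp["digestive"])
    other_organs = _rcr("compartments.other_organs", comp["other_organs"])
    central_venous = _rcr("compartments.central_venous", comp["central_venous"])
    c_la = float(comp["pulmonary_venous_compliance"])

    hep = raw["hepatic"]
    _check_keys("hepatic", hep, _HEPATIC_SECTIONS)
    pv = hep["portal_vein"]
    ha = hep["hepatic_artery"]
    hs = hep["sinusoid"]
    hv = hep["hepatic_veins"]
    _check_keys("hepatic.portal_vein", pv, _RCR_KEYS)
    _check_keys("hepatic.hepatic_artery", ha, _RCR_KEYS)
    _check_keys("hepatic.sinusoid", hs, {"C", "R_d"})
    _check_keys("hepatic.hepatic_veins", hv, {"left", "middle", "right"})
    try:
        hepatic = HepaticParams(
            R_pv_p=float(pv["R_p"]), R_pv_d=float(pv["R_d"]), C_pv=float(pv["C"]),
            R_ha_p=float(ha["R_p"]), R_ha_d=float(ha["R_d"]), C_ha=float(ha["C"]),
            R_hs=float(hs["R_d"]), C_hs=float(hs["C"]),
            R_lhv=float(hv["left"]), R_mhv=float(hv["middle"]), R_rhv=float(hv["right"]),
        )
        return CirculationModel(
            left_ventricle=lv, right_ventricle=rv,
            mitral=mitral, aortic=aortic, tricuspid=tricuspid, pulmonary=pulmonary,
            lung=lung, digestive=digestive, other_organs=other_organs,
            central_venous=central_venous, hepatic=hepatic,
            pulmonary_venous_compliance=c_la,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc


def model_to_dict(m: CirculationModel) -> dict:
    def valve(v: ValveParams) -> dict:
        return {"R": v.R, "L": v.L, "steepness": v.steepness,
                "closed_resistance_factor": v.closed_resistance_factor}

    def rcr(p: RcrParams) -> dict:
        return {"R_p": p.R_p, "C": p.C, "R_d": p.R_d}

    lv, rv, h = m.left_ventricle, m.right_ventricle, m.hepatic
    return {
        "valves": {
            "mitral": valve(m.mitral), "aortic": valve(m.aortic),
            "tricuspid": valve(m.tricuspid), "pulmonary": valve(m.pulmonary),
        },
        "elastance": {
            "E_maxL": lv.E_max, "E_minL": lv.E_min,
            "E_maxR": rv.E_max, "E_minR": rv.E_min,
            "T": lv.T, "t_max": lv.t_max, "t_toRelax": lv.t_toRelax,
            "V0_mL": lv.V0 * MM3_TO_ML,
        },
        "compartments": {
            "lung": rcr(m.lung), "digestive": rcr(m.digestive),
            "other_organs": rcr(m.other_organs),
            "central_venous": rcr(m.central_venous),
            "pulmonary_venous_compliance": m.pulmonary_venous_compliance,
        },
        "hepatic": {
            "portal_vein": {"R_p": h.R_pv_p, "C": h.C_pv, "R_d": h.R_pv_d},
            "hepatic_artery": {"R_p": h.R_ha_p, "C": h.C_ha, "R_d": h.R_ha_d},
            "sinusoid": {"C": h.C_hs, "R_d": h.R_hs},
            "hepatic_veins": {"left": h.R_lhv, "middle": h.R_mhv, "right": h.R_rhv},
        },
    }


def save_model_config(m: CirculationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(m), fh, sort_keys=False)


def default_config_path():
    """Path to the shipped healthy-baseline configuration."""
    return resources.files("hepacirc").joinpath("data/default_model.yaml")


# ---------------------------------------------------------------------------
# Analytic test fixtures
# ---------------------------------------------------------------------------


class _ScalarSystem:
    """Minimal one-state linear system driving the shared TR-BDF2 core."""

    B = 1
    state_names = ("P",)

    def __init__(self, a: float, forcing=None):
        self._a = a
        self._forcing = forcing

    def system(self, t: float, x: np.ndarray):
        A = np.array([[[self._a]]])
        c = np.zeros((1, 1))
        if self._forcing is not None:
            c[0, 0] = self._forcing(t)
        return A, c


@dataclass
class RcDischargeFixture:
    """Capacitor C discharging through resistance R from pressure P0.

    Closed form: P(t) = P0 · exp(−t / (R·C)).
    """

    R: float = 1.0
    C: float = 1.0
    P0: float = 1.0

    def analytic(self, t):
        return self.P0 * np.exp(-np.asarray(t, dtype=float) / (self.R * self.C))

    def simulate(self, dt: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        from .simulate import _integrate

        sys_ = _ScalarSystem(-1.0 / (self.R * self.C))
        traj, _ = _integrate(sys_, np.array([[self.P0]]), dt, n_steps)
        time = np.arange(n_steps + 1) * dt
        return time, traj[0, :, 0]


@dataclass
class Windkessel2Fixture:
    """Two-element Windkessel driven by Q(t) = Q0·sin(ω t).

    C dP/dt = Q(t) − P/R.  After transients the pressure is sinusoidal
    with amplitude Q0·|Z| where |Z| = R / sqrt(1 + (ωRC)^2) and phase lag
    arctan(ωRC) behind the flow.
    """

    R: float = 1.0
    C: float = 1.0
    Q0: float = 1.0
    omega: float = 2.0 * np.pi

    @property
    def analytic_amplitude(self) -> float:
        return self.Q0 * self.R / np.sqrt(1.0 + (self.omega * self.R * self.C) ** 2)

    @property
    def analytic_phase_lag(self) -> float:
        return float(np.arctan(self.omega * self.R * self.C))

    def analytic(self, t):
        t = np.asarray(t, dtype=float)
        return self.analytic_amplitude * np.sin(self.omega * t - self.analytic_phase_lag)

    def simulate(self, dt: float, n_steps: int, p0: float = 0.0):
        from .simulate import _integrate

        sys_ = _ScalarSystem(-1.0 / (self.R * self.C),
                             forcing=lambda t: self.Q0 * np.sin(self.omega * t) / self.C)
        traj, _ = _integrate(sys_, np.array([[p0]]), dt, n_steps)
        time = np.arange(n_steps + 1) * dt
        return time, traj[0, :, 0]


def _sawtooth_waveforms(period: float = 0.5, dt: float = 0.001,
                        n_periods: int = 6) -> WaveformSet:
    n = int(round(n_periods * period / dt))
    time = np.arange(n + 1) * dt
    saw = np.mod(time, period) / period
    return WaveformSet(
        time=time,
        channels={"Q_aortic": saw.copy(), "P_aorta": 1.0 + saw.copy()},
        period=period,
    )


def make_fixture(kind: str, **kwargs):
    """Analytic oracle circuits/waveforms for validation.

    kinds: ``rc_discharge`` (RC decay, closed form e^(−t/RC)),
    ``windkessel2`` (sinusoidally driven 2-element Windkessel with analytic
    impedance), ``sawtooth`` (exactly periodic synthetic WaveformSet).
    """
    if kind == "rc_discharge":
        return RcDischargeFixture(**kwargs)
    if kind == "windkessel2":
        return Windkessel2Fixture(**kwargs)
    if kind == "sawtooth":
        return _sawtooth_waveforms(**kwargs)
    raise ValueError(f"unknown fixture kind: {kind!r}")


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


def waveform_to_csv(w: WaveformSet, path) -> None:
    """Waveforms in report units (mmHg / mL·s^-1 / mL), one row per step."""
    w.to_frame().to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def frame_to_csv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format=_CSV_FLOAT_FORMAT)


def write_manifest(path, *, command: str, config_path=None, settings=None,
                   seed=None, outputs=None) -> None:
    """Run manifest sufficient to re-run bit-compatibly on one platform."""
    from . import __version__

    manifest: dict = {"command": command, "package_version": __version__}
    if config_path is not None:
        data = Path(config_path).read_bytes()
        manifest["config"] = {
            "path": str(config_path),
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    if settings is not None:
        manifest["settings"] = {
            "dt": settings.dt, "n_steps": settings.n_steps,
            "convergence_threshold": settings.convergence_threshold,
            "n_report_cycles": settings.n_report_cycles,
        }
    if seed is not None:
        manifest["seed"] = int(seed)
    if outputs:
        manifest["outputs"] = [str(p) for p in outputs]
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote manifest %s", path)
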