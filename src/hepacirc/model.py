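"""Closed-loop lumped-parameter (0D) model of the human circulation with a
dual-inflow liver.

The circulation is represented as an electrical-analog network: pressure is
voltage, volumetric flow is current, and vessels are resistor/capacitor/
inductor elements.  The network is a single closed loop:

    LV --[aortic valve]--> systemic arterial junction, which feeds
        (i)   the hepatic-artery RCR      --> hepatic sinusoid
        (ii)  the digestive RCR --> portal vein --> hepatic sinusoid
        (iii) the other-organs RCR        --> central-venous junction
    sinusoid --R_hs--> parallel hepatic veins --> central-venous junction
        --> central-venous RCR --[tricuspid valve]--> RV
    RV --[pulmonary valve]--> lung RCR --> pulmonary-venous reservoir
        --[mitral valve]--> LV

Portal and hepatic-arterial blood converge at the sinusoidal node (the
liver's capillary bed); sinusoidal outflow drains through the sinusoidal
resistance and three parallel hepatic veins into the central venous system.
Both ventricles are time-varying elastance chambers (P = E(t)·(V − V0));
the four heart valves are smooth tanh "diodes" with a small inertance.

Internal units are SI-consistent {Pa, mm^3, s}; user-facing reports use
mmHg / mL / L·min^-1 (see the conversion constants below).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "PA_TO_MMHG",
    "ML_TO_MM3",
    "MM3_TO_ML",
    "MM3S_TO_LMIN",
    "LMIN_TO_MM3S",
    "STATE_LAYOUT",
    "ElastanceParams",
    "ValveParams",
    "RcrParams",
    "HepaticParams",
    "CirculationModel",
    "IntegrationError",
    "elastance_at",
    "chamber_pressure",
    "valve_openness",
    "assemble_rhs",
    "default_model",
    "default_initial_state",
]

# ---------------------------------------------------------------------------
# Unit conversions (internal units: Pa, mm^3, s)
# ---------------------------------------------------------------------------

MMHG_TO_PA = 133.322
PA_TO_MMHG = 1.0 / MMHG_TO_PA
ML_TO_MM3 = 1000.0
MM3_TO_ML = 1.0e-3
MM3S_TO_LMIN = 60.0 / 1.0e6  # mm^3/s -> L/min
LMIN_TO_MM3S = 1.0e6 / 60.0


class IntegrationError(RuntimeError):
    """Raised when the ODE state becomes non-finite or diverges."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElastanceParams:
    """Triphasic time-varying elastance of one ventricle.

    E(t) rises from E_min to E_max over [0, t_max] (contraction, raised
    cosine), falls back to E_min over (t_max, t_max + t_toRelax]
    (relaxation, raised cosine), and stays at E_min for the rest of the
    cardiac period T (diastasis).

    Units: elastances Pa·mm^-3, times s, V0 mm^3.
    """

    E_max: float
    E_min: float
    T: float
    t_max: float
    t_toRelax: float
    V0: float

    def __post_init__(self) -> None:
        if not (self.E_max > self.E_min > 0.0):
            raise ValueError(
                f"require E_max > E_min > 0, got E_max={self.E_max}, E_min={self.E_min}"
            )
        if not (0.0 < self.t_max and self.t_max + self.t_toRelax < self.T):
            raise ValueError(
                "require 0 < t_max and t_max + t_toRelax < T, got "
                f"t_max={self.t_max}, t_toRelax={self.t_toRelax}, T={self.T}"
            )
        if self.V0 < 0.0:
            raise ValueError(f"V0 must be >= 0, got {self.V0}")


@dataclass(frozen=True)
class ValveParams:
    """Heart-valve branch: open resistance, inertance, and the smooth-diode law.

    The valve is a nonlinear hyperbolic-tangent resistor: its effective
    resistance interpolates between R (fully open) and
    closed_resistance_factor·R (fully closed) as a function of the pressure
    difference across it, with `steepness` (Pa) setting the width of the
    open/close transition.
    """

    R: float
    L: float
    steepness: float = 0.1 * MMHG_TO_PA
    closed_resistance_factor: float = 1.0e6

    def __post_init__(self) -> None:
        if not (self.R > 0.0 and self.L > 0.0 and self.steepness > 0.0):
            raise ValueError("valve R, L, steepness must all be > 0")
        if self.closed_resistance_factor < 1.0e4:
            raise ValueError("closed_resistance_factor must be >= 1e4")


@dataclass(frozen=True)
class RcrParams:
    """Three-element Windkessel (proximal R, compliance C, distal R)."""

    R_p: float
    C: float
    R_d: float

    def __post_init__(self) -> None:
        if self.R_p < 0.0 or self.R_d < 0.0:
            raise ValueError("RCR resistances must be >= 0")
        if self.C <= 0.0:
            raise ValueError("RCR compliance must be > 0")


@dataclass(frozen=True)
class HepaticParams:
    """Hepatic subsystem: portal vein, hepatic artery, sinusoid, hepatic veins.

    The portal vein (R_pv_p, C_pv, R_pv_d) carries digestive-organ outflow
    to the sinusoid; the hepatic artery (R_ha_p, C_ha, R_ha_d) branches
    directly off the systemic arterial junction; both converge at the
    sinusoidal node (C_hs), which drains through R_hs and the three parallel
    hepatic veins (R_lhv, R_mhv, R_rhv).
    """

    R_pv_p: float
    R_pv_d: float
    C_pv: float
    R_ha_p: float
    R_ha_d: float
    C_ha: float
    R_hs: float
    C_hs: float
    R_lhv: float
    R_mhv: float
    R_rhv: float

    def __post_init__(self) -> None:
        for name in ("R_pv_p", "R_pv_d", "R_ha_p", "R_ha_d", "R_hs", "R_lhv", "R_mhv", "R_rhv"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"hepatic resistance {name} must be > 0")
        for name in ("C_pv", "C_ha", "C_hs"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"hepatic compliance {name} must be > 0")

    @property
    def R_hv_parallel(self) -> float:
        """Equivalent resistance of the three parallel hepatic veins."""
        return 1.0 / (1.0 / self.R_lhv + 1.0 / self.R_mhv + 1.0 / self.R_rhv)


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

# Chamber volumes (mm^3), inductor branch flows (mm^3/s), capacitor node
# pressures (Pa), in this fixed order.
STATE_LAYOUT = (
    "V_lv",       # left-ventricular volume
    "V_rv",       # right-ventricular volume
    "Q_mitral",   # mitral-valve branch flow (lung node -> LV)
    "Q_aortic",   # aortic-valve branch flow (LV -> arterial junction)
    "Q_tricuspid",  # tricuspid-valve branch flow (central-venous node -> RV)
    "Q_pulmonary",  # pulmonary-valve branch flow (RV -> lung node)
    "P_ha",       # hepatic-artery capacitor node
    "P_digestive",  # digestive-organs capacitor node
    "P_other",    # other-organs capacitor node
    "P_pv",       # portal-vein capacitor node
    "P_sinusoid",  # hepatic-sinusoid capacitor node
    "P_cv",       # central-venous capacitor node (right-atrial reservoir)
    "P_lung",     # lung capacitor node
    "P_la",       # pulmonary-venous / left-atrial reservoir node
)

NSTATE = len(STATE_LAYOUT)

# Index constants
IV_LV, IV_RV, IQ_MV, IQ_AV, IQ_TV, IQ_PV = 0, 1, 2, 3, 4, 5
IP_HA, IP_DIG, IP_OTH, IP_PV, IP_HS, IP_CV, IP_LUNG, IP_LA = 6, 7, 8, 9, 10, 11, 12, 13


@dataclass(frozen=True)
class CirculationModel:
    """The full closed-loop network (heart + valves + RCR beds + liver)."""

    left_ventricle: ElastanceParams
    right_ventricle: ElastanceParams
    mitral: ValveParams
    aortic: ValveParams
    tricuspid: ValveParams
    pulmonary: ValveParams
    lung: RcrParams
    digestive: RcrParams
    other_organs: RcrParams
    central_venous: RcrParams
    hepatic: HepaticParams
    # Pulmonary-venous / left-atrial reservoir compliance (mm^3/Pa).  The
    # left heart needs a compliant filling reservoir downstream of the lung
    # bed to buffer the right-ventricular stroke while the mitral valve is
    # closed; this mirrors the role the central-venous compliance plays for
    # the right heart.  See docs/methods.md for the reconstruction argument.
    pulmonary_venous_compliance: float = 12.0

    def __post_init__(self) -> None:
        if self.pulmonary_venous_compliance <= 0.0:
            raise ValueError("pulmonary_venous_compliance must be > 0")
        lv, rv = self.left_ventricle, self.right_ventricle
        for a, b, name in ((lv.T, rv.T, "T"), (lv.t_max, rv.t_max, "t_max"),
                           (lv.t_toRelax, rv.t_toRelax, "t_toRelax")):
            if abs(a - b) > 1e-12:
                raise ValueError(f"timing parameter {name} must match between ventricles")

    @property
    def state_layout(self) -> tuple[str, ...]:
        return STATE_LAYOUT

    @property
    def period(self) -> float:
        """Cardiac period T (s), shared by both ventricles."""
        return self.left_ventricle.T

    def replace(self, **kwargs) -> "CirculationModel":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _elastance_raw(t, E_max, E_min, t_max, t_toRelax):
    """Triphasic elastance for t already reduced to [0, T). Vectorized."""
    t = np.asarray(t, dtype=float)
    dE = E_max - E_min
    rise = E_min + 0.5 * dE * (1.0 - np.cos(np.pi * t / t_max))
    fall = E_min + 0.5 * dE * (1.0 + np.cos(np.pi * (t - t_max) / t_toRelax))
    out = np.where(
        t <= t_max, rise, np.where(t <= t_max + t_toRelax, fall, E_min)
    )
    return out


def elastance_at(t, p: ElastanceParams):
    """Triphasic elastance E(t) (Pa·mm^-3) at time-in-cycle ``t``.

    ``t`` must lie in [0, T); reduce modulo T first for absolute times.
    Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr >= p.T):
        raise ValueError(f"t must satisfy 0 <= t < T={p.T}; reduce modulo T first")
    out = _elastance_raw(t_arr, p.E_max, p.E_min, p.t_max, p.t_toRelax)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def chamber_pressure(V, E, V0):
    """Ventricular pressure P = E·(V − V0).

    May be negative when V < V0 (the linear elastance law is used as-is;
    there is no unstressed-volume floor).
    """
    return E * (np.asarray(V, dtype=float) - V0)


def valve_openness(dP, v: ValveParams):
    """Smooth open-fraction of a valve as a function of forward pressure drop.

    0.5·(1 + tanh(dP / steepness)): 0.5 at dP = 0, -> 1 for strongly
    forward-biased, -> 0 for strongly reverse-biased valves.
    """
    return 0.5 * (1.0 + np.tanh(np.asarray(dP, dtype=float) / v.steepness))


# ---------------------------------------------------------------------------
# Vectorized network assembly
#
# Given the smooth-diode law, the ODE system is linear in the state once the
# four valve resistances (functions of state via tanh) and the elastances
# (functions of time) are fixed:  x' = A(t, x) x + c(t, x).  Only the four
# valve-flow rows of A and c depend on (t, x); everything else is constant.
# The _Network class precomputes the constant part and supports a batch
# dimension B so that many parameterizations integrate simultaneously.
# ---------------------------------------------------------------------------


class _Network:
    """Batched matrix form of the circuit equations.

    All element parameters are stored as shape-(B,) arrays; the constant
    rows of the system matrix are prebuilt.  ``B = 1`` for a single model.
    """

    _SCALAR_FIELDS = (
        "R_mv", "L_mv", "steep_mv", "cf_mv",
        "R_av", "L_av", "steep_av", "cf_av",
        "R_tv", "L_tv", "steep_tv", "cf_tv",
        "R_pvalve", "L_pvalve", "steep_pvalve", "cf_pvalve",
        "EmaxL", "EminL", "EmaxR", "EminR", "T", "t_max", "t_toRelax",
        "V0L", "V0R",
        "R_lung_p", "C_lung", "R_lung_d",
        "R_dig_p", "C_dig", "R_dig_d",
        "R_oth_p", "C_oth", "R_oth_d",
        "R_cv_p", "C_cv", "R_cv_d",
        "R_pv_p", "R_pv_d", "C_pv",
        "R_ha_p", "R_ha_d", "C_ha",
        "R_hs", "C_hs", "R_lhv", "R_mhv", "R_rhv",
        "C_la",
    )

    def __init__(self, params: dict[str, np.ndarray]):
        self.B = len(next(iter(params.values())))
        for name in self._SCALAR_FIELDS:
            setattr(self, name, np.asarray(params[name], dtype=float))
        self._derive()
        self._build_constant()

    # -- construction -------------------------------------------------

    @classmethod
    def from_models(cls, models: list[CirculationModel]) -> "_Network":
        cols: dict[str, list[float]] = {k: [] for k in cls._SCALAR_FIELDS}
        for m in models:
            lv, rv, h = m.left_ventricle, m.right_ventricle, m.hepatic
            vals = {
                "R_mv": m.mitral.R, "L_mv": m.mitral.L,
                "steep_mv": m.mitral.steepness, "cf_mv": m.mitral.closed_resistance_factor,
                "R_av": m.aortic.R, "L_av": m.aortic.L,
                "steep_av": m.aortic.steepness, "cf_av": m.aortic.closed_resistance_factor,
                "R_tv": m.tricuspid.R, "L_tv": m.tricuspid.L,
                "steep_tv": m.tricuspid.steepness, "cf_tv": m.tricuspid.closed_resistance_factor,
                "R_pvalve": m.pulmonary.R, "L_pvalve": m.pulmonary.L,
                "steep_pvalve": m.pulmonary.steepness,
                "cf_pvalve": m.pulmonary.closed_resistance_factor,
                "EmaxL": lv.E_max, "EminL": lv.E_min, "EmaxR": rv.E_max, "EminR": rv.E_min,
                "T": lv.T, "t_max": lv.t_max, "t_toRelax": lv.t_toRelax,
                "V0L": lv.V0, "V0R": rv.V0,
                "R_lung_p": m.lung.R_p, "C_lung": m.lung.C, "R_lung_d": m.lung.R_d,
                "R_dig_p": m.digestive.R_p, "C_dig": m.digestive.C, "R_dig_d": m.digestive.R_d,
                "R_oth_p": m.other_organs.R_p, "C_oth": m.other_organs.C,
                "R_oth_d": m.other_organs.R_d,
                "R_cv_p": m.central_venous.R_p, "C_cv": m.central_venous.C,
                "R_cv_d": m.central_venous.R_d,
                "R_pv_p": h.R_pv_p, "R_pv_d": h.R_pv_d, "C_pv": h.C_pv,
                "R_ha_p": h.R_ha_p, "R_ha_d": h.R_ha_d, "C_ha": h.C_ha,
                "R_hs": h.R_hs, "C_hs": h.C_hs,
                "R_lhv": h.R_lhv, "R_mhv": h.R_mhv, "R_rhv": h.R_rhv,
                "C_la": m.pulmonary_venous_compliance,
            }
            for k, v in vals.items():
                cols[k].append(v)
        return cls({k: np.array(v, dtype=float) for k, v in cols.items()})

    @classmethod
    def from_scaled(cls, base: CirculationModel, scales: dict[str, np.ndarray]) -> "_Network":
        """Batch of models that differ from ``base`` only by hepatic scale
        factors.  Recognized keys: R_pv_d, R_ha_d, R_hs, R_hv (joint scale
        of the three hepatic veins)."""
        allowed = {"R_pv_d", "R_ha_d", "R_hs", "R_hv"}
        unknown = set(scales) - allowed
        if unknown:
            raise ValueError(f"unknown hepatic scale keys: {sorted(unknown)}")
        B = len(next(iter(scales.values())))
        net = cls.from_models([base])
        params = {k: np.repeat(getattr(net, k), B) for k in cls._SCALAR_FIELDS}
        for key, fac in scales.items():
            fac = np.asarray(fac, dtype=float)
            if fac.shape != (B,):
                raise ValueError("all scale arrays must share one length")
            if key == "R_hv":
                for r in ("R_lhv", "R_mhv", "R_rhv"):
                    params[r] = params[r] * fac
            else:
                params[key] = params[key] * fac
        return cls(params)

    # -- derived quantities -------------------------------------------

    def _derive(self) -> None:
        # arterial junction: parallel conductances of the three branches
        self.G_ha = 1.0 / self.R_ha_p
        self.G_dig = 1.0 / self.R_dig_p
        self.G_oth = 1.0 / self.R_oth_p
        self.Rsa = 1.0 / (self.G_ha + self.G_dig + self.G_oth)
        # digestive outflow is in series with the proximal portal resistance
        self.R_dp = self.R_dig_d + self.R_pv_p
        # liver outflow path: sinusoidal resistance + parallel hepatic veins
        self.R_hv_par = 1.0 / (1.0 / self.R_lhv + 1.0 / self.R_mhv + 1.0 / self.R_rhv)
        self.R_lo = self.R_hs + self.R_hv_par
        # central-venous junction: other-organs outflow, liver outflow, CV inflow
        self.G_od = 1.0 / self.R_oth_d
        self.G_lo = 1.0 / self.R_lo
        self.G_cp = 1.0 / self.R_cv_p
        self.Rcj = 1.0 / (self.G_od + self.G_lo + self.G_cp)

    # -- algebraic junction pressures ---------------------------------

    def p_arterial(self, x: np.ndarray) -> np.ndarray:
        """Systemic arterial junction pressure (aortic root), shape (B,)."""
        return self.Rsa * (
            x[:, IQ_AV]
            + self.G_ha * x[:, IP_HA]
            + self.G_dig * x[:, IP_DIG]
            + self.G_oth * x[:, IP_OTH]
        )

    def p_cv_junction(self, x: np.ndarray) -> np.ndarray:
        """Central-venous junction pressure (hepatic veins + other organs)."""
        return self.Rcj * (
            self.G_od * x[:, IP_OTH]
            + self.G_lo * x[:, IP_HS]
            + self.G_cp * x[:, IP_CV]
        )

    def elastances(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        tc = np.mod(t, self.T)
        eL = _elastance_raw(tc, self.EmaxL, self.EminL, self.t_max, self.t_toRelax)
        eR = _elastance_raw(tc, self.EmaxR, self.EminR, self.t_max, self.t_toRelax)
        return eL, eR

    # -- system matrices ----------------------------------------------

    def _build_constant(self) -> None:
        """Constant rows of A: chamber volumes and all capacitor nodes."""
        B = self.B
        A = np.zeros((B, NSTATE, NSTATE))

        # chamber volume balances
        A[:, IV_LV, IQ_MV] = 1.0
        A[:, IV_LV, IQ_AV] = -1.0
        A[:, IV_RV, IQ_TV] = 1.0
        A[:, IV_RV, IQ_PV] = -1.0

        Rsa, Rcj = self.Rsa, self.Rcj
        G_ha, G_dig, G_oth = self.G_ha, self.G_dig, self.G_oth
        G_od, G_lo, G_cp = self.G_od, self.G_lo, self.G_cp

        # hepatic-artery node: C_ha dP = (P_sa - P_ha)G_ha - (P_ha - P_hs)/R_ha_d
        C = self.C_ha
        A[:, IP_HA, IQ_AV] = G_ha * Rsa / C
        A[:, IP_HA, IP_HA] = (G_ha * (Rsa * G_ha - 1.0) - 1.0 / self.R_ha_d) / C
        A[:, IP_HA, IP_DIG] = G_ha * Rsa * G_dig / C
        A[:, IP_HA, IP_OTH] = G_ha * Rsa * G_oth / C
        A[:, IP_HA, IP_HS] = 1.0 / (self.R_ha_d * C)

        # digestive node: outflow through R_dig_d + R_pv_p to the portal node
        C = self.C_dig
        A[:, IP_DIG, IQ_AV] = G_dig * Rsa / C
        A[:, IP_DIG, IP_DIG] = (G_dig * (Rsa * G_dig - 1.0) - 1.0 / self.R_dp) / C
        A[:, IP_DIG, IP_HA] = G_dig * Rsa * G_ha / C
        A[:, IP_DIG, IP_OTH] = G_dig * Rsa * G_oth / C
        A[:, IP_DIG, IP_PV] = 1.0 / (self.R_dp * C)

        # other-organs node: outflow through R_oth_d to the CV junction
        C = self.C_oth
        A[:, IP_OTH, IQ_AV] = G_oth * Rsa / C
        A[:, IP_OTH, IP_HA] = G_oth * Rsa * G_ha / C
        A[:, IP_OTH, IP_DIG] = G_oth * Rsa * G_dig / C
        A[:, IP_OTH, IP_OTH] = (G_oth * (Rsa * G_oth - 1.0) - G_od * (1.0 - Rcj * G_od)) / C
        A[:, IP_OTH, IP_HS] = G_od * Rcj * G_lo / C
        A[:, IP_OTH, IP_CV] = G_od * Rcj * G_cp / C

        # portal-vein node
        C = self.C_pv
        A[:, IP_PV, IP_DIG] = 1.0 / (self.R_dp * C)
        A[:, IP_PV, IP_PV] = -(1.0 / self.R_dp + 1.0 / self.R_pv_d) / C
        A[:, IP_PV, IP_HS] = 1.0 / (self.R_pv_d * C)

        # sinusoidal node: portal + arterial inflow, outflow to CV junction
        C = self.C_hs
        A[:, IP_HS, IP_HA] = 1.0 / (self.R_ha_d * C)
        A[:, IP_HS, IP_PV] = 1.0 / (self.R_pv_d * C)
        A[:, IP_HS, IP_OTH] = G_lo * Rcj * G_od / C
        A[:, IP_HS, IP_CV] = G_lo * Rcj * G_cp / C
        A[:, IP_HS, IP_HS] = -(
            1.0 / self.R_ha_d + 1.0 / self.R_pv_d + G_lo * (1.0 - Rcj * G_lo)
        ) / C

        # central-venous node: inflow from junction, outflow = tricuspid branch
        C = self.C_cv
        A[:, IP_CV, IP_OTH] = G_cp * Rcj * G_od / C
        A[:, IP_CV, IP_HS] = G_cp * Rcj * G_lo / C
        A[:, IP_CV, IP_CV] = G_cp * (Rcj * G_cp - 1.0) / C
        A[:, IP_CV, IQ_TV] = -1.0 / C

        # lung node: pulmonary-valve inflow, outflow through R_lung_d to the
        # pulmonary-venous reservoir
        C = self.C_lung
        A[:, IP_LUNG, IQ_PV] = 1.0 / C
        A[:, IP_LUNG, IP_LUNG] = -1.0 / (self.R_lung_d * C)
        A[:, IP_LUNG, IP_LA] = 1.0 / (self.R_lung_d * C)

        # pulmonary-venous / left-atrial reservoir: mitral outflow
        C = self.C_la
        A[:, IP_LA, IP_LUNG] = 1.0 / (self.R_lung_d * C)
        A[:, IP_LA, IP_LA] = -1.0 / (self.R_lung_d * C)
        A[:, IP_LA, IQ_MV] = -1.0 / C

        self._A0 = A
        self._valve_rows = (IQ_MV, IQ_AV, IQ_TV, IQ_PV)

    @staticmethod
    def _r_eff(dP, R, steep, cf):
        openness = 0.5 * (1.0 + np.tanh(dP / steep))
        return R / np.maximum(openness, 1.0 / cf)

    def system(self, t: float, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full (A, c) at time t, with valve resistances evaluated at x.

        x has shape (B, NSTATE); returns A (B, NSTATE, NSTATE), c (B, NSTATE).
        """
        A = self._A0.copy()
        c = np.zeros((self.B, NSTATE))

        eL, eR = self.elastances(t)
        p_lv = eL * (x[:, IV_LV] - self.V0L)
        p_rv = eR * (x[:, IV_RV] - self.V0R)
        p_sa = self.p_arterial(x)

        r_mv = self._r_eff(x[:, IP_LA] - p_lv, self.R_mv, self.steep_mv, self.cf_mv)
        r_av = self._r_eff(p_lv - p_sa, self.R_av, self.steep_av, self.cf_av)
        r_tv = self._r_eff(x[:, IP_CV] - p_rv, self.R_tv, self.steep_tv, self.cf_tv)
        r_pv = self._r_eff(p_rv - x[:, IP_LUNG], self.R_pvalve, self.steep_pvalve,
                           self.cf_pvalve)

        # mitral: L dQ/dt = P_la - P_lv - r_mv Q
        L = self.L_mv
        A[:, IQ_MV, IP_LA] = 1.0 / L
        A[:, IQ_MV, IV_LV] = -eL / L
        A[:, IQ_MV, IQ_MV] = -r_mv / L
        c[:, IQ_MV] = eL * self.V0L / L

        # aortic: L dQ/dt = P_lv - P_sa(x) - r_av Q
        L = self.L_av
        A[:, IQ_AV, IV_LV] = eL / L
        A[:, IQ_AV, IQ_AV] = -(self.Rsa + r_av) / L
        A[:, IQ_AV, IP_HA] = -self.Rsa * self.G_ha / L
        A[:, IQ_AV, IP_DIG] = -self.Rsa * self.G_dig / L
        A[:, IQ_AV, IP_OTH] = -self.Rsa * self.G_oth / L
        c[:, IQ_AV] = -eL * self.V0L / L

        # tricuspid: L dQ/dt = P_cv - P_rv - (R_cv_d + r_tv) Q
        L = self.L_tv
        A[:, IQ_TV, IP_CV] = 1.0 / L
        A[:, IQ_TV, IV_RV] = -eR / L
        A[:, IQ_TV, IQ_TV] = -(self.R_cv_d + r_tv) / L
        c[:, IQ_TV] = eR * self.V0R / L

        # pulmonary: L dQ/dt = P_rv - P_lung - (r_pv + R_lung_p) Q
        L = self.L_pvalve
        A[:, IQ_PV, IV_RV] = eR / L
        A[:, IQ_PV, IP_LUNG] = -1.0 / L
        A[:, IQ_PV, IQ_PV] = -(r_pv + self.R_lung_p) / L
        c[:, IQ_PV] = -eR * self.V0R / L

        return A, c

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        A, c = self.system(t, x)
        return (A @ x[..., None])[..., 0] + c

    def volume_weights(self) -> np.ndarray:
        """Weights w such that w · dx/dt is the total stressed-volume rate
        (zero for the closed loop): 1 for chamber volumes, C for capacitor
        nodes, 0 for inductor flows."""
        w = np.zeros((self.B, NSTATE))
        w[:, IV_LV] = 1.0
        w[:, IV_RV] = 1.0
        w[:, IP_HA] = self.C_ha
        w[:, IP_DIG] = self.C_dig
        w[:, IP_OTH] = self.C_oth
        w[:, IP_PV] = self.C_pv
        w[:, IP_HS] = self.C_hs
        w[:, IP_CV] = self.C_cv
        w[:, IP_LUNG] = self.C_lung
        w[:, IP_LA] = self.C_la
        return w


def assemble_rhs(t: float, state: np.ndarray, m: CirculationModel) -> np.ndarray:
    """Right-hand side dx/dt of the coupled circuit ODEs at time ``t``.

    ``state`` follows :data:`STATE_LAYOUT`.  Kirchhoff balance laws: chamber
    volumes integrate net valve flow, capacitor nodes integrate net branch
    flow divided by C, inductor branches integrate the net pressure drop
    divided by L.  The weighted sum of all volume-rate terms is zero (the
    closed loop conserves blood volume).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (NSTATE,):
        raise ValueError(f"state must have shape ({NSTATE},) matching state_layout")
    if not np.all(np.isfinite(state)):
        raise IntegrationError("non-finite value in state vector")
    net = _Network.from_models([m])
    return net.rhs(float(t), state[None, :])[0]


# ---------------------------------------------------------------------------
# Shipped baseline parameterization (healthy adult, calibrated)
# ---------------------------------------------------------------------------


def default_model() -> CirculationModel:
    """The calibrated healthy-baseline model (scenario M1).

    Valve and elastance parameters and all RCR/hepatic element values are
    the shipped defaults (identical to ``data/default_model.yaml``); units
    are Pa·s·mm^-3 (R), Pa·s^2·mm^-3 (L), mm^3·Pa^-1 (C), Pa·mm^-3 (E),
    s (times), mm^3 (V0).
    """
    lv = ElastanceParams(E_max=0.394, E_min=9e-5, T=0.684, t_max=0.377,
                         t_toRelax=0.104, V0=10_000.0)
    rv = ElastanceParams(E_max=0.152, E_min=9e-5, T=0.684, t_max=0.377,
                         t_toRelax=0.104, V0=10_000.0)
    return CirculationModel(
        left_ventricle=lv,
        right_ventricle=rv,
        mitral=ValveParams(R=3.9e-4, L=1e-5),
        aortic=ValveParams(R=1e-5, L=1e-5),
        tricuspid=ValveParams(R=1e-5, L=1e-5),
        pulmonary=ValveParams(R=1e-5, L=1e-5),
        lung=RcrParams(R_p=0.00027, C=1.000, R_d=0.00265),
        digestive=RcrParams(R_p=0.05607, C=0.630, R_d=0.58110),
        other_organs=RcrParams(R_p=0.01869, C=6.302, R_d=0.19370),
        central_venous=RcrParams(R_p=0.00014, C=12.000, R_d=0.00142),
        hepatic=HepaticParams(
            R_pv_p=0.00318, R_pv_d=0.03184, C_pv=1.200,
            R_ha_p=0.17755, R_ha_d=1.84015, C_ha=0.630,
            R_hs=0.00884, C_hs=1.000,
            R_lhv=1e-5, R_mhv=1e-5, R_rhv=1e-5,
        ),
    )


def default_initial_state(
    m: CirculationModel,
    node_pressure_mmhg: float = 10.0,
    ventricle_volume_ml: float = 120.0,
) -> np.ndarray:
    """Default initial state: uniform node pressures, equal ventricular
    volumes, zero valve flows.

    Note that the closed loop conserves total stressed volume, so these
    initial values fix the operating blood volume of every subsequent steady
    cycle; the defaults are part of the model specification, not a
    convenience (see docs/methods.md).
    """
    x0 = np.zeros(NSTATE)
    x0[IV_LV] = x0[IV_RV] = ventricle_volume_ml * ML_TO_MM3
    for idx in (IP_HA, IP_DIG, IP_OTH, IP_PV, IP_HS, IP_CV, IP_LUNG, IP_LA):
        x0[idx] = node_pressure_mmhg * MMHG_TO_PA
    return x0


def total_stressed_volume(m: CirculationModel, state: np.ndarray) -> float:
    """Total stressed blood volume (mm^3): chamber volumes + sum of C·P."""
    net = _Network.from_models([m])
    w = net.volume_weights()[0]
    return float(w @ np.asarray(state, dtype=float))
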