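"""Calibration of the closed-loop model to normative aortic targets.

The free parameters are the seven cardiac elastance-function values
(E_maxL, E_minL, E_maxR, E_minR, T, t_max, t_toRelax) and three peripheral
scaling coefficients: A1 (all distal resistances), A2 (all proximal
resistances), A3 (all vascular compliances).  Valve parameters are held
fixed.  The loss is the sum of absolute relative deviations of four aortic
quantities from their healthy targets:

    L = |Q̄/5 − 1| + |P_max/120 − 1| + |P_min/80 − 1| + |Q_max/30 − 1|

(targets: mean aortic flow 5 L/min, systolic 120 mmHg, diastolic 80 mmHg,
peak aortic flow 30 L/min).  Minimization is multi-start Nelder–Mead
(scipy.optimize.minimize) with a soft out-of-bounds barrier; afterwards the
distal hepatic-artery : portal resistance ratio is tuned by bisection so
the portal vein carries ~75% of hepatic inflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .metrics import CycleMetrics, compute_cycle_metrics
from .model import CirculationModel, ElastanceParams, IntegrationError, RcrParams, default_initial_state
from .simulate import SimulationSettings, run_simulation

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "AorticTargets",
    "loss",
    "apply_scalings",
    "calibrate",
    "tune_portal_ratio",
]

logger = logging.getLogger("hepacirc")

_PENALTY = 1.0e6

# Parameter vector order used throughout this module
PARAM_NAMES = ("A1", "A2", "A3", "E_maxL", "E_minL", "E_maxR", "E_minR",
               "T", "t_max", "t_toRelax")

# Physiologically plausible search ranges per parameter
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "A1": (0.1, 10.0),
    "A2": (0.1, 10.0),
    "A3": (0.1, 10.0),
    "E_maxL": (1e-5, 1.0),
    "E_minL": (1e-5, 1.0),
    "E_maxR": (1e-5, 1.0),
    "E_minR": (1e-5, 1.0),
    "T": (0.5, 2.0),
    "t_max": (0.1, 0.5),
    "t_toRelax": (0.05, 0.2),
}


@dataclass(frozen=True)
class AorticTargets:
    """Normative aortic pressure-flow values for a healthy adult."""

    Q_mean: float = 5.0    # L/min
    Q_max: float = 30.0    # L/min
    P_min: float = 80.0    # mmHg
    P_max: float = 120.0   # mmHg

    def __post_init__(self) -> None:
        for name in ("Q_mean", "Q_max", "P_min", "P_max"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"target {name} must be > 0")


@dataclass(frozen=True)
class CalibrationSpec:
    """Multi-start Nelder–Mead settings and search ranges."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    targets: AorticTargets = field(default_factory=AorticTargets)
    max_evaluations: int = 300
    tolerance: float = 1e-4
    n_starts: int = 8
    seed: int = 0


@dataclass
class CalibrationResult:
    params: dict[str, float]
    loss: float
    metrics: CycleMetrics
    trace: np.ndarray                 # best-so-far loss after each evaluation
    n_evaluations: int
    converged: bool                   # at least one start met the tolerance
    near_bound: dict[str, bool]       # fitted parameter within 1% of a bound
    start_losses: list[float]


def loss(m: CycleMetrics, targets: AorticTargets | None = None) -> float:
    """Sum of the four absolute relative deviations from the aortic targets."""
    t = targets or AorticTargets()
    return (
        abs(m.CO - t.Q_mean) / t.Q_mean
        + abs(m.SBP - t.P_max) / t.P_max
        + abs(m.DBP - t.P_min) / t.P_min
        + abs(m.Q_aorta_max - t.Q_max) / t.Q_max
    )


def apply_scalings(base: CirculationModel, A1: float, A2: float, A3: float) -> CirculationModel:
    """Scale every peripheral distal resistance by A1, proximal resistance
    by A2, and vascular compliance by A3.  Valve and elastance parameters
    are untouched."""
    for name, val in (("A1", A1), ("A2", A2), ("A3", A3)):
        lo, hi = DEFAULT_BOUNDS[name]
        if not (lo <= val <= hi):
            raise ValueError(f"{name}={val} outside search range [{lo}, {hi}]")

    def rcr(p: RcrParams) -> RcrParams:
        return RcrParams(R_p=p.R_p * A2, C=p.C * A3, R_d=p.R_d * A1)

    h = base.hepatic
    hepatic = replace(
        h,
        R_pv_p=h.R_pv_p * A2, R_pv_d=h.R_pv_d * A1, C_pv=h.C_pv * A3,
        R_ha_p=h.R_ha_p * A2, R_ha_d=h.R_ha_d * A1, C_ha=h.C_ha * A3,
        R_hs=h.R_hs * A1, C_hs=h.C_hs * A3,
        R_lhv=h.R_lhv * A1, R_mhv=h.R_mhv * A1, R_rhv=h.R_rhv * A1,
    )
    return base.replace(
        lung=rcr(base.lung),
        digestive=rcr(base.digestive),
        other_organs=rcr(base.other_organs),
        central_venous=rcr(base.central_venous),
        hepatic=hepatic,
        pulmonary_venous_compliance=base.pulmonary_venous_compliance * A3,
    )


def _build_model(base: CirculationModel, theta: np.ndarray) -> CirculationModel:
    p = dict(zip(PARAM_NAMES, theta))
    m = apply_scalings(base, p["A1"], p["A2"], p["A3"])
    lv = ElastanceParams(E_max=p["E_maxL"], E_min=p["E_minL"], T=p["T"],
                         t_max=p["t_max"], t_toRelax=p["t_toRelax"],
                         V0=base.left_ventricle.V0)
    rv = ElastanceParams(E_max=p["E_maxR"], E_min=p["E_minR"], T=p["T"],
                         t_max=p["t_max"], t_toRelax=p["t_toRelax"],
                         V0=base.right_ventricle.V0)
    return m.replace(left_ventricle=lv, right_ventricle=rv)


def _out_of_bounds(theta: np.ndarray, bounds: dict) -> bool:
    for name, val in zip(PARAM_NAMES, theta):
        lo, hi = bounds[name]
        if not (lo <= val <= hi):
            return True
    p = dict(zip(PARAM_NAMES, theta))
    # elastance-function feasibility beyond the box bounds
    if p["t_max"] + p["t_toRelax"] >= p["T"]:
        return True
    if p["E_maxL"] <= p["E_minL"] or p["E_maxR"] <= p["E_minR"]:
        return True
    return False


def calibrate(
    spec: CalibrationSpec,
    base: CirculationModel,
    settings: SimulationSettings | None = None,
) -> CalibrationResult:
    """Multi-start Nelder–Mead fit of the ten calibration parameters.

    Each evaluation applies the scalings, simulates to periodic steady
    state, computes the aortic metrics, and scores the four-term loss;
    out-of-bounds proposals are penalized (soft barrier).  Returns the
    argmin across starts with a best-so-far loss trace and a report of
    fitted parameters sitting within 1% of a search bound.
    """
    settings = settings or SimulationSettings()
    rng = np.random.default_rng(spec.seed)
    bounds = spec.bounds

    trace: list[float] = []
    best = {"loss": np.inf}

    def objective(theta: np.ndarray) -> float:
        if _out_of_bounds(theta, bounds):
            val = _PENALTY
        else:
            try:
                model = _build_model(base, theta)
                w = run_simulation(model, settings)
                metrics = compute_cycle_metrics(w)
                val = loss(metrics, spec.targets)
                if val < best["loss"]:
                    best.update(loss=val, theta=np.array(theta), metrics=metrics)
            except (IntegrationError, ValueError):
                val = _PENALTY
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    def random_start() -> np.ndarray:
        for _ in range(1000):
            theta = np.array([rng.uniform(*bounds[n]) for n in PARAM_NAMES])
            # strictly inside the box, feasible timing/elastance ordering
            theta = np.clip(theta,
                            [bounds[n][0] * 1.001 for n in PARAM_NAMES],
                            [bounds[n][1] * 0.999 for n in PARAM_NAMES])
            if not _out_of_bounds(theta, bounds):
                return theta
        raise RuntimeError("could not draw a feasible start point")

    # first start: the shipped parameter set (identity scalings)
    lv = base.left_ventricle
    rv = base.right_ventricle
    starts = [np.array([1.0, 1.0, 1.0, lv.E_max, lv.E_min, rv.E_max, rv.E_min,
                        lv.T, lv.t_max, lv.t_toRelax])]
    starts += [random_start() for _ in range(spec.n_starts - 1)]

    start_losses: list[float] = []
    any_converged = False
    for i, x0 in enumerate(starts):
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxfev": spec.max_evaluations, "xatol": spec.tolerance,
                     "fatol": spec.tolerance, "adaptive": False},
        )
        start_losses.append(float(res.fun))
        any_converged |= bool(res.success)
        logger.info("calibration start %d/%d: loss %.4f (%s)",
                    i + 1, len(starts), res.fun, res.message)

    if not any_converged:
        logger.warning(
            "no start converged within %d evaluations; returning best-so-far",
            spec.max_evaluations,
        )
    if "theta" not in best:
        raise RuntimeError("every calibration evaluation failed")

    fitted = dict(zip(PARAM_NAMES, best["theta"]))
    # proximity measured relative to the bound value (the ranges span up to
    # five decades, so a linear-width criterion would flag any small value)
    near_bound = {}
    for name, val in fitted.items():
        lo, hi = bounds[name]
        near_bound[name] = bool(val <= lo * 1.01 or val >= hi * 0.99)

    return CalibrationResult(
        params=fitted,
        loss=float(best["loss"]),
        metrics=best["metrics"],
        trace=np.asarray(trace),
        n_evaluations=len(trace),
        converged=any_converged,
        near_bound=near_bound,
        start_losses=start_losses,
    )


def fitted_model(base: CirculationModel, params: dict[str, float]) -> CirculationModel:
    """Model built from a calibration parameter dictionary."""
    return _build_model(base, np.array([params[n] for n in PARAM_NAMES]))


def tune_portal_ratio(
    m: CirculationModel,
    target_portal_fraction: float = 0.75,
    tolerance: float = 0.01,
    settings: SimulationSettings | None = None,
    max_steps: int = 60,
) -> CirculationModel:
    """Adjust the distal hepatic-artery : portal resistance ratio so the
    portal vein carries ``target_portal_fraction`` of hepatic inflow.

    Scalar bisection on a multiplier of R_ha_d (raising arterial resistance
    monotonically raises the portal fraction), terminating when the
    cycle-mean portal fraction is within ``tolerance`` of the target.
    """
    if not (0.0 < target_portal_fraction < 1.0):
        raise ValueError("target_portal_fraction must be in (0, 1)")
    settings = settings or SimulationSettings()

    def fraction(factor: float) -> float:
        model = m.replace(hepatic=replace(m.hepatic, R_ha_d=m.hepatic.R_ha_d * factor))
        w = run_simulation(model, settings, init=default_initial_state(model))
        from .metrics import compute_hepatic_metrics

        hm = compute_hepatic_metrics(w)
        return 1.0 - hm.arterial_fraction / 100.0

    n_eval = 0
    f = 1.0
    frac = fraction(f)
    n_eval += 1
    if abs(frac - target_portal_fraction) <= tolerance:
        return m

    # bracket in log2-space; fraction is increasing in the multiplier
    lo, hi = -8.0, 8.0
    if frac < target_portal_fraction:
        lo = 0.0
    else:
        hi = 0.0
    while n_eval < max_steps:
        mid = 0.5 * (lo + hi)
        frac = fraction(2.0 ** mid)
        n_eval += 1
        if abs(frac - target_portal_fraction) <= tolerance:
            new = m.replace(hepatic=replace(
                m.hepatic, R_ha_d=m.hepatic.R_ha_d * 2.0 ** mid))
            logger.info("portal ratio tuned: R_ha_d x %.4f, portal fraction %.3f",
                        2.0 ** mid, frac)
            return new
        if frac < target_portal_fraction:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"portal fraction {frac:.3f} did not reach {target_portal_fraction} "
        f"± {tolerance} within {max_steps} evaluations"
    )
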