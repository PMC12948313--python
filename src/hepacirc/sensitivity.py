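"""Variance-based global sensitivity analysis of cardiac function with
respect to hepatic vascular resistances.

Four hepatic factors are perturbed multiplicatively around their baseline
values: distal portal resistance (R_pv_d), distal hepatic-artery resistance
(R_ha_d), sinusoidal resistance (R_hs), and the hepatic venous resistance
R_hv (one factor jointly scaling the three parallel hepatic veins).  Scale
factors are drawn on [0.5, 10] with Saltelli's quasi-random cross-sampling
scheme (a scrambled Sobol' low-discrepancy sequence of dimension 2K split
into base matrices A and B plus the K column-swapped matrices AB_j and
BA_j, N·(2K+2) model evaluations in total).

For output y, the first-order index S_j = V(E(y|x_j))/V(y) measures the
variance fraction explained by parameter j alone; the total-order index
ST_j = 1 − V(E(y|x_-j))/V(y) additionally counts all interactions
involving j.  Estimators: the symmetrized Saltelli 2010 estimator for S_j
and the Jansen estimator for ST_j, with bootstrap confidence half-widths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import (
    IP_DIG,
    IP_HA,
    IP_OTH,
    IQ_AV,
    IV_LV,
    MM3_TO_ML,
    MM3S_TO_LMIN,
    PA_TO_MMHG,
    CirculationModel,
    _Network,
    _elastance_raw,
    default_initial_state,
)
from .simulate import SimulationSettings, run_batch_final_cycle

__all__ = [
    "SensitivityDesign",
    "SobolResult",
    "saltelli_matrix",
    "sobol_indices",
    "run_sensitivity",
]

logger = logging.getLogger("hepacirc")

HEPATIC_PARAMETERS = ("R_pv_d", "R_ha_d", "R_hs", "R_hv")

_BATCH_CHUNK = 256
_BOOTSTRAP_REPS = 200
_MAX_FAILURE_FRACTION = 0.01


@dataclass(frozen=True)
class SensitivityDesign:
    """Saltelli design over multiplicative hepatic scale factors.

    ``scale_bounds`` may be one (lo, hi) pair shared by all parameters or a
    mapping parameter -> (lo, hi).  ``N`` is the base sample count; the
    total number of model evaluations is N·(2K+2).  Scales are sampled
    uniformly in linear space by default (``log_scale=True`` switches to
    log-uniform).
    """

    parameters: tuple[str, ...] = HEPATIC_PARAMETERS
    scale_bounds: object = (0.5, 10.0)
    N: int = 500
    seed: int = 0
    outputs: tuple[str, ...] = ("CO", "MAP", "SW")
    log_scale: bool = False

    @property
    def K(self) -> int:
        return len(self.parameters)

    @property
    def n_evaluations(self) -> int:
        return self.N * (2 * self.K + 2)

    def bounds_array(self) -> np.ndarray:
        if isinstance(self.scale_bounds, dict):
            missing = set(self.parameters) - set(self.scale_bounds)
            if missing:
                raise ValueError(f"scale_bounds missing parameters: {sorted(missing)}")
            arr = np.array([self.scale_bounds[p] for p in self.parameters], dtype=float)
        else:
            lo, hi = self.scale_bounds
            arr = np.tile([float(lo), float(hi)], (self.K, 1))
        if np.any(arr[:, 0] > arr[:, 1]) or np.any(arr[:, 0] <= 0.0):
            raise ValueError("scale bounds must satisfy 0 < lo <= hi")
        return arr


@dataclass
class SobolResult:
    """First-/total-order indices per output and parameter, with bootstrap
    95% confidence half-widths."""

    parameters: tuple[str, ...]
    outputs: tuple[str, ...]
    S: dict[str, np.ndarray]
    ST: dict[str, np.ndarray]
    S_ci: dict[str, np.ndarray]
    ST_ci: dict[str, np.ndarray]
    n_samples: int
    seed: int | None = None
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for out in self.outputs:
            for j, p in enumerate(self.parameters):
                rows.append({
                    "output": out, "parameter": p,
                    "S": self.S[out][j], "ST": self.ST[out][j],
                    "S_ci": self.S_ci[out][j], "ST_ci": self.ST_ci[out][j],
                })
        return pd.DataFrame(rows)


def saltelli_matrix(d: SensitivityDesign) -> np.ndarray:
    """The N·(2K+2) × K matrix of scale vectors in Saltelli block order
    [A; B; AB_1 .. AB_K; BA_1 .. BA_K].

    AB_j is the base matrix A with column j taken from B (and vice versa
    for BA_j); comparing outputs across these blocks isolates the variance
    contribution of parameter j.
    """
    K, N = d.K, d.N
    if N < 2:
        raise ValueError("N must be >= 2")
    if N & (N - 1) != 0:
        warnings.warn(
            f"N={N} is not a power of two; Sobol' sequence balance is degraded",
            UserWarning, stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # qmc.Sobol's own power-of-two warning
        sampler = qmc.Sobol(d=2 * K, scramble=True, seed=d.seed)
        U = sampler.random(N)
    A, B = U[:, :K], U[:, K:]

    blocks = [A, B]
    for j in range(K):
        AB = A.copy()
        AB[:, j] = B[:, j]
        blocks.append(AB)
    for j in range(K):
        BA = B.copy()
        BA[:, j] = A[:, j]
        blocks.append(BA)
    u = np.vstack(blocks)

    bounds = d.bounds_array()
    lo, hi = bounds[:, 0], bounds[:, 1]
    if d.log_scale:
        scales = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    else:
        scales = lo + u * (hi - lo)
    return scales


def _as_blocks(y: np.ndarray, K: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    nblk = 2 * K + 2
    if y.ndim == 1:
        if y.size % nblk:
            raise ValueError(f"output length {y.size} is not a multiple of 2K+2={nblk}")
        y = y.reshape(nblk, y.size // nblk)
    elif y.shape[0] != nblk:
        raise ValueError(f"expected {nblk} Saltelli blocks, got {y.shape[0]}")
    return y


def _estimate(yb: np.ndarray, K: int, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """S and ST from block matrix yb (2K+2, N) restricted to sample idx.

    Outputs are centered on the A/B mean first; the first-order estimator
    involves products of outputs, so a large uncentered mean would destroy
    its accuracy through cancellation.
    """
    yb = yb[:, idx]
    mu = np.mean(yb[:2])
    yb = yb - mu
    idx = np.arange(yb.shape[1])
    fA, fB = yb[0], yb[1]
    var = np.var(np.concatenate([fA, fB]))
    S = np.empty(K)
    ST = np.empty(K)
    for j in range(K):
        fAB = yb[2 + j, idx]
        fBA = yb[2 + K + j, idx]
        # symmetrized Saltelli (2010) first-order estimator
        S[j] = 0.5 * (np.mean(fB * (fAB - fA)) + np.mean(fA * (fBA - fB))) / var
        # symmetrized Jansen total-order estimator
        ST[j] = 0.25 * (np.mean((fA - fAB) ** 2) + np.mean((fB - fBA) ** 2)) / var
    return S, ST


def sobol_indices(
    sample_outputs: np.ndarray,
    K: int,
    rng: np.random.Generator | None = None,
    n_bootstrap: int = _BOOTSTRAP_REPS,
) -> dict[str, np.ndarray]:
    """First-/total-order Sobol indices from outputs in Saltelli block order.

    ``sample_outputs`` is either flat (length N·(2K+2), blocks contiguous)
    or a (2K+2, N) matrix.  Returns {"S", "ST", "S_ci", "ST_ci"} with one
    entry per parameter; the CI entries are bootstrap 95% half-widths over
    resampled Saltelli rows.
    """
    yb = _as_blocks(sample_outputs, K)
    if not np.all(np.isfinite(yb)):
        raise ValueError("sample outputs contain NaN/Inf")
    N = yb.shape[1]
    if np.var(yb[:2]) <= 0.0:
        raise ValueError("output variance is zero; Sobol indices are undefined")

    full = np.arange(N)
    S, ST = _estimate(yb, K, full)

    rng = rng or np.random.default_rng(0)
    bs_S = np.empty((n_bootstrap, K))
    bs_ST = np.empty((n_bootstrap, K))
    for b in range(n_bootstrap):
        idx = rng.integers(0, N, size=N)
        bs_S[b], bs_ST[b] = _estimate(yb, K, idx)
    S_ci = 0.5 * (np.quantile(bs_S, 0.975, axis=0) - np.quantile(bs_S, 0.025, axis=0))
    ST_ci = 0.5 * (np.quantile(bs_ST, 0.975, axis=0) - np.quantile(bs_ST, 0.025, axis=0))
    return {"S": S, "ST": ST, "S_ci": S_ci, "ST_ci": ST_ci}


# ---------------------------------------------------------------------------
# Model evaluation over the design
# ---------------------------------------------------------------------------


def _batch_outputs(net: _Network, time: np.ndarray, traj: np.ndarray) -> dict[str, np.ndarray]:
    """CO (L/min), MAP (mmHg) and SW (mmHg·mL) per batch element from one
    steady cycle (trapezoid-consistent cycle means over the closed window)."""
    q_av = traj[:, :, IQ_AV]
    co = np.mean(0.5 * (q_av[:, 1:] + q_av[:, :-1]), axis=1) * MM3S_TO_LMIN

    p_sa = net.Rsa[:, None] * (
        q_av
        + net.G_ha[:, None] * traj[:, :, IP_HA]
        + net.G_dig[:, None] * traj[:, :, IP_DIG]
        + net.G_oth[:, None] * traj[:, :, IP_OTH]
    )
    map_ = np.mean(0.5 * (p_sa[:, 1:] + p_sa[:, :-1]), axis=1) * PA_TO_MMHG

    tc = np.mod(time[None, :], net.T[:, None])
    eL = _elastance_raw(tc, net.EmaxL[:, None], net.EminL[:, None],
                        net.t_max[:, None], net.t_toRelax[:, None])
    v = traj[:, :, IV_LV]
    p_lv = eL * (v - net.V0L[:, None])
    # shoelace over the closed PV loop (first == last point of the cycle)
    v_, p_ = v[:, :-1], p_lv[:, :-1]
    sw = 0.5 * np.sum(
        v_ * np.roll(p_, -1, axis=1) - np.roll(v_, -1, axis=1) * p_, axis=1
    ) * MM3_TO_ML * PA_TO_MMHG
    return {"CO": co, "MAP": map_, "SW": sw}


def run_sensitivity(
    base: CirculationModel,
    d: SensitivityDesign | None = None,
    settings: SimulationSettings | None = None,
) -> tuple[SobolResult, pd.DataFrame]:
    """Evaluate the closed-loop model over the Saltelli design and estimate
    Sobol indices of CO, MAP and SW for the four hepatic resistances.

    One steady-state simulation per design row (batched internally).
    Rows that fail to integrate are excluded together with their Saltelli
    siblings; more than 1% failures aborts.
    Returns (SobolResult, raw evaluation table).
    """
    d = d or SensitivityDesign()
    unknown = set(d.parameters) - set(HEPATIC_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown hepatic parameters: {sorted(unknown)}")
    settings = settings or SimulationSettings()
    scales = saltelli_matrix(d)
    n_rows = scales.shape[0]
    x0 = default_initial_state(base)

    outputs = {name: np.empty(n_rows) for name in ("CO", "MAP", "SW")}
    ok = np.ones(n_rows, dtype=bool)
    for start in range(0, n_rows, _BATCH_CHUNK):
        sl = slice(start, min(start + _BATCH_CHUNK, n_rows))
        chunk = scales[sl]
        net = _Network.from_scaled(
            base, {p: chunk[:, j] for j, p in enumerate(d.parameters)}
        )
        init = np.tile(x0, (chunk.shape[0], 1))
        time, traj, chunk_ok = run_batch_final_cycle(net, settings, init)
        vals = _batch_outputs(net, time, traj)
        for name in outputs:
            outputs[name][sl] = vals[name]
            chunk_ok &= np.isfinite(vals[name])
        ok[sl] = chunk_ok
        logger.info("sensitivity: %d/%d evaluations done", sl.stop, n_rows)

    n_failed = int(np.sum(~ok))
    if n_failed > _MAX_FAILURE_FRACTION * n_rows:
        raise RuntimeError(
            f"{n_failed}/{n_rows} model evaluations failed (> "
            f"{_MAX_FAILURE_FRACTION:.0%}); aborting sensitivity analysis"
        )
    if n_failed:
        logger.warning("%d/%d evaluations failed; excluding their Saltelli rows",
                       n_failed, n_rows)

    # a failed row invalidates its whole cross-sample (same base index in
    # every block)
    K, N = d.K, d.N
    ok_rows = ok.reshape(2 * K + 2, N).all(axis=0)

    raw = pd.DataFrame(scales, columns=[f"scale_{p}" for p in d.parameters])
    for name, arr in outputs.items():
        raw[name] = arr
    raw["ok"] = ok

    rng = np.random.default_rng(d.seed + 1)
    res = SobolResult(
        parameters=d.parameters,
        outputs=tuple(d.outputs),
        S={}, ST={}, S_ci={}, ST_ci={},
        n_samples=int(np.sum(ok_rows)),
        seed=d.seed,
        n_failed=n_failed,
    )
    for name in d.outputs:
        yb = outputs[name].reshape(2 * K + 2, N)[:, ok_rows]
        est = sobol_indices(yb, K, rng=rng)
        res.S[name] = est["S"]
        res.ST[name] = est["ST"]
        res.S_ci[name] = est["S_ci"]
        res.ST_ci[name] = est["ST_ci"]
    return res, raw
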