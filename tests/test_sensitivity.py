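"""Saltelli design construction and Sobol-index estimation against
closed-form benchmarks."""

import numpy as np
import pytest
from scipy.stats import qmc

import hepacirc as hc
from hepacirc.sensitivity import (
    SensitivityDesign,
    saltelli_matrix,
    sobol_indices,
)


def _blocks_from_unit(A, B):
    K = A.shape[1]
    blocks = [A, B]
    for j in range(K):
        AB = A.copy()
        AB[:, j] = B[:, j]
        blocks.append(AB)
    for j in range(K):
        BA = B.copy()
        BA[:, j] = A[:, j]
        blocks.append(BA)
    return np.vstack(blocks)


def _unit_design(K, N, seed):
    U = qmc.Sobol(d=2 * K, scramble=True, seed=seed).random(N)
    return _blocks_from_unit(U[:, :K], U[:, K:])


class TestSaltelliMatrix:
    def test_row_count_is_n_times_2k_plus_2(self):
        d = SensitivityDesign(N=500)
        with pytest.warns(UserWarning):  # 500 is not a power of two
            s = saltelli_matrix(d)
        assert s.shape == (5000, 4)

    def test_generic_k_row_count(self):
        d = SensitivityDesign(parameters=("R_pv_d", "R_ha_d"), N=8)
        assert saltelli_matrix(d).shape == (48, 2)

    def test_degenerate_bounds_give_unit_scales(self):
        d = SensitivityDesign(N=8, scale_bounds=(1.0, 1.0))
        assert np.allclose(saltelli_matrix(d), 1.0)

    def test_scales_respect_bounds(self):
        d = SensitivityDesign(N=64, seed=3)
        s = saltelli_matrix(d)
        assert s.min() >= 0.5 and s.max() <= 10.0

    def test_log_scale_sampling_stays_in_bounds(self):
        d = SensitivityDesign(N=64, seed=3, log_scale=True)
        s = saltelli_matrix(d)
        assert s.min() >= 0.5 and s.max() <= 10.0

    def test_mismatched_bounds_rejected(self):
        d = SensitivityDesign(scale_bounds={"R_pv_d": (0.5, 10.0)}, N=8)
        with pytest.raises(ValueError):
            saltelli_matrix(d)

    def test_design_reproducible_for_fixed_seed(self):
        d = SensitivityDesign(N=16, seed=9)
        assert np.array_equal(saltelli_matrix(d), saltelli_matrix(d))


class TestSobolEstimators:
    def test_single_factor_function(self):
        """y = x1 with a dummy x2: S1 ≈ ST1 ≈ 1, S2 ≈ ST2 ≈ 0."""
        X = _unit_design(2, 512, seed=1)
        est = sobol_indices(X[:, 0], K=2)
        assert est["S"][0] == pytest.approx(1.0, abs=0.05)
        assert est["ST"][0] == pytest.approx(1.0, abs=0.05)
        assert est["S"][1] == pytest.approx(0.0, abs=0.05)
        assert est["ST"][1] == pytest.approx(0.0, abs=0.05)

    def test_additive_symmetric_function(self):
        """y = x1 + x2 with equal ranges: S1 ≈ S2 ≈ 0.5."""
        X = _unit_design(2, 512, seed=2)
        est = sobol_indices(X[:, 0] + X[:, 1], K=2)
        assert est["S"][0] == pytest.approx(0.5, abs=0.05)
        assert est["S"][1] == pytest.approx(0.5, abs=0.05)

    def test_ishigami_closed_form(self):
        """Ishigami (a=7, b=0.1) against its analytic Sobol indices.

        With V1 = (1 + b·pi^4/5)^2 / 2, V2 = a^2/8, V13 = 8 b^2 pi^8 / 225
        and V = V1 + V2 + V13:  S = (V1, V2, 0)/V and
        ST = (V1+V13, V2, V13)/V.
        """
        a, b, pi = 7.0, 0.1, np.pi
        V1 = 0.5 * (1 + b * pi ** 4 / 5) ** 2
        V2 = a ** 2 / 8
        V13 = 8 * b ** 2 * pi ** 8 / 225
        V = V1 + V2 + V13

        X = _unit_design(3, 1024, seed=3) * 2 * pi - pi
        y = np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2 + b * X[:, 2] ** 4 * np.sin(X[:, 0])
        est = sobol_indices(y, K=3)
        np.testing.assert_allclose(est["S"], [V1 / V, V2 / V, 0.0], atol=0.05)
        np.testing.assert_allclose(est["ST"], [(V1 + V13) / V, V2 / V, V13 / V],
                                   atol=0.05)

    def test_total_order_dominates_first_order(self):
        """ST_j >= S_j up to estimator noise for an interacting function."""
        X = _unit_design(3, 512, seed=4)
        y = X[:, 0] * X[:, 1] + X[:, 2]
        est = sobol_indices(y, K=3)
        assert np.all(est["ST"] >= est["S"] - 0.05)

    def test_estimates_stable_under_doubling_n(self):
        y1 = _unit_design(2, 256, seed=5)
        y2 = _unit_design(2, 512, seed=5)
        e1 = sobol_indices(y1[:, 0] + 0.5 * y1[:, 1], K=2)
        e2 = sobol_indices(y2[:, 0] + 0.5 * y2[:, 1], K=2)
        assert np.all(np.abs(e1["S"] - e2["S"]) < 0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sobol_indices(np.ones(48), K=2)

    def test_nonfinite_outputs_rejected(self):
        y = np.ones(48)
        y[3] = np.nan
        with pytest.raises(ValueError):
            sobol_indices(y, K=2)


@pytest.fixture(scope="module")
def small_run(model):
    """Small Saltelli experiment on the full model (N=64, 640 runs — the
    smallest base sample at which the estimator noise bands of the
    invariants hold)."""
    d = SensitivityDesign(N=64, seed=21)
    return hc.run_sensitivity(model, d)


class TestRunSensitivity:

    def test_indices_within_estimator_bands(self, small_run):
        res, raw = small_run
        assert res.n_failed == 0
        for out in res.outputs:
            assert np.all(res.S[out] >= -0.05)
            assert np.all(res.S[out] <= res.ST[out] + 0.05)
            assert np.all(res.ST[out] <= 1.1)
            assert np.sum(res.S[out]) <= 1.1

    def test_raw_table_covers_every_evaluation(self, small_run):
        res, raw = small_run
        assert len(raw) == 64 * 10
        assert raw["ok"].all()
        assert {"CO", "MAP", "SW"} <= set(raw.columns)

    def test_hepatic_venous_resistance_is_inert(self, small_run):
        """The printed hepatic-vein resistances are ~1e-5 Pa·s·mm^-3; even
        a tenfold scale perturbs nothing measurable."""
        res, _ = small_run
        j = res.parameters.index("R_hv")
        for out in res.outputs:
            assert abs(res.S[out][j]) < 0.02
            assert abs(res.ST[out][j]) < 0.02

    def test_unknown_parameter_rejected(self, model):
        with pytest.raises(ValueError):
            hc.run_sensitivity(model, SensitivityDesign(parameters=("bogus",), N=8))
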