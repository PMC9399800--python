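"""Estimation tests: objective arithmetic, fitting, uncertainty, regressions."""

import math

import numpy as np
import pytest

from sesakin import (
    ArrheniusParams,
    KineticParameters,
    ResidualMatrix,
    VantHoffParams,
    equilibrium_constant,
    fit,
    hpd_intervals,
    objective,
    objective_from_residuals,
    parameter_correlation,
    parity_r2,
    residuals,
    response_covariance,
    vant_hoff_fit,
)
from sesakin.synthetic_data import NoiseModel, default_design, generate_dataset


@pytest.fixture(scope="module")
def five_run_clean(ref_params):
    """Noise-free dataset over the five concentration/temperature runs."""
    return generate_dataset(ref_params, default_design()[:5])


class TestResiduals:
    def test_noise_free_self_consistency(self, ref_params, five_run_clean):
        res = residuals(five_run_clean, ref_params)
        assert res.m == 2
        assert res.n == 5 * 10
        assert np.max(np.abs(res.r)) < 1e-7   # integrator reproducibility

    def test_pooling_with_mismatched_time_grids(self, ref_params):
        from sesakin.simulator import KineticDataset
        rows = default_design()
        a = generate_dataset(ref_params, rows[:1],
                             times=(0.0, 5.0, 30.0, 240.0))
        b = generate_dataset(ref_params, rows[1:2],
                             times=(0.0, 10.0, 60.0, 120.0, 180.0))
        ds = KineticDataset(a.profiles + b.profiles)
        res = residuals(ds, ref_params)
        assert res.n == 4 + 5
        res_no0 = residuals(ds, ref_params, include_t0=False)
        assert res_no0.n == 3 + 4

    def test_empty_dataset_rejected(self, ref_params):
        from sesakin.simulator import KineticDataset
        with pytest.raises(ValueError, match="empty"):
            residuals(KineticDataset([]), ref_params)


class TestResponseCovariance:
    def test_two_response_hand_example(self):
        res = ResidualMatrix(r=np.array([[1.0, 2.0], [0.0, 1.0]]), n=2, m=2)
        v = response_covariance(res)
        assert np.allclose(v, [[5.0, 2.0], [2.0, 1.0]])
        assert np.linalg.det(v) == pytest.approx(1.0)

    def test_zero_residuals(self):
        res = ResidualMatrix(r=np.zeros((2, 4)), n=4, m=2)
        assert np.all(response_covariance(res) == 0.0)

    def test_single_response_is_ssr(self):
        res = ResidualMatrix(r=np.array([[1.0, 2.0]]), n=2, m=1)
        assert np.allclose(response_covariance(res), [[5.0]])


class TestObjective:
    def test_single_response_hand_value(self):
        # S = (n+m+1) ln SSR = 4 ln 5
        res = ResidualMatrix(r=np.array([[1.0, 2.0]]), n=2, m=1)
        assert objective_from_residuals(res) == pytest.approx(4 * math.log(5),
                                                              rel=1e-9)
        assert objective_from_residuals(res) == pytest.approx(6.4378, abs=1e-4)

    def test_unit_determinant_hand_value(self):
        res = ResidualMatrix(r=np.array([[1.0, 2.0], [0.0, 1.0]]), n=2, m=2)
        assert objective_from_residuals(res) == pytest.approx(0.0, abs=1e-9)

    def test_minimum_at_generating_parameters(self, ref_params,
                                              five_run_clean):
        s_truth = objective(five_run_clean, ref_params)
        for scale in (0.98, 1.02):
            other = KineticParameters(
                arrhenius=ArrheniusParams(9.74 * scale, 21.4),
                vant_hoff=ref_params.vant_hoff, K1=ref_params.K1)
            assert objective(five_run_clean, other) > s_truth

    def test_response_rescaling_shifts_by_constant(self):
        """Scaling one response by c adds (n+m+1)*2*ln c, argmin unchanged."""
        rng = np.random.default_rng(4)
        c = 7.3
        shifts = []
        for _ in range(5):
            r = rng.normal(size=(2, 10))
            res = ResidualMatrix(r=r, n=10, m=2)
            scaled = ResidualMatrix(r=np.diag([1.0, c]) @ r, n=10, m=2)
            shifts.append(objective_from_residuals(scaled)
                          - objective_from_residuals(res))
        expected = (10 + 2 + 1) * 2 * math.log(c)
        assert np.allclose(shifts, expected, rtol=1e-9)
        # constant shift => the ranking (hence argmin) over any grid is stable
        base = [objective_from_residuals(ResidualMatrix(
            r=rng.normal(size=(2, 10)) * s, n=10, m=2)) for s in (1, 2, 3)]
        assert np.argmin(base) == 0


class TestFit:
    def test_zero_iteration_from_truth(self, ref_params, five_run_clean):
        """Starting at the generating values, the fit stays there."""
        result = fit(five_run_clean, ref_params, fixed=("K1",),
                     compute_uncertainty=False)
        assert result.estimates["ln_k_ref"] == pytest.approx(9.74, rel=1e-6)
        assert result.estimates["dH_r"] == pytest.approx(34578.0, rel=1e-6)
        # the perfect-fit objective floor is resolved only to ~1e-5 (1-ulp
        # parameter round-trips move the ridge-regularized log-det slightly)
        assert result.objective <= objective(five_run_clean, ref_params) + 1e-3

    def test_single_temperature_flags_activation_energy(self, ref_params,
                                                        perturbed_init):
        iso_rows = [r for r in default_design() if r.T_C == 80.0]
        ds = generate_dataset(ref_params, iso_rows,
                              noise=NoiseModel("multiplicative-gaussian",
                                               0.02, 5))
        result = fit(ds, perturbed_init, fixed=("K1",))
        assert result.indeterminate["ea_over_RTref"]
        assert math.isnan(result.hpd["ea_over_RTref"])

    def test_unknown_fixed_parameter_rejected(self, ref_params,
                                              five_run_clean):
        with pytest.raises(ValueError, match="unknown parameter"):
            fit(five_run_clean, ref_params, fixed=("not_a_param",))

    def test_hpd_percent_is_ratio_of_halfwidth_to_estimate(self, ref_params,
                                                           perturbed_init):
        ds = generate_dataset(ref_params, default_design()[:5],
                              noise=NoiseModel("multiplicative-gaussian",
                                               0.02, 7))
        result = fit(ds, perturbed_init, fixed=("K1",))
        for name in result.free:
            if result.indeterminate[name]:
                continue
            assert result.hpd_percent[name] == pytest.approx(
                100.0 * result.hpd[name] / abs(result.estimates[name]))


class TestUncertainty:
    def test_free_adsorption_constant_is_indeterminate(self, ref_params,
                                                       perturbed_init):
        """K1 trades off against ln_k almost exactly: flagged, zeroed row."""
        ds = generate_dataset(ref_params, default_design()[:5],
                              noise=NoiseModel("multiplicative-gaussian",
                                               0.02, 3))
        result = fit(ds, perturbed_init)   # all five parameters free
        assert result.indeterminate["K1"]
        assert math.isnan(result.hpd["K1"])
        k = result.correlation_names.index("K1")
        off_diag = np.delete(result.correlation[k], k)
        assert np.all(off_diag == 0.0)
        assert result.correlation[k, k] == 1.0

    def test_arrhenius_reparameterization_decorrelates(self, ref_params,
                                                       perturbed_init):
        """|corr(ln_k_ref, Ea/(R*T_ref))| < 0.5 on the default design."""
        ds = generate_dataset(ref_params, default_design()[:5],
                              noise=NoiseModel("multiplicative-gaussian",
                                               0.02, 9))
        result = fit(ds, perturbed_init, fixed=("K1",))
        i = result.correlation_names.index("ln_k_ref")
        j = result.correlation_names.index("ea_over_RTref")
        assert abs(result.correlation[i, j]) < 0.5

    def test_single_free_parameter_trivial_correlation(self, ref_params,
                                                       five_run_clean):
        corr, names = parameter_correlation(
            five_run_clean, ref_params,
            fixed=("ea_over_RTref", "K_ref", "dH_r", "K1"))
        assert names == ("ln_k_ref",)
        assert np.array_equal(corr, [[1.0]])

    def test_hpd_wrapper_matches_fit(self, ref_params, perturbed_init):
        ds = generate_dataset(ref_params, default_design()[:5],
                              noise=NoiseModel("multiplicative-gaussian",
                                               0.02, 7))
        result = fit(ds, perturbed_init, fixed=("K1",))
        hpd, flags = hpd_intervals(ds, result.parameters(), fixed=("K1",))
        for name in result.free:
            if not flags[name]:
                assert hpd[name] == pytest.approx(result.hpd[name], rel=1e-6)


class TestVantHoff:
    def test_recovers_generating_enthalpy(self):
        vh = VantHoffParams(0.536, 34578.0)
        pairs = [(T, equilibrium_constant(T, vh))
                 for T in (343.15, 353.15, 363.15)]
        vf = vant_hoff_fit(pairs, T_ref=353.15)
        assert vf.dH_r == pytest.approx(34578.0, rel=1e-3)
        assert vf.K_ref == pytest.approx(0.536, rel=1e-6)

    def test_flat_equilibrium_means_zero_enthalpy(self):
        vf = vant_hoff_fit([(343.15, 0.7), (363.15, 0.7)], T_ref=353.15)
        assert vf.dH_r == pytest.approx(0.0, abs=1e-9)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError, match="distinct temperatures"):
            vant_hoff_fit([(353.15, 0.5), (353.15, 0.6)], T_ref=353.15)

    def test_endothermic_sign_convention(self):
        """K increasing with T must map to a positive recovered enthalpy."""
        vh = VantHoffParams(1.0, 20000.0)
        pairs = [(T, equilibrium_constant(T, vh)) for T in (340.0, 370.0)]
        assert vant_hoff_fit(pairs, T_ref=353.15).dH_r > 0


class TestParityR2:
    def test_perfect_prediction(self):
        assert parity_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = [1.0, 2.0, 3.0]
        assert parity_r2(obs, [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert parity_r2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == \
            pytest.approx(0.5)

    def test_constant_observations_undefined(self):
        assert math.isnan(parity_r2([2.0, 2.0], [1.0, 3.0]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            parity_r2([1.0, 2.0], [1.0])
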