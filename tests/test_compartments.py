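"""Compartment signal models: closed forms, limits, and representations."""

import numpy as np
import pytest

from mcdmri import compartments as cm
from mcdmri.acquisition import build_scheme_from_bvalues, \
    build_scheme_from_gradients
from mcdmri.shm import real_sh_basis, sh_fit
from mcdmri.sphere import angles_to_unit_vector, golden_spiral_directions, \
    icosphere

ALL_MODELS = ["G1", "G2", "G3", "C1", "C2", "C3", "C4",
              "S1", "S2", "S3", "S4"]

VALID_PARAMS = {
    "G1": dict(lambda_iso=2e-9),
    "G2": dict(mu=[0.5, 0.3], lambda_par=1.7e-9, lambda_perp=0.5e-9),
    "G3": dict(mu=[0.5, 0.3], lambda_par=1.7e-9, lambda_inf=0.5e-9, A=1e-12),
    "C1": dict(mu=[0.5, 0.3], lambda_par=1.7e-9),
    "C2": dict(mu=[0.5, 0.3], lambda_par=1.7e-9, diameter=4e-6),
    "C3": dict(mu=[0.5, 0.3], lambda_par=1.7e-9, lambda_intra=1.7e-9,
               diameter=4e-6),
    "C4": dict(mu=[0.5, 0.3], lambda_par=1.7e-9, lambda_intra=1.7e-9,
               diameter=4e-6),
    "S1": dict(),
    "S2": dict(diameter=8e-6),
    "S3": dict(lambda_intra=1.7e-9, diameter=8e-6),
    "S4": dict(lambda_intra=1.7e-9, diameter=8e-6),
}


@pytest.mark.parametrize("model_id", ALL_MODELS)
class TestCommonContract:
    def test_unit_attenuation_at_b0_and_range(self, model_id,
                                              multi_shell_scheme):
        model = cm.model_from_id(model_id)
        e = model.attenuation(multi_shell_scheme, **VALID_PARAMS[model_id])
        np.testing.assert_allclose(e[multi_shell_scheme.b0_mask], 1.0,
                                   atol=1e-9)
        assert np.all(e >= -1e-12) and np.all(e <= 1 + 1e-9)

    def test_spherical_mean_orientation_free(self, model_id,
                                             multi_shell_scheme):
        model = cm.model_from_id(model_id)
        params = {k: v for k, v in VALID_PARAMS[model_id].items()
                  if k != "mu"}
        sm = model.spherical_mean(multi_shell_scheme, **params)
        assert sm.shape == (multi_shell_scheme.n_shells,)
        assert np.all(sm >= 0) and np.all(sm <= 1 + 1e-9)


class TestGaussianModels:
    def test_gaussian_attenuation_monotone_in_b(self,
                                                single_direction_scheme):
        for model_id in ("G1", "G2", "G3"):
            model = cm.model_from_id(model_id)
            e = model.attenuation(single_direction_scheme,
                                  **VALID_PARAMS[model_id])
            assert np.all(np.diff(e) <= 1e-12)

    def test_zeppelin_with_equal_eigenvalues_is_ball(self,
                                                     multi_shell_scheme):
        e_zep = cm.G2Zeppelin().attenuation(
            multi_shell_scheme, mu=[1.0, -0.4], lambda_par=1.7e-9,
            lambda_perp=1.7e-9)
        e_ball = cm.G1Ball().attenuation(multi_shell_scheme, lambda_iso=1.7e-9)
        np.testing.assert_allclose(e_zep, e_ball, atol=1e-12)

    def test_zeppelin_rejects_prolate_violation(self, multi_shell_scheme):
        with pytest.raises(ValueError, match="lambda_perp"):
            cm.G2Zeppelin().attenuation(
                multi_shell_scheme, mu=[0, 0], lambda_par=1e-9,
                lambda_perp=2e-9)

    def test_temporal_zeppelin_with_zero_packing_is_zeppelin(
            self, multi_shell_scheme):
        e_g3 = cm.G3TemporalZeppelin().attenuation(
            multi_shell_scheme, mu=[0.5, 0.3], lambda_par=1.7e-9,
            lambda_inf=0.5e-9, A=0.0)
        e_g2 = cm.G2Zeppelin().attenuation(
            multi_shell_scheme, mu=[0.5, 0.3], lambda_par=1.7e-9,
            lambda_perp=0.5e-9)
        np.testing.assert_allclose(e_g3, e_g2, atol=1e-15)

    def test_temporal_zeppelin_requires_delta_gap(self):
        s = build_scheme_from_bvalues([1e9], [[0, 0, 1.0]], 20e-3, 15e-3)
        with pytest.raises(ValueError, match="Delta > delta"):
            cm.G3TemporalZeppelin().attenuation(
                s, mu=[0, 0], lambda_par=1.7e-9, lambda_inf=0.5e-9, A=1e-12)


class TestSticksAndDots:
    def test_stick_parallel_closed_form(self):
        s = build_scheme_from_bvalues([1e9], [[0, 0, 1.0]], 10e-3, 40e-3)
        e = cm.C1Stick().attenuation(s, mu=[0, 0], lambda_par=1.7e-9)
        assert e[0] == pytest.approx(np.exp(-1.7), rel=1e-12)

    def test_stick_perpendicular_no_attenuation(self):
        s = build_scheme_from_bvalues([3e9], [[1, 0, 0.0]], 10e-3, 40e-3)
        e = cm.C1Stick().attenuation(s, mu=[0, 0], lambda_par=1.7e-9)
        assert e[0] == pytest.approx(1.0, abs=1e-12)

    def test_dot_is_unit_everywhere(self, multi_shell_scheme):
        e = cm.S1Dot().attenuation(multi_shell_scheme)
        np.testing.assert_array_equal(e, 1.0)


class TestRestrictedLimits:
    def test_gaussian_phase_cylinder_converges_to_stick(self,
                                                        multi_shell_scheme):
        e4 = cm.C4CylinderGaussianPhase().attenuation(
            multi_shell_scheme, mu=[0.3, 0.4], lambda_par=1.7e-9,
            lambda_intra=1.7e-9, diameter=1e-8)
        e1 = cm.C1Stick().attenuation(
            multi_shell_scheme, mu=[0.3, 0.4], lambda_par=1.7e-9)
        assert np.abs(e4 - e1).max() < 1e-6

    def _sgp_long_time_scheme(self):
        # delta << Delta and Delta >> d^2 / lambda_intra (d = 10 um)
        G = np.linspace(0.01, 0.6, 15)
        return build_scheme_from_gradients(
            G, np.tile([[1, 0, 0.0]], (15, 1)), 0.5e-3, 0.5)

    def test_cylinder_approximations_agree_in_sgp_long_time_regime(self):
        s = self._sgp_long_time_scheme()
        kw = dict(mu=[0, 0], lambda_par=1.7e-9, diameter=10e-6)
        e2 = cm.C2CylinderStejskalTanner().attenuation(s, **kw)
        e3 = cm.C3CylinderCallaghan().attenuation(s, lambda_intra=1.7e-9,
                                                  **kw)
        e4 = cm.C4CylinderGaussianPhase().attenuation(s, lambda_intra=1.7e-9,
                                                      **kw)
        assert e2.min() < 0.97  # regime has measurable attenuation
        assert np.abs(e2 - e3).max() < 0.01
        assert np.abs(e2 - e4).max() < 0.01

    def test_cylinder_approximations_diverge_outside_regime(self):
        # long pulses comparable to Delta violate the SGP assumption
        G = np.linspace(0.01, 0.3, 10)
        s = build_scheme_from_gradients(
            G, np.tile([[1, 0, 0.0]], (10, 1)), 15e-3, 20e-3)
        kw = dict(mu=[0, 0], lambda_par=1.7e-9, diameter=10e-6)
        e2 = cm.C2CylinderStejskalTanner().attenuation(s, **kw)
        e4 = cm.C4CylinderGaussianPhase().attenuation(s, lambda_intra=1.7e-9,
                                                      **kw)
        assert np.abs(e2 - e4).max() > 0.01

    def test_sphere_approximations_agree_in_sgp_long_time_regime(self):
        G = np.linspace(0.01, 0.6, 15)
        s = build_scheme_from_gradients(
            G, np.tile([[1, 0, 0.0]], (15, 1)), 0.5e-3, 0.5)
        e2 = cm.S2SphereStejskalTanner().attenuation(s, diameter=10e-6)
        e3 = cm.S3SphereCallaghan().attenuation(
            s, lambda_intra=1.7e-9, diameter=10e-6)
        e4 = cm.S4SphereGaussianPhase().attenuation(
            s, lambda_intra=1.7e-9, diameter=10e-6)
        assert np.abs(e2 - e3).max() < 0.01
        assert np.abs(e2 - e4).max() < 0.01

    def test_callaghan_series_short_time_limit(self):
        # at vanishing diffusion time no signal is lost
        qt = np.linspace(0.05, 2.5, 8)
        e = cm._callaghan_cylinder_perp(qt, np.array(1e-4))
        assert np.all(e > 0.985)

    def test_callaghan_series_converged(self, monkeypatch):
        qt = np.linspace(0.05, 2.5, 12)
        t = np.array(0.3)
        e_ref = cm._callaghan_cylinder_perp(qt, t)
        monkeypatch.setattr(cm, "CALLAGHAN_N_ORDERS", 18)
        monkeypatch.setattr(cm, "CALLAGHAN_N_ROOTS", 18)
        e_more = cm._callaghan_cylinder_perp(qt, t)
        assert np.abs(e_ref - e_more).max() < 1e-4

    def test_diameter_must_be_positive(self, multi_shell_scheme):
        with pytest.raises(ValueError, match="diameter"):
            cm.C2CylinderStejskalTanner().attenuation(
                multi_shell_scheme, mu=[0, 0], lambda_par=1.7e-9,
                diameter=-1e-6)


class TestSphericalMeans:
    @pytest.mark.parametrize("model_id", ["C1", "G2", "G1"])
    def test_analytic_mean_matches_dense_quadrature(self, model_id,
                                                    multi_shell_scheme):
        model = cm.model_from_id(model_id)
        params = {k: v for k, v in VALID_PARAMS[model_id].items()
                  if k != "mu"}
        analytic = model.spherical_mean(multi_shell_scheme, **params)
        # oracle: weighted product-Gauss quadrature over the sphere
        from mcdmri.shm import gauss_legendre_sphere

        grid, w = gauss_legendre_sphere(48, 96)
        numeric = []
        for shell in multi_shell_scheme.shells:
            from mcdmri.acquisition import shell_probe
            p = dict(params)
            if model.is_anisotropic:
                p["mu"] = np.array([0.0, 0.0])
            numeric.append(float(w @ model.attenuation(
                shell_probe(shell, grid), **p)) / (4 * np.pi))
        np.testing.assert_allclose(analytic, numeric, atol=1e-5)

    def test_mean_invariant_to_orientation(self, multi_shell_scheme, rng):
        from mcdmri.shm import gauss_legendre_sphere

        grid, w = gauss_legendre_sphere(48, 96)
        model = cm.G2Zeppelin()
        ref = model.spherical_mean(multi_shell_scheme, lambda_par=1.7e-9,
                                   lambda_perp=0.4e-9)
        from mcdmri.acquisition import shell_probe
        for _ in range(3):
            mu = [rng.uniform(0, np.pi), rng.uniform(-np.pi, np.pi)]
            means = [float(w @ model.attenuation(
                shell_probe(shell, grid), mu=mu, lambda_par=1.7e-9,
                lambda_perp=0.4e-9)) / (4 * np.pi)
                for shell in multi_shell_scheme.shells]
            np.testing.assert_allclose(ref, means, atol=1e-6)


class TestConvolutionKernelMatrix:
    def test_isotropic_kernel_uses_only_l0_columns(self, multi_shell_scheme):
        m = cm.G1Ball().convolution_kernel_matrix(
            multi_shell_scheme, 6, lambda_iso=2e-9)
        assert np.abs(m[:, 1:]).max() < 1e-12
        assert np.abs(m[:, 0]).min() > 0

    def test_kernel_times_peaked_fod_approximates_rotated_kernel(
            self, multi_shell_scheme):
        # forward-simulation oracle: convolving with a near-delta FOD at mu
        # reproduces the kernel attenuation oriented along mu
        from mcdmri.distributions import watson_density

        mu = np.array([1.1, 0.4])
        grid = icosphere(4)
        errs = []
        for order in (6, 12):
            fod = sh_fit(watson_density(grid, mu, 0.12), grid, order)
            m = cm.C1Stick().convolution_kernel_matrix(
                multi_shell_scheme, order, lambda_par=1.7e-9)
            predicted = m @ fod
            # oracle: dispersing the Stick by the same Watson directly
            from mcdmri.distributed import SphericalDistributedModel

            sd = SphericalDistributedModel([cm.C1Stick()], "watson",
                                           sh_order=order)
            direct = sd.attenuation(
                multi_shell_scheme, C1Stick_1_lambda_par=1.7e-9,
                SD1Watson_1_mu=mu, SD1Watson_1_odi=0.12)
            errs.append(np.abs(predicted - direct).max())
        assert errs[1] < 1e-3          # agreement at matched order
        assert errs[1] <= errs[0]      # truncation error shrinks with order

    def test_funk_hecke_l0_consistency(self, multi_shell_scheme):
        # uniform FOD (1/4pi) convolved with any kernel gives its mean
        order = 6
        ncoef = (order + 1) * (order + 2) // 2
        fod = np.zeros(ncoef)
        fod[0] = 1.0 / np.sqrt(4 * np.pi)  # integrates to 1
        m = cm.G2Zeppelin().convolution_kernel_matrix(
            multi_shell_scheme, order, lambda_par=1.7e-9, lambda_perp=0.4e-9)
        predicted = m @ fod
        sm = cm.G2Zeppelin().spherical_mean(
            multi_shell_scheme, lambda_par=1.7e-9, lambda_perp=0.4e-9)
        np.testing.assert_allclose(
            predicted, sm[multi_shell_scheme.shell_indices], atol=1e-10)

    def test_odd_order_rejected(self, multi_shell_scheme):
        with pytest.raises(ValueError, match="even"):
            cm.G1Ball().convolution_kernel_matrix(
                multi_shell_scheme, 5, lambda_iso=2e-9)


class TestParameterSpecs:
    def test_registry_matches_field_conventions(self):
        specs = {
            "G1": {"lambda_iso": 1},
            "G2": {"mu": 2, "lambda_par": 1, "lambda_perp": 1},
            "G3": {"mu": 2, "lambda_par": 1, "lambda_inf": 1, "A": 1},
            "C1": {"mu": 2, "lambda_par": 1},
            "C2": {"mu": 2, "lambda_par": 1, "diameter": 1},
            "C3": {"mu": 2, "lambda_par": 1, "lambda_intra": 1,
                   "diameter": 1},
            "C4": {"mu": 2, "lambda_par": 1, "lambda_intra": 1,
                   "diameter": 1},
            "S1": {},
            "S2": {"diameter": 1},
            "S3": {"lambda_intra": 1, "diameter": 1},
            "S4": {"lambda_intra": 1, "diameter": 1},
        }
        for model_id, expected in specs.items():
            model = cm.model_from_id(model_id)
            assert model.parameter_cardinality == expected

    def test_default_bounds_physical(self):
        for model_id in ALL_MODELS:
            model = cm.model_from_id(model_id)
            for name, bounds in model.parameter_bounds.items():
                if name == "mu":
                    continue
                lo, hi = bounds
                if model.parameter_units[name] == "m^2/s":
                    assert 0.1e-10 <= lo and hi <= 1000e-10
                if name == "diameter":
                    assert 1e-7 <= lo and hi <= 2e-5
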