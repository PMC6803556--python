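"""Composite distributed models: Gamma-integrated scalars and
Watson/Bingham orientation dispersion, with intra-model links."""

import numpy as np
import pytest

from mcdmri.compartments import (
    C1Stick,
    C4CylinderGaussianPhase,
    G1Ball,
    G2Zeppelin,
)
from mcdmri.distributed import (
    ParameterDistributedModel,
    SphericalDistributedModel,
    distribute_orientation,
    distribute_parameter,
)


@pytest.fixture(scope="module")
def watson_stick_zeppelin():
    return SphericalDistributedModel([C1Stick(), G2Zeppelin()], "watson")


WSZ_PARAMS = {
    "C1Stick_1_lambda_par": 1.7e-9,
    "G2Zeppelin_1_lambda_par": 1.7e-9,
    "G2Zeppelin_1_lambda_perp": 0.5e-9,
    "SD1Watson_1_mu": np.array([0.8, 0.5]),
    "SD1Watson_1_odi": 0.3,
    "partial_volume_0": 0.6,
}


class TestParameterDistributed:
    def _gamma_cylinder(self):
        return ParameterDistributedModel(
            [C4CylinderGaussianPhase()],
            "C4CylinderGaussianPhase_1_diameter", volume_norm="cylinder")

    def _axcal_scheme(self):
        from mcdmri.phantoms import cat_axcaliber_scheme

        return cat_axcaliber_scheme(n_gradients=20)

    def test_effective_parameters_swap_xi_for_gamma(self):
        pd = self._gamma_cylinder()
        names = set(pd._parameters)
        assert "PD1Gamma_1_alpha" in names and "PD1Gamma_1_beta" in names
        assert "C4CylinderGaussianPhase_1_diameter" not in names

    def test_degenerate_gamma_equals_single_cylinder(self):
        scheme = self._axcal_scheme()
        pd = self._gamma_cylinder()
        mean_d = 3e-6
        alpha = 3000.0
        e_pd = pd.attenuation(
            scheme, C4CylinderGaussianPhase_1_mu=np.zeros(2),
            C4CylinderGaussianPhase_1_lambda_par=1.7e-9,
            C4CylinderGaussianPhase_1_lambda_intra=1.7e-9,
            PD1Gamma_1_alpha=alpha, PD1Gamma_1_beta=mean_d / alpha)
        e_single = C4CylinderGaussianPhase().attenuation(
            scheme, mu=np.zeros(2), lambda_par=1.7e-9, lambda_intra=1.7e-9,
            diameter=mean_d)
        assert np.abs(e_pd - e_single).max() < 1e-3

    def test_cylinder_volume_weights_scale_as_diameter_squared(self):
        # two equal-probability diameters d and 2d weigh 1:4 under pi xi^2
        d = 1e-6
        xi = np.array([d, 2 * d])
        norm = np.pi * xi ** 2
        w = norm / norm.sum()
        assert w[1] / w[0] == pytest.approx(4.0, rel=1e-12)

    def test_quadrature_weights_sum_to_one(self):
        pd = self._gamma_cylinder()
        for alpha, beta in [(2.0, 1e-6), (6.0, 4e-7), (15.0, 2e-7)]:
            _, w = pd._quadrature(alpha, beta)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_density_converged(self, monkeypatch):
        from mcdmri import distributed as dd

        scheme = self._axcal_scheme()
        pd = self._gamma_cylinder()
        kw = dict(C4CylinderGaussianPhase_1_mu=np.zeros(2),
                  C4CylinderGaussianPhase_1_lambda_par=1.7e-9,
                  C4CylinderGaussianPhase_1_lambda_intra=1.7e-9,
                  PD1Gamma_1_alpha=3.0, PD1Gamma_1_beta=1e-6)
        e_ref = pd.attenuation(scheme, **kw)
        monkeypatch.setattr(dd, "GAMMA_QUAD_POINTS", 105)
        e_dense = pd.attenuation(scheme, **kw)
        assert np.abs(e_ref - e_dense).max() < 2e-3

    def test_mean_reporting_conventions(self):
        pd = self._gamma_cylinder()
        assert pd.mean_distributed_value(3.0, 1e-6) == pytest.approx(3e-6)
        pd2 = ParameterDistributedModel(
            [C4CylinderGaussianPhase()],
            "C4CylinderGaussianPhase_1_diameter",
            diameter_mean_convention="2*alpha*beta")
        assert pd2.mean_distributed_value(3.0, 1e-6) == pytest.approx(6e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            distribute_parameter([C4CylinderGaussianPhase()], "nope")
        with pytest.raises(ValueError, match="cardinality-1"):
            distribute_parameter([C4CylinderGaussianPhase()],
                                 "C4CylinderGaussianPhase_1_mu")


class TestSphericalDistributed:
    def test_registry_replaces_kernel_orientations(self,
                                                   watson_stick_zeppelin):
        names = set(watson_stick_zeppelin._parameters)
        assert "SD1Watson_1_mu" in names and "SD1Watson_1_odi" in names
        assert "C1Stick_1_mu" not in names and "G2Zeppelin_1_mu" not in names
        assert "partial_volume_0" in names

    def test_low_dispersion_approaches_undispersed_kernels(
            self, watson_stick_zeppelin, multi_shell_scheme):
        p = dict(WSZ_PARAMS, SD1Watson_1_odi=0.03)
        dispersed = watson_stick_zeppelin.attenuation(multi_shell_scheme, **p)
        mu = p["SD1Watson_1_mu"]
        direct = 0.6 * C1Stick().attenuation(
            multi_shell_scheme, mu=mu, lambda_par=1.7e-9) + \
            0.4 * G2Zeppelin().attenuation(
                multi_shell_scheme, mu=mu, lambda_par=1.7e-9,
                lambda_perp=0.5e-9)
        # truncation-limited agreement that improves with the SH order
        err14 = np.abs(dispersed - direct).max()
        sd20 = SphericalDistributedModel([C1Stick(), G2Zeppelin()], "watson",
                                         sh_order=20)
        err20 = np.abs(sd20.attenuation(multi_shell_scheme, **p)
                       - direct).max()
        assert err14 < 0.08
        assert err20 < err14

    def test_full_dispersion_is_direction_independent(
            self, watson_stick_zeppelin, multi_shell_scheme):
        p = dict(WSZ_PARAMS, SD1Watson_1_odi=0.999)
        e = watson_stick_zeppelin.attenuation(multi_shell_scheme, **p)
        sm = watson_stick_zeppelin.spherical_mean(multi_shell_scheme, **p)
        np.testing.assert_allclose(
            e, sm[multi_shell_scheme.shell_indices], atol=2e-3)

    def test_spherical_mean_is_kernel_mixture_mean(
            self, watson_stick_zeppelin, multi_shell_scheme):
        sm = watson_stick_zeppelin.spherical_mean(multi_shell_scheme,
                                                  **WSZ_PARAMS)
        sm_stick = C1Stick().spherical_mean(multi_shell_scheme,
                                            lambda_par=1.7e-9)
        sm_zep = G2Zeppelin().spherical_mean(
            multi_shell_scheme, lambda_par=1.7e-9, lambda_perp=0.5e-9)
        np.testing.assert_allclose(sm, 0.6 * sm_stick + 0.4 * sm_zep,
                                   rtol=1e-10)

    def test_numeric_mean_confirms_dispersion_invariance(
            self, watson_stick_zeppelin, multi_shell_scheme):
        sm = watson_stick_zeppelin.spherical_mean(multi_shell_scheme,
                                                  **WSZ_PARAMS)
        numeric = watson_stick_zeppelin._spherical_mean_numeric(
            multi_shell_scheme.shells, **WSZ_PARAMS)
        np.testing.assert_allclose(sm, numeric, atol=1e-6)

    def test_bingham_beta_zero_equals_watson(self, watson_stick_zeppelin,
                                             multi_shell_scheme):
        sdb = SphericalDistributedModel([C1Stick(), G2Zeppelin()], "bingham")
        pb = {
            "C1Stick_1_lambda_par": 1.7e-9,
            "G2Zeppelin_1_lambda_par": 1.7e-9,
            "G2Zeppelin_1_lambda_perp": 0.5e-9,
            "SD2Bingham_1_mu": np.array([0.8, 0.5]),
            "SD2Bingham_1_psi": 0.7, "SD2Bingham_1_odi": 0.3,
            "SD2Bingham_1_beta": 0.0, "partial_volume_0": 0.6,
        }
        e_b = sdb.attenuation(multi_shell_scheme, **pb)
        e_w = watson_stick_zeppelin.attenuation(multi_shell_scheme,
                                                **WSZ_PARAMS)
        assert np.abs(e_b - e_w).max() < 1e-8

    def test_attenuation_bounds_and_b0(self, watson_stick_zeppelin,
                                       multi_shell_scheme):
        e = watson_stick_zeppelin.attenuation(multi_shell_scheme,
                                              **WSZ_PARAMS)
        assert np.all(e > -1e-6) and np.all(e < 1 + 1e-6)
        np.testing.assert_allclose(e[multi_shell_scheme.b0_mask], 1.0,
                                   atol=1e-6)

    def test_isotropic_only_kernels_warn_and_pass_through(
            self, multi_shell_scheme):
        with pytest.warns(UserWarning, match="identity"):
            sd = distribute_orientation([G1Ball()], "watson")
        e = sd.attenuation(multi_shell_scheme, G1Ball_1_lambda_iso=2e-9,
                           SD1Watson_1_mu=np.zeros(2), SD1Watson_1_odi=0.3)
        np.testing.assert_allclose(
            e, G1Ball().attenuation(multi_shell_scheme, lambda_iso=2e-9),
            atol=1e-12)


class TestLinks:
    def test_tortuosity_values(self):
        sd = SphericalDistributedModel([C1Stick(), G2Zeppelin()], "watson")
        sd.set_equal_parameter("G2Zeppelin_1_lambda_par",
                               "C1Stick_1_lambda_par")
        sd.set_tortuous_parameter("G2Zeppelin_1_lambda_perp",
                                  "G2Zeppelin_1_lambda_par",
                                  "partial_volume_0")
        for f, expected in [(0.5, 0.85e-9), (0.0, 1.7e-9), (1.0, 0.0)]:
            full = sd.registry.resolve({
                "C1Stick_1_lambda_par": 1.7e-9,
                "SD1Watson_1_mu": np.zeros(2), "SD1Watson_1_odi": 0.3,
                "partial_volume_0": f})
            assert full["G2Zeppelin_1_lambda_perp"] == \
                pytest.approx(expected * 1.0, abs=1e-24)

    def test_equal_link_removes_parameter_from_free_set(self):
        sd = SphericalDistributedModel([C1Stick(), G2Zeppelin()], "watson")
        sd.set_equal_parameter("G2Zeppelin_1_lambda_par",
                               "C1Stick_1_lambda_par")
        assert "G2Zeppelin_1_lambda_par" not in sd._parameters

    def test_cyclic_links_rejected(self):
        sd = SphericalDistributedModel([C1Stick(), G2Zeppelin()], "watson")
        sd.set_equal_parameter("G2Zeppelin_1_lambda_par",
                               "C1Stick_1_lambda_par")
        with pytest.raises(ValueError, match="cyclic"):
            sd.set_equal_parameter("C1Stick_1_lambda_par",
                                   "G2Zeppelin_1_lambda_par")


class TestStacking:
    def test_gamma_then_watson_commutes_on_spherical_mean(self):
        """Diameter distribution and orientation dispersion commute in the
        spherical mean (dispersion leaves it invariant)."""
        from mcdmri.phantoms import cat_axcaliber_scheme

        scheme = cat_axcaliber_scheme(n_gradients=12)
        pd = ParameterDistributedModel(
            [C4CylinderGaussianPhase()],
            "C4CylinderGaussianPhase_1_diameter", volume_norm="cylinder")
        sd_of_pd = SphericalDistributedModel([pd], "watson", sh_order=10)
        kw_pd = {
            "PD1GammaDistributed_1_C4CylinderGaussianPhase_1_lambda_par":
                1.7e-9,
            "PD1GammaDistributed_1_C4CylinderGaussianPhase_1_lambda_intra":
                1.7e-9,
            "PD1GammaDistributed_1_PD1Gamma_1_alpha": 3.0,
            "PD1GammaDistributed_1_PD1Gamma_1_beta": 1e-6,
        }
        sm_stacked = sd_of_pd.spherical_mean(
            scheme, SD1Watson_1_mu=np.zeros(2), SD1Watson_1_odi=0.4, **kw_pd)
        sm_pd = pd.spherical_mean(
            scheme,
            C4CylinderGaussianPhase_1_lambda_par=1.7e-9,
            C4CylinderGaussianPhase_1_lambda_intra=1.7e-9,
            PD1Gamma_1_alpha=3.0, PD1Gamma_1_beta=1e-6)
        np.testing.assert_allclose(sm_stacked, sm_pd, atol=1e-3)
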