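"""Fitting strategies: brute2fine, MIX, the two CSD solvers, the
multi-tissue correction and the SS3T schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcdmri.compartments import C1Stick, G1Ball, G2Zeppelin
from mcdmri.framework import MultiCompartmentModel
from mcdmri.optimizers import (
    fractions_to_nested,
    multi_tissue_fit,
    nested_to_fractions,
)
from mcdmri.phantoms import NoiseSpec, add_noise, hcp_like_scheme
from mcdmri.shm import sh_fit
from mcdmri.sphere import angles_to_unit_vector, icosphere


class TestNestedFractions:
    def test_round_trip(self):
        f = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(
            nested_to_fractions(fractions_to_nested(f)), f, atol=1e-14)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(raw=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6))
    def test_any_simplex_point_round_trips(self, raw):
        f = np.asarray(raw) / np.sum(raw)
        back = nested_to_fractions(fractions_to_nested(f))
        np.testing.assert_allclose(back, f, atol=1e-12)

    def test_corner(self):
        f = np.array([1.0, 0.0, 0.0])
        x = fractions_to_nested(f)
        assert x[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nested_to_fractions(x), f, atol=1e-14)

    def test_cube_maps_onto_simplex(self, rng):
        x = rng.uniform(0, 1, (500, 3))
        f = np.stack([nested_to_fractions(xi) for xi in x])
        assert np.all(f >= 0)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)
        # the map covers the simplex: every component reaches both the
        # dominant and the vanishing regime
        assert f.max(axis=0).min() > 0.7
        assert f.min(axis=0).max() < 5e-3


@pytest.fixture(scope="module")
def scheme():
    return hcp_like_scheme(n_per_shell=30, n_b0=6)


def _ball_stick_signal(scheme, mu=(1.1, 0.7), f_stick=0.7):
    mc = MultiCompartmentModel([G1Ball(), C1Stick()])
    truth = {"G1Ball_1_lambda_iso": 2.7e-9, "C1Stick_1_lambda_par": 1.7e-9,
             "C1Stick_1_mu": np.asarray(mu),
             "partial_volume_0": 1 - f_stick, "partial_volume_1": f_stick}
    return mc, truth, mc.simulate_signal(scheme, truth)


class TestBrute2Fine:
    def test_noiseless_recovery(self, scheme):
        mc, truth, sig = _ball_stick_signal(scheme)
        res = mc.fit(scheme, sig)
        for name in ("G1Ball_1_lambda_iso", "C1Stick_1_lambda_par",
                     "partial_volume_1"):
            est = float(np.ravel(res.fitted_parameters[name])[0])
            assert abs(est - truth[name]) / truth[name] < 1e-3
        mu_est = angles_to_unit_vector(
            res.fitted_parameters["C1Stick_1_mu"].ravel())
        mu_true = angles_to_unit_vector(truth["C1Stick_1_mu"])
        angle = np.degrees(np.arccos(min(abs(mu_est @ mu_true), 1.0)))
        assert angle < 0.5

    def test_refinement_never_worse_than_grid_seed(self, scheme):
        mc, truth, sig = _ball_stick_signal(scheme)
        res = mc.fit(scheme, sig)
        assert float(res.mse) < 1e-10  # refined far beyond grid resolution

    def test_deterministic_under_seed(self, scheme):
        mc, truth, sig = _ball_stick_signal(scheme)
        noisy = add_noise(sig[None], NoiseSpec("rician", 30), seed=5)
        r1 = mc.fit(scheme, noisy, seed=11)
        r2 = mc.fit(scheme, noisy, seed=11)
        for name in r1.fitted_parameters:
            np.testing.assert_array_equal(r1.fitted_parameters[name],
                                          r2.fitted_parameters[name])

    def test_noisy_fraction_recovery(self, scheme, rng):
        mc = MultiCompartmentModel([G1Ball(), C1Stick()])
        n = 50
        f = rng.uniform(0.4, 0.8, n)
        sig = mc.simulate_signal(scheme, {
            "G1Ball_1_lambda_iso": np.full(n, 2.7e-9),
            "C1Stick_1_lambda_par": np.full(n, 1.7e-9),
            "C1Stick_1_mu": np.column_stack(
                [rng.uniform(0.3, 2.8, n), rng.uniform(-np.pi, np.pi, n)]),
            "partial_volume_0": 1 - f, "partial_volume_1": f})
        noisy = add_noise(sig, NoiseSpec("rician", 30), seed=3)
        res = mc.fit(scheme, noisy)
        err = np.abs(res.fitted_parameters["partial_volume_1"] - f)
        assert np.median(err) < 0.05

    def test_voxelwise_fixed_map_cascading(self, scheme):
        """Fixing a per-voxel parameter map reproduces per-voxel manual
        fixes (parameter cascading)."""
        lam = np.array([2.0e-9, 2.8e-9])
        mc = MultiCompartmentModel([G1Ball(), C1Stick()])
        sig = mc.simulate_signal(scheme, {
            "G1Ball_1_lambda_iso": lam,
            "C1Stick_1_lambda_par": np.full(2, 1.7e-9),
            "C1Stick_1_mu": np.tile([0.9, 0.4], (2, 1)),
            "partial_volume_0": np.full(2, 0.35),
            "partial_volume_1": np.full(2, 0.65)})
        cascaded = MultiCompartmentModel([G1Ball(), C1Stick()])
        cascaded.fix_parameter("G1Ball_1_lambda_iso", lam)
        res = cascaded.fit(scheme, sig)
        for j in range(2):
            manual = MultiCompartmentModel([G1Ball(), C1Stick()])
            manual.fix_parameter("G1Ball_1_lambda_iso", float(lam[j]))
            res_j = manual.fit(scheme, sig[j][None])
            assert res.fitted_parameters["partial_volume_1"][j] == \
                pytest.approx(
                    float(res_j.fitted_parameters["partial_volume_1"][0]),
                    abs=1e-6)


class TestMix:
    def test_matches_or_beats_brute2fine_on_crossing(self, scheme):
        mc = MultiCompartmentModel([G1Ball(), C1Stick(), C1Stick()])
        sig = mc.simulate_signal(scheme, {
            "G1Ball_1_lambda_iso": 2.7e-9,
            "C1Stick_1_mu": np.array([np.pi / 2, 0.0]),
            "C1Stick_2_mu": np.array([np.pi / 2, np.pi / 2]),
            "C1Stick_1_lambda_par": 1.7e-9, "C1Stick_2_lambda_par": 1.7e-9,
            "partial_volume_0": 0.2, "partial_volume_1": 0.4,
            "partial_volume_2": 0.4})
        res_b = mc.fit(scheme, sig, method="brute2fine")
        res_m = mc.fit(scheme, sig, method="mix", seed=4, de_maxiter=60)
        assert float(res_m.mse) <= float(res_b.mse) + 1e-12

    def test_single_compartment_reduces_to_linear_fit(self, scheme):
        mc = MultiCompartmentModel([G1Ball()])
        mc.fix_parameter("G1Ball_1_lambda_iso", 2e-9)
        sig = G1Ball().attenuation(scheme, lambda_iso=2e-9)
        res = mc.fit(scheme, sig[None], method="mix")
        assert float(res.mse[0]) < 1e-20

    def test_seeded_repeatability(self, scheme):
        mc, truth, sig = _ball_stick_signal(scheme)
        noisy = add_noise(sig[None], NoiseSpec("rician", 25), seed=9)
        r1 = mc.fit(scheme, noisy, method="mix", seed=21, de_maxiter=15)
        r2 = mc.fit(scheme, noisy, method="mix", seed=21, de_maxiter=15)
        for name in r1.fitted_parameters:
            np.testing.assert_array_equal(r1.fitted_parameters[name],
                                          r2.fitted_parameters[name])

    def test_rejects_nonlinear_fractions(self):
        from mcdmri.presets import build_named_model

        mc = build_named_model("mc_mdi")
        sch = hcp_like_scheme(n_per_shell=15, n_b0=3)
        sig = mc.simulate_signal(sch, {"C1Stick_1_lambda_par": 1.7e-9,
                                       "partial_volume_0": 0.6,
                                       "partial_volume_1": 0.4})
        with pytest.raises(ValueError, match="linear"):
            mc.fit(sch, sig[None], method="mix")


class TestCsd:
    def _sh_model(self, scheme, fix_fraction=None):
        mc = MultiCompartmentModel([G1Ball(), C1Stick()], flavor="MC-SH",
                                   sh_order=8)
        mc.fix_parameter("G1Ball_1_lambda_iso", 3e-9)
        mc.fix_parameter("C1Stick_1_lambda_par", 1.7e-9)
        if fix_fraction is not None:
            mc.fix_parameter("partial_volume_0", fix_fraction)
        return mc

    def _single_fiber_signal(self, scheme, mc, mu, f_iso=0.3):
        from mcdmri.distributions import watson_density

        grid = icosphere(4)
        fod = sh_fit(watson_density(grid, mu, 0.06), grid, 8) * (1 - f_iso)
        full = mc.registry.resolve({"sh_coeff": fod,
                                    "partial_volume_0": f_iso})
        return mc.evaluate(scheme, full)

    def test_tournier_single_fiber_peak(self, scheme):
        mc = self._sh_model(scheme, fix_fraction=0.3)
        mu = np.array([1.0, 0.5])
        sig = self._single_fiber_signal(scheme, mc, mu)
        res = mc.fit(scheme, sig[None], method="csd_tournier")
        peak = res.fod_peaks(n_peaks=1).reshape(3)
        angle = np.degrees(np.arccos(
            min(abs(peak @ angles_to_unit_vector(mu)), 1.0)))
        assert angle < 3.0

    def test_tournier_zero_data_zero_fod(self, scheme):
        mc = self._sh_model(scheme, fix_fraction=0.0)
        res = mc.fit(scheme, np.zeros((1, scheme.n_measurements)),
                     method="csd_tournier")
        assert np.abs(res.fitted_parameters["sh_coeff"]).max() < 1e-10

    def test_tournier_rejects_free_fraction_kernels(self, scheme):
        mc = self._sh_model(scheme)
        with pytest.raises(ValueError, match="fixed"):
            mc.fit(scheme, np.ones((1, scheme.n_measurements)),
                   method="csd_tournier")

    def test_tournier_negative_mass_monotone_in_regularization(self, scheme):
        from mcdmri.sphere import symmetric_sphere

        mc = self._sh_model(scheme, fix_fraction=0.3)
        sig = self._single_fiber_signal(scheme, mc, np.array([1.0, 0.5]))
        half = symmetric_sphere(362)[:362]
        masses = []
        for rw in (0.05, 0.5, 5.0):
            res = mc.fit(scheme, sig[None], method="csd_tournier",
                         reg_weight=rw)
            fod = res.fod(half).ravel()
            masses.append(-fod[fod < 0].sum())
        assert masses[0] >= masses[1] >= masses[2]

    def test_constrained_crossing_recovery(self, scheme):
        from mcdmri.distributions import watson_density

        mc = self._sh_model(scheme)
        grid = icosphere(4)
        mu1 = np.array([np.pi / 2, 0.0])
        mu2 = np.array([np.pi / 2, np.pi / 2])
        fod = 0.45 * (sh_fit(watson_density(grid, mu1, 0.06), grid, 8)
                      + sh_fit(watson_density(grid, mu2, 0.06), grid, 8))
        full = mc.registry.resolve({"sh_coeff": fod,
                                    "partial_volume_0": 0.1})
        sig = mc.evaluate(scheme, full)
        res = mc.fit(scheme, sig[None], method="csd")
        peaks = res.fod_peaks(n_peaks=2).reshape(2, 3)
        v1, v2 = (angles_to_unit_vector(m) for m in (mu1, mu2))
        for p in peaks:
            err = min(np.degrees(np.arccos(min(abs(p @ v), 1.0)))
                      for v in (v1, v2))
            assert err < 5.0

    def test_constrained_isotropic_voxel(self, scheme):
        mc = self._sh_model(scheme)
        sig = G1Ball().attenuation(scheme, lambda_iso=3e-9)
        res = mc.fit(scheme, sig[None], method="csd")
        vf = res.volume_fractions
        assert float(vf["anisotropic"][0]) < 0.02

    def test_constrained_fod_nonnegative_on_grid(self, scheme):
        from mcdmri.sphere import symmetric_sphere

        mc = self._sh_model(scheme)
        sig = self._single_fiber_signal(scheme, mc, np.array([0.8, -0.7]))
        res = mc.fit(scheme, sig[None], method="csd")
        fod = res.fod(symmetric_sphere(362)[:362]).ravel()
        assert fod.min() >= -1e-8


class TestMultiTissue:
    def _two_tissue(self, scheme, s0=(2.0, 1.0)):
        mc = MultiCompartmentModel([G1Ball(), G1Ball()],
                                   S0_responses=list(s0))
        mc.fix_parameter("G1Ball_1_lambda_iso", 0.8e-9)
        mc.fix_parameter("G1Ball_2_lambda_iso", 2.5e-9)
        return mc

    def test_s0_ratio_bias_corrected(self, scheme):
        mc = self._two_tissue(scheme)
        sig = mc.simulate_signal(scheme, {"partial_volume_0": 0.5,
                                          "partial_volume_1": 0.5})
        # attenuation-only fitting is measurably biased
        mc_att = MultiCompartmentModel([G1Ball(), G1Ball()])
        mc_att.fix_parameter("G1Ball_1_lambda_iso", 0.8e-9)
        mc_att.fix_parameter("G1Ball_2_lambda_iso", 2.5e-9)
        res_att = mc_att.fit(scheme, sig[None])
        assert abs(float(res_att.fitted_parameters["partial_volume_0"][0])
                   - 0.5) > 0.1
        fr = multi_tissue_fit(mc, scheme, sig[None])
        np.testing.assert_allclose(fr[0], [0.5, 0.5], atol=1e-6)

    def test_equal_s0_matches_attenuation_fit(self, scheme):
        mc = self._two_tissue(scheme, s0=(1.0, 1.0))
        sig = mc.simulate_signal(scheme, {"partial_volume_0": 0.4,
                                          "partial_volume_1": 0.6})
        fr = multi_tissue_fit(mc, scheme, sig[None])
        np.testing.assert_allclose(fr[0], [0.4, 0.6], atol=1e-8)

    def test_zero_signal_zero_fractions(self, scheme):
        mc = self._two_tissue(scheme)
        fr = multi_tissue_fit(mc, scheme,
                              np.zeros((1, scheme.n_measurements)))
        np.testing.assert_array_equal(fr[0], [0.0, 0.0])


class TestSs3t:
    def _setup(self):
        from mcdmri.phantoms import generate_phantom
        from mcdmri.presets import build_named_model
        from mcdmri.tissue_response import (
            estimate_anisotropic_response, estimate_isotropic_response)

        ph = generate_phantom("three_tissue", 60, seed=2)
        sch = ph.scheme
        wm = estimate_anisotropic_response(
            ph.signal, ph.labels == "wm", sch, sh_order=8)
        gm = estimate_isotropic_response(ph.signal, ph.labels == "gm", sch)
        csf = estimate_isotropic_response(ph.signal, ph.labels == "csf", sch)
        mt = build_named_model("mt_csd",
                               responses={"wm": wm, "gm": gm, "csf": csf})
        sub = (sch.bvalues < 10e6) | (np.abs(sch.bvalues - 3e9) < 0.2e9)
        return mt, sch.subset(sub), sub, sch

    def test_zero_iterations_leave_wm_empty(self):
        mt, sch_ss, sub, sch = self._setup()
        sig, _ = _mixed_signals(mt, sch, 3)
        res = mt.fit(sch_ss, sig[:, sub], method="ss3t", n_iterations=0)
        assert np.abs(res.fitted_parameters["sh_coeff"]).max() == 0.0

    def test_fractions_nonnegative(self):
        mt, sch_ss, sub, sch = self._setup()
        sig, _ = _mixed_signals(mt, sch, 4)
        res = mt.fit(sch_ss, sig[:, sub], method="ss3t", n_iterations=4)
        assert res.fitted_parameters["partial_volume_1"].min() >= 0
        assert res.fitted_parameters["partial_volume_2"].min() >= 0

    def test_requires_single_shell(self):
        mt, sch_ss, sub, sch = self._setup()
        sig, _ = _mixed_signals(mt, sch, 2)
        with pytest.raises(ValueError, match="one non-zero shell"):
            mt.fit(sch, sig, method="ss3t")


def _mixed_signals(mt, scheme, n):
    from mcdmri.phantoms import mixed_three_tissue_signals

    return mixed_three_tissue_signals(mt, scheme, n, seed=8)
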