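"""Synthetic ground-truth phantoms, noise models, and reference acquisition
schemes.

The phantom kinds mirror the acquisition regimes in which the preset models
are used in practice:

* ``ivim``          — two-Gaussian (blood/tissue) voxels on a low-b scheme
                      (b <= 1000 s/mm^2, 21 measurements);
* ``gamma_cylinder``— Gamma-distributed-diameter cylinder voxels plus a
                      hindered Ball on a multi-(delta, Delta) high-gradient
                      scheme, perpendicular to the fiber axis;
* ``crossing``      — two Sticks + Ball on a multi-shell scheme with random
                      crossing angles;
* ``dispersed``     — Watson-dispersed Stick+Zeppelin bundles plus CSF Ball;
* ``three_tissue``  — pure WM/GM/CSF voxels with distinct S0 amplitudes
                      (CSF 3x brighter) for tissue-response and
                      multi-tissue workflows.

Every phantom stores the exact noiseless signal, the per-voxel ground-truth
parameter table, the scheme, and the noise specification. Noise is Gaussian
(additive) or Rician (magnitude of a complex Gaussian perturbation), with
SNR defined as b0 amplitude over sigma. All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, build_scheme_from_bvalues, \
    build_scheme_from_gradients
from .sphere import angles_to_unit_vector, golden_spiral_directions, \
    unit_vector_to_angles

__all__ = [
    "Phantom",
    "NoiseSpec",
    "generate_phantom",
    "add_noise",
    "hcp_like_scheme",
    "cat_multishell_scheme",
    "cat_axcaliber_scheme",
    "ivim_scheme",
]


# ---------------------------------------------------------------------------
# reference schemes (printed protocols)

def hcp_like_scheme(n_per_shell: int = 90, n_b0: int = 14) -> AcquisitionScheme:
    """Multi-shell protocol: b = {0, 1000, 2000, 3000} s/mm^2 with
    {14, 90, 90, 90} directions, delta/Delta = 10.6/43.1 ms, TE 89.5 ms."""
    shells_si = [1.0e9, 2.0e9, 3.0e9]
    bvals = [np.zeros(n_b0)]
    dirs = [golden_spiral_directions(n_b0)]
    for i, b in enumerate(shells_si):
        bvals.append(np.full(n_per_shell, b))
        # rotate shells slightly so directions differ between shells
        d = golden_spiral_directions(n_per_shell)
        angle = 0.1 * (i + 1)
        rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                        [np.sin(angle), np.cos(angle), 0], [0, 0, 1.0]])
        dirs.append(d @ rot.T)
    return build_scheme_from_bvalues(
        np.concatenate(bvals), np.vstack(dirs), 10.6e-3, 43.1e-3, TE=89.5e-3)


def cat_multishell_scheme(n_per_shell: int = 40,
                          n_b0: int = 4) -> AcquisitionScheme:
    """Small-bore multi-shell protocol: b = {40, 189, 1680, 6720} s/mm^2,
    delta = 3 ms, Delta = 30 ms, TE = 47 ms."""
    shells_si = [40e6, 189e6, 1680e6, 6720e6]
    bvals = [np.zeros(n_b0)]
    dirs = [golden_spiral_directions(n_b0)]
    for b in shells_si:
        bvals.append(np.full(n_per_shell, b))
        dirs.append(golden_spiral_directions(n_per_shell))
    return build_scheme_from_bvalues(
        np.concatenate(bvals), np.vstack(dirs), 3e-3, 30e-3, TE=47e-3)


def cat_axcaliber_scheme(n_gradients: int = 40) -> AcquisitionScheme:
    """Axon-diameter protocol: pulse timings delta = {3, 8, 8, 8} ms,
    Delta = {7, 12, 25, 40} ms, gradients 0..0.849 T/m, measured
    perpendicular to the (z-aligned) fiber axis."""
    deltas = [3e-3, 8e-3, 8e-3, 8e-3]
    Deltas = [7e-3, 12e-3, 25e-3, 40e-3]
    G = np.linspace(0.0, 0.849, n_gradients)
    g_all, d_all, D_all = [], [], []
    for d, D in zip(deltas, Deltas):
        g_all.append(G)
        d_all.append(np.full(n_gradients, d))
        D_all.append(np.full(n_gradients, D))
    g_all = np.concatenate(g_all)
    dirs = np.tile([[1.0, 0.0, 0.0]], (len(g_all), 1))
    return build_scheme_from_gradients(
        g_all, dirs, np.concatenate(d_all), np.concatenate(D_all))


def ivim_scheme() -> AcquisitionScheme:
    """Low-b protocol: 21 measurements, b spread over 0..1000 s/mm^2."""
    b_smm2 = np.array([0, 10, 20, 30, 40, 60, 80, 100, 120, 140, 160, 180,
                       200, 300, 400, 500, 600, 700, 800, 900, 1000])
    dirs = golden_spiral_directions(len(b_smm2))
    return build_scheme_from_bvalues(b_smm2 * 1e6, dirs, 10e-3, 40e-3)


# ---------------------------------------------------------------------------
# noise

@dataclass
class NoiseSpec:
    family: str = "none"      # none | gaussian | rician
    snr: float = np.inf       # b0 amplitude / sigma

    def __post_init__(self):
        if self.family not in ("none", "gaussian", "rician"):
            raise ValueError("noise family must be none/gaussian/rician")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


def add_noise(signal, noise_spec: NoiseSpec, seed: int = 0,
              b0_amplitude: float = 1.0) -> np.ndarray:
    """Apply the noise model; sigma = b0_amplitude / SNR."""
    signal = np.asarray(signal, dtype=float)
    if noise_spec.family == "none" or not np.isfinite(noise_spec.snr):
        return signal.copy()
    rng = np.random.default_rng(seed)
    sigma = b0_amplitude / noise_spec.snr
    if noise_spec.family == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(real ** 2 + imag ** 2)


# ---------------------------------------------------------------------------
# phantoms

@dataclass
class Phantom:
    signal: np.ndarray          # (n_voxels, n_measurements), noise applied
    noiseless: np.ndarray       # exact simulate_signal output
    ground_truth: pd.DataFrame  # one row per voxel
    scheme: AcquisitionScheme
    noise_spec: NoiseSpec
    labels: np.ndarray | None = None  # tissue class per voxel where relevant


def _finish(model, scheme, params: dict, gt_rows, noise_spec, seed,
            labels=None, s0=None):
    noiseless = model.simulate_signal(scheme, params)
    if s0 is not None:
        noiseless = noiseless * np.asarray(s0)[:, None]
    b0_amp = float(np.mean(np.asarray(s0))) if s0 is not None else 1.0
    signal = add_noise(noiseless, noise_spec, seed=seed + 1,
                       b0_amplitude=b0_amp)
    return Phantom(signal=signal, noiseless=noiseless,
                   ground_truth=pd.DataFrame(gt_rows), scheme=scheme,
                   noise_spec=noise_spec,
                   labels=None if labels is None else np.asarray(labels))


def generate_phantom(kind: str, n_voxels: int, scheme=None, seed: int = 0,
                     noise_spec: NoiseSpec | None = None) -> Phantom:
    """Generate a seeded ground-truth phantom of the requested kind."""
    from .presets import build_named_model

    noise_spec = noise_spec or NoiseSpec()
    rng = np.random.default_rng(seed)

    if kind == "ivim":
        scheme = scheme or ivim_scheme()
        model = build_named_model("ivim_fixed_dstar")
        f_blood = rng.uniform(0.05, 0.35, n_voxels)
        lam_d = rng.uniform(0.6e-9, 2.0e-9, n_voxels)
        params = {"G1Ball_2_lambda_iso": lam_d,
                  "partial_volume_0": f_blood,
                  "partial_volume_1": 1.0 - f_blood}
        gt = {"f_blood": f_blood, "lambda_diffusion": lam_d,
              "lambda_blood": np.full(n_voxels, 7e-9)}
        return _finish(model, scheme, params, gt, noise_spec, seed)

    if kind == "gamma_cylinder":
        scheme = scheme or cat_axcaliber_scheme()
        model = build_named_model("axcaliber")
        model.fix_parameter("PD1GammaDistributed_1_C4CylinderGaussianPhase_1_mu",
                            np.array([0.0, 0.0]))
        alpha = rng.uniform(2.0, 6.0, n_voxels)
        mean_d = rng.uniform(1.5e-6, 5e-6, n_voxels)
        beta = mean_d / alpha
        f_r = rng.uniform(0.4, 0.8, n_voxels)
        lam_h = rng.uniform(0.5e-9, 1.5e-9, n_voxels)
        params = {"G1Ball_1_lambda_iso": lam_h,
                  "PD1GammaDistributed_1_PD1Gamma_1_alpha": alpha,
                  "PD1GammaDistributed_1_PD1Gamma_1_beta": beta,
                  "partial_volume_0": 1.0 - f_r,
                  "partial_volume_1": f_r}
        gt = {"alpha": alpha, "beta": beta, "mean_diameter": mean_d,
              "f_intra": f_r, "lambda_hindered": lam_h}
        return _finish(model, scheme, params, gt, noise_spec, seed)

    if kind == "crossing":
        scheme = scheme or hcp_like_scheme()
        model = build_named_model("ball_and_sticks", n_bundles=2)
        mu1 = np.column_stack([rng.uniform(0.3, np.pi - 0.3, n_voxels),
                               rng.uniform(-np.pi, np.pi, n_voxels)])
        # second bundle crossing at 40-90 degrees from the first
        angles = rng.uniform(np.deg2rad(40), np.deg2rad(90), n_voxels)
        mu2 = np.empty_like(mu1)
        for v in range(n_voxels):
            v1 = angles_to_unit_vector(mu1[v])
            helper = np.array([0.0, 0.0, 1.0]) \
                if abs(v1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            perp = np.cross(v1, helper)
            perp /= np.linalg.norm(perp)
            mu2[v] = unit_vector_to_angles(
                np.cos(angles[v]) * v1 + np.sin(angles[v]) * perp)
        f_iso = rng.uniform(0.1, 0.3, n_voxels)
        f1 = rng.uniform(0.3, 0.5, n_voxels) * (1 - f_iso)
        f2 = (1 - f_iso) - f1
        lam = rng.uniform(1.5e-9, 2.0e-9, n_voxels)
        params = {"G1Ball_1_lambda_iso": np.full(n_voxels, 3e-9),
                  "C1Stick_1_mu": mu1, "C1Stick_2_mu": mu2,
                  "C1Stick_1_lambda_par": lam, "C1Stick_2_lambda_par": lam,
                  "partial_volume_0": f_iso, "partial_volume_1": f1,
                  "partial_volume_2": f2}
        gt = {"f_iso": f_iso, "f_bundle_1": f1, "f_bundle_2": f2,
              "crossing_angle_deg": np.rad2deg(angles),
              "mu1_theta": mu1[:, 0], "mu1_phi": mu1[:, 1],
              "mu2_theta": mu2[:, 0], "mu2_phi": mu2[:, 1]}
        return _finish(model, scheme, params, gt, noise_spec, seed)

    if kind == "dispersed":
        scheme = scheme or hcp_like_scheme()
        model = build_named_model("noddi_watson")
        mu = np.column_stack([rng.uniform(0.3, np.pi - 0.3, n_voxels),
                              rng.uniform(-np.pi, np.pi, n_voxels)])
        odi = rng.uniform(0.15, 0.6, n_voxels)
        f_intra = rng.uniform(0.4, 0.7, n_voxels)
        f_csf = rng.uniform(0.0, 0.2, n_voxels)
        params = {"SD1WatsonDistributed_1_SD1Watson_1_mu": mu,
                  "SD1WatsonDistributed_1_SD1Watson_1_odi": odi,
                  "SD1WatsonDistributed_1_partial_volume_0": f_intra,
                  "partial_volume_0": f_csf,
                  "partial_volume_1": 1.0 - f_csf}
        gt = {"odi": odi, "f_intra": f_intra, "f_csf": f_csf,
              "mu_theta": mu[:, 0], "mu_phi": mu[:, 1]}
        return _finish(model, scheme, params, gt, noise_spec, seed)

    if kind == "three_tissue":
        scheme = scheme or hcp_like_scheme()
        # pure-tissue voxels; CSF S0 three times brighter than WM/GM
        from .compartments import G1Ball, G2Zeppelin
        from .framework import MultiCompartmentModel

        n_each = n_voxels // 3
        n_wm = n_voxels - 2 * n_each
        labels = np.array(["wm"] * n_wm + ["gm"] * n_each + ["csf"] * n_each)
        wm = MultiCompartmentModel([G2Zeppelin()])
        mu = np.column_stack([rng.uniform(0, np.pi, n_wm),
                              rng.uniform(-np.pi, np.pi, n_wm)])
        sig_wm = wm.simulate_signal(scheme, {
            "G2Zeppelin_1_mu": mu,
            "G2Zeppelin_1_lambda_par": np.full(n_wm, 1.7e-9),
            "G2Zeppelin_1_lambda_perp": np.full(n_wm, 0.35e-9)})
        gm = MultiCompartmentModel([G1Ball()])
        sig_gm = gm.simulate_signal(scheme, {
            "G1Ball_1_lambda_iso": np.full(n_each, 0.8e-9)})
        csf = gm.simulate_signal(scheme, {
            "G1Ball_1_lambda_iso": np.full(n_each, 3.0e-9)})
        s0 = np.concatenate([np.full(n_wm, 1.0), np.full(n_each, 1.0),
                             np.full(n_each, 3.0)])
        noiseless = np.vstack([sig_wm, sig_gm, csf]) * s0[:, None]
        signal = add_noise(noiseless, noise_spec, seed=seed + 1,
                           b0_amplitude=1.0)
        gt = pd.DataFrame({"tissue": labels, "S0": s0})
        return Phantom(signal=signal, noiseless=noiseless, ground_truth=gt,
                       scheme=scheme, noise_spec=noise_spec, labels=labels)

    raise ValueError(f"unknown phantom kind {kind!r}")


def mixed_three_tissue_signals(mt_model, scheme, n_voxels, seed=0,
                               odi_range=(0.03, 0.10),
                               noise_spec: NoiseSpec | None = None):
    """Mixed WM/GM/CSF voxels built from a multi-tissue MC-SH model's own
    responses.

    White matter enters as a coherent single bundle: a Watson FOD with an
    orientation dispersion drawn from ``odi_range`` (default: the coherent-
    tract regime) at a random orientation. Returns (signals, fractions
    (n, 3) in WM/GM/CSF order).
    """
    from .distributions import watson_density
    from .shm import sh_fit
    from .sphere import icosphere

    noise_spec = noise_spec or NoiseSpec()
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet([4.0, 2.5, 1.5], n_voxels)
    odis = rng.uniform(*odi_range, n_voxels)
    grid = icosphere(4)
    order = mt_model.sh_order
    iso = mt_model._iso_indices()
    sig = np.zeros((n_voxels, scheme.n_measurements))
    for v in range(n_voxels):
        mu = [rng.uniform(0.3, np.pi - 0.3), rng.uniform(-np.pi, np.pi)]
        fod_c = sh_fit(watson_density(grid, mu, odis[v]), grid, order) \
            * fractions[v, 0]
        full = mt_model.registry.resolve({
            "sh_coeff": fod_c,
            f"partial_volume_{iso[0]}": fractions[v, 1],
            f"partial_volume_{iso[1]}": fractions[v, 2]})
        sig[v] = mt_model.evaluate(scheme, full)
    sig = add_noise(sig, noise_spec, seed=seed + 1, b0_amplitude=1.0)
    return sig, fractions
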