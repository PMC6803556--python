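"""Microscopic compartment signal models for PGSE.

Gaussian models (G1 Ball, G2 Zeppelin, G3 Temporal Zeppelin), restricted
cylinders (C1 Stick, C2 Stejskal-Tanner, C3 Callaghan, C4 Gaussian Phase) and
restricted spheres (S1 Dot, S2-S4 under the same three approximations).

Every model exposes the three attenuation representations used by the
multi-compartment machinery:

* ``attenuation(scheme, **params)`` — one value in [0, 1] per measurement;
* ``spherical_mean(scheme, **params)`` — one value per acquisition shell
  (closed form where available, Gauss-Legendre quadrature otherwise);
* ``rotational_harmonics(shells, order, **params)`` — per-shell m = 0 SH
  coefficients of the z-aligned kernel, feeding spherical convolution.

Anisotropic models are axially symmetric about an orientation ``mu`` given
as (theta, phi) Euler angles and factorize into parallel and perpendicular
components via b_par = b (mu.n)^2 and q_perp = q sqrt(1 - (mu.n)^2).

The restricted-geometry series use the standard literature results: the
long-time SGP diffraction patterns (C2/S2), the finite-time SGP
eigenfunction expansions over Neumann Bessel roots (C3/S3), and the
Gaussian-phase Bessel-root series (C4 cylinder, S4 sphere). Series lengths
are module constants with convergence checked in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, j1, jnp_zeros, jv, jvp, spherical_jn

from .acquisition import AcquisitionScheme, shell_probe
from .constants import GYROMAGNETIC_RATIO
from .shm import (
    _gauss_legendre,
    convolution_scaling,
    real_sh_basis,
    rotational_harmonics_transform,
    sh_degrees,
)
from .sphere import angles_to_unit_vector

__all__ = [
    "CompartmentModel",
    "G1Ball", "G2Zeppelin", "G3TemporalZeppelin",
    "C1Stick", "C2CylinderStejskalTanner", "C3CylinderCallaghan",
    "C4CylinderGaussianPhase",
    "S1Dot", "S2SphereStejskalTanner", "S3SphereCallaghan",
    "S4SphereGaussianPhase",
    "model_from_id",
]

# default optimization bounds (SI)
DIFFUSIVITY_BOUNDS = (0.1e-9, 3e-9)
DIAMETER_BOUNDS = (1e-7, 2e-5)
MU_BOUNDS = ((0.0, np.pi), (-np.pi, np.pi))

GAUSSIAN_PHASE_N_ROOTS = 20
CALLAGHAN_N_ORDERS = 12
CALLAGHAN_N_ROOTS = 12


# ---------------------------------------------------------------------------
# Bessel-root caches

@lru_cache(maxsize=64)
def _cylinder_neumann_roots(n: int, k: int):
    """First k positive roots of J_n'."""
    return jnp_zeros(n, k)


@lru_cache(maxsize=64)
def _sphere_neumann_roots(n: int, k: int):
    """First k positive roots of the spherical Bessel derivative j_n'."""
    f = lambda x: spherical_jn(n, x, derivative=True)
    roots, x0, step = [], 0.1 + 1e-3, 0.05
    hi = (k + n + 4) * np.pi
    xs = np.arange(x0, hi, step)
    vals = f(xs)
    sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    for i in sign_change:
        roots.append(brentq(f, xs[i], xs[i + 1]))
        if len(roots) == k:
            break
    return np.array(roots)


def _erf_mean(x):
    """sqrt(pi) erf(sqrt(x)) / (2 sqrt(x)), the spherical mean of
    exp(-x t^2) over t in [0, 1]; equals 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    pos = x > 1e-12
    sx = np.sqrt(x[pos])
    out[pos] = np.sqrt(np.pi) * erf(sx) / (2 * sx)
    return out


# ---------------------------------------------------------------------------
# base class

class CompartmentModel:
    """Base class: named parameters with cardinality, SI unit and bounds."""

    # subclasses fill: name -> (cardinality, unit, bounds)
    _parameters: dict = {}
    is_anisotropic: bool = False
    is_axially_symmetric: bool = True

    @property
    def orientation_parameter(self):
        """Name of the orientation parameter, or None for isotropic models."""
        return "mu" if self.is_anisotropic else None

    @property
    def model_id(self) -> str:
        return type(self).__name__[:2]

    @property
    def name(self) -> str:
        return type(self).__name__

    @property
    def parameter_names(self):
        return list(self._parameters)

    @property
    def parameter_cardinality(self):
        return {k: v[0] for k, v in self._parameters.items()}

    @property
    def parameter_units(self):
        return {k: v[1] for k, v in self._parameters.items()}

    @property
    def parameter_bounds(self):
        return {k: v[2] for k, v in self._parameters.items()}

    # hooks ------------------------------------------------------------
    def _check_params(self, params):
        missing = set(self._parameters) - set(params)
        if missing:
            raise ValueError(f"{self.name}: missing parameters {sorted(missing)}")

    def attenuation(self, scheme, **params) -> np.ndarray:
        self._check_params(params)
        return self._attenuation(scheme, **params)

    __call__ = attenuation

    def spherical_mean(self, scheme, **params) -> np.ndarray:
        """Per-shell mean over the sphere; the orientation is irrelevant and
        may be omitted."""
        params = dict(params)
        if self.orientation_parameter:
            params.pop(self.orientation_parameter, None)
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        if not shells:
            raise ValueError("empty shell list")
        analytic = self._spherical_mean_analytic(shells, **params)
        if analytic is not None:
            return analytic
        return self._spherical_mean_numeric(shells, **params)

    def _spherical_mean_analytic(self, shells, **params):
        return None

    def _spherical_mean_numeric(self, shells, n_nodes: int = 64, **params):
        p = dict(params)
        if self.orientation_parameter:
            p[self.orientation_parameter] = np.array([0.0, 0.0])
        out = np.empty(len(shells))
        if self.is_axially_symmetric:
            u, w, theta = _gauss_legendre(n_nodes)
            dirs = np.column_stack(
                [np.sin(theta), np.zeros_like(theta), np.cos(theta)])
            for s, shell in enumerate(shells):
                vals = self._attenuation(shell_probe(shell, dirs), **p)
                out[s] = 0.5 * float(w @ vals)
        else:
            from .shm import gauss_legendre_sphere

            dirs, w = gauss_legendre_sphere(32, 64)
            for s, shell in enumerate(shells):
                vals = self._attenuation(shell_probe(shell, dirs), **p)
                out[s] = float(w @ vals) / (4 * np.pi)
        return out

    def rotational_harmonics(self, scheme, sh_order: int, **params) -> np.ndarray:
        """Per-shell r_{s,l} of the z-aligned kernel (orientation fixed to +z)."""
        params = dict(params)
        orient = self.orientation_parameter
        if orient:
            params.pop(orient, None)
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        if not self.is_anisotropic:
            sm = self.spherical_mean(shells, **params)
            out = np.zeros((len(shells), sh_order // 2 + 1))
            out[:, 0] = sm * np.sqrt(4 * np.pi)
            return out
        if not self.is_axially_symmetric:
            raise ValueError(f"{self.name} is not axially symmetric and has "
                             "no rotational-harmonics representation")
        p = dict(params, **{orient: np.array([0.0, 0.0])})

        def sampler(shell, dirs):
            return self._attenuation(shell_probe(shell, dirs), **p)

        return rotational_harmonics_transform(sampler, shells, sh_order)

    def convolution_kernel_matrix(self, scheme: AcquisitionScheme,
                                  sh_order: int, **params) -> np.ndarray:
        """Matrix mapping FOD SH coefficients to the predicted per-DWI signal."""
        if sh_order % 2:
            raise ValueError("sh_order must be even")
        rh = self.rotational_harmonics(scheme, sh_order, **params)
        ls, _ = sh_degrees(sh_order)
        from .shm import scheme_sh_basis
        basis = scheme_sh_basis(scheme, sh_order)
        scale = convolution_scaling(sh_order)
        per_meas_rh = rh[scheme.shell_indices][:, ls // 2]
        return basis * scale * per_meas_rh

    # helpers ----------------------------------------------------------
    @staticmethod
    def _mu_vector(mu):
        mu = np.asarray(mu, dtype=float)
        if mu.shape == (3,):
            return mu / np.linalg.norm(mu)
        return angles_to_unit_vector(mu)


# ---------------------------------------------------------------------------
# Gaussian models

class G1Ball(CompartmentModel):
    """Isotropic Gaussian (free/hindered isotropic diffusion)."""

    _parameters = {"lambda_iso": (1, "m^2/s", DIFFUSIVITY_BOUNDS)}

    def _attenuation(self, scheme, lambda_iso):
        if lambda_iso < 0:
            raise ValueError("lambda_iso must be non-negative")
        return np.exp(-scheme.bvalues * lambda_iso)

    def _spherical_mean_analytic(self, shells, lambda_iso):
        b = np.array([s.b for s in shells])
        return np.exp(-b * lambda_iso)


class G2Zeppelin(CompartmentModel):
    """Axially symmetric Gaussian with lambda_perp <= lambda_par."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "lambda_perp": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
    }
    is_anisotropic = True

    def _attenuation(self, scheme, mu, lambda_par, lambda_perp):
        if lambda_perp > lambda_par * (1 + 1e-12):
            raise ValueError("Zeppelin requires lambda_perp <= lambda_par")
        muv = self._mu_vector(mu)
        dot2 = (scheme.directions @ muv) ** 2
        return np.exp(-scheme.bvalues *
                      (lambda_perp + (lambda_par - lambda_perp) * dot2))

    def _spherical_mean_analytic(self, shells, lambda_par, lambda_perp):
        if lambda_perp > lambda_par * (1 + 1e-12):
            raise ValueError("Zeppelin requires lambda_perp <= lambda_par")
        b = np.array([s.b for s in shells])
        return np.exp(-b * lambda_perp) * _erf_mean(b * (lambda_par - lambda_perp))


class G3TemporalZeppelin(CompartmentModel):
    """Zeppelin whose perpendicular diffusivity relaxes with diffusion time:
    lambda_perp = lambda_inf + A [ln(Delta/delta) + 3/2] / (Delta - delta/3),
    modeling disordered extra-axonal hindrance."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "lambda_inf": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "A": (1, "m^-2", (0.0, 1e-11)),
    }
    is_anisotropic = True

    def _lambda_perp(self, scheme, lambda_inf, A):
        if np.any(scheme.Delta <= scheme.delta):
            raise ValueError("Temporal Zeppelin requires Delta > delta")
        tau = scheme.Delta - scheme.delta / 3.0
        return lambda_inf + A * (np.log(scheme.Delta / scheme.delta) + 1.5) / tau

    def _attenuation(self, scheme, mu, lambda_par, lambda_inf, A):
        lperp = self._lambda_perp(scheme, lambda_inf, A)
        muv = self._mu_vector(mu)
        dot2 = (scheme.directions @ muv) ** 2
        return np.exp(-scheme.bvalues * (lperp + (lambda_par - lperp) * dot2))


# ---------------------------------------------------------------------------
# cylinders

def _perp_decomposition(scheme, muv):
    dot = scheme.directions @ muv
    dot2 = np.clip(dot ** 2, 0.0, 1.0)
    sin2 = 1.0 - dot2
    return dot2, np.sqrt(sin2)


class C1Stick(CompartmentModel):
    """Zero-radius cylinder: Gaussian along mu, no perpendicular signal loss."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
    }
    is_anisotropic = True

    def _attenuation(self, scheme, mu, lambda_par):
        muv = self._mu_vector(mu)
        dot2, _ = _perp_decomposition(scheme, muv)
        return np.exp(-scheme.bvalues * lambda_par * dot2)

    def _spherical_mean_analytic(self, shells, lambda_par):
        b = np.array([s.b for s in shells])
        return _erf_mean(b * lambda_par)


def _cylinder_diffraction(x):
    """SGP long-time disk pattern |2 J1(x) / x|^2."""
    out = np.ones_like(x)
    nz = x > 1e-8
    out[nz] = (2 * j1(x[nz]) / x[nz]) ** 2
    return out


def _sphere_diffraction(x):
    """SGP long-time sphere pattern |3 j1(x) / x|^2."""
    out = np.ones_like(x)
    nz = x > 1e-8
    xn = x[nz]
    out[nz] = (3 * (np.sin(xn) - xn * np.cos(xn)) / xn ** 3) ** 2
    return out


class C2CylinderStejskalTanner(CompartmentModel):
    """Cylinder under SGP + long diffusion time (diffraction pattern)."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "diameter": (1, "m", DIAMETER_BOUNDS),
    }
    is_anisotropic = True

    def _attenuation(self, scheme, mu, lambda_par, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        muv = self._mu_vector(mu)
        dot2, sin_ = _perp_decomposition(scheme, muv)
        e_par = np.exp(-scheme.bvalues * lambda_par * dot2)
        x = 2 * np.pi * scheme.qvalues * sin_ * (diameter / 2.0)
        return e_par * _cylinder_diffraction(x)


def _callaghan_cylinder_perp(q_tilde, t_norm):
    """Finite-time SGP disk attenuation; q_tilde = 2 pi q R, t_norm = D t / R^2."""
    e = _cylinder_diffraction(q_tilde)  # stationary mode
    qt = np.where(q_tilde < 1e-8, 1e-8, q_tilde)
    for n in range(CALLAGHAN_N_ORDERS):
        beta = _cylinder_neumann_roots(n, CALLAGHAN_N_ROOTS)[:, None]
        jp = jvp(n, qt)
        denom = np.maximum((qt ** 2 - beta ** 2) ** 2, 1e-24)
        coef = 4.0 if n == 0 else 8.0 * beta ** 2 / (beta ** 2 - n ** 2)
        e = e + (coef * (qt * jp) ** 2 / denom
                 * np.exp(-beta ** 2 * t_norm)).sum(axis=0)
    return np.clip(e, 0.0, 1.0)


class C3CylinderCallaghan(CompartmentModel):
    """Cylinder under SGP with finite diffusion time (eigenmode series)."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "lambda_intra": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "diameter": (1, "m", DIAMETER_BOUNDS),
    }
    is_anisotropic = True

    def _attenuation(self, scheme, mu, lambda_par, lambda_intra, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        muv = self._mu_vector(mu)
        dot2, sin_ = _perp_decomposition(scheme, muv)
        e_par = np.exp(-scheme.bvalues * lambda_par * dot2)
        radius = diameter / 2.0
        q_tilde = 2 * np.pi * scheme.qvalues * sin_ * radius
        t_norm = lambda_intra * scheme.tau / radius ** 2
        return e_par * _callaghan_cylinder_perp(q_tilde, t_norm)


def _gaussian_phase_log(G_eff, delta, Delta, D, radius, roots, planar_offset):
    """Common Gaussian-phase log-attenuation series.

    roots are the dimensionless Neumann roots (J1' for cylinders, j1' for
    spheres); planar_offset is 1 (cylinder) or 2 (sphere) in the
    (R^2 alpha^2 - offset) denominator.
    """
    alpha = (roots / radius)[:, None]                      # (n_roots, 1)
    a2d = alpha ** 2 * D
    num = (2 * a2d * delta - 2
           + 2 * np.exp(-a2d * delta) + 2 * np.exp(-a2d * Delta)
           - np.exp(-a2d * (Delta - delta)) - np.exp(-a2d * (Delta + delta)))
    den = D ** 2 * alpha ** 6 * (radius ** 2 * alpha ** 2 - planar_offset)
    ln_e = (num / den).sum(axis=0)
    return -2 * GYROMAGNETIC_RATIO ** 2 * G_eff ** 2 * ln_e


class C4CylinderGaussianPhase(CompartmentModel):
    """Cylinder under the Gaussian-phase approximation (finite pulses)."""

    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "lambda_par": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "lambda_intra": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "diameter": (1, "m", DIAMETER_BOUNDS),
    }
    is_anisotropic = True

    def _attenuation(self, scheme, mu, lambda_par, lambda_intra, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        muv = self._mu_vector(mu)
        dot2, sin_ = _perp_decomposition(scheme, muv)
        e_par = np.exp(-scheme.bvalues * lambda_par * dot2)
        roots = _cylinder_neumann_roots(1, GAUSSIAN_PHASE_N_ROOTS)
        ln_e = _gaussian_phase_log(
            scheme.gradient_strengths * sin_, scheme.delta, scheme.Delta,
            lambda_intra, diameter / 2.0, roots, planar_offset=1.0)
        return e_par * np.exp(ln_e)


# ---------------------------------------------------------------------------
# spheres

class S1Dot(CompartmentModel):
    """Non-diffusing compartment: unit attenuation everywhere."""

    _parameters = {}

    def _attenuation(self, scheme):
        return np.ones(len(scheme.bvalues))

    def _spherical_mean_analytic(self, shells):
        return np.ones(len(shells))


class S2SphereStejskalTanner(CompartmentModel):
    """Sphere under SGP + long diffusion time (diffraction pattern)."""

    _parameters = {"diameter": (1, "m", DIAMETER_BOUNDS)}

    def _attenuation(self, scheme, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        x = 2 * np.pi * scheme.qvalues * (diameter / 2.0)
        return _sphere_diffraction(x)


class S3SphereCallaghan(CompartmentModel):
    """Sphere under SGP with finite diffusion time (eigenmode series)."""

    _parameters = {
        "lambda_intra": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "diameter": (1, "m", DIAMETER_BOUNDS),
    }

    def _attenuation(self, scheme, lambda_intra, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        radius = diameter / 2.0
        q_tilde = 2 * np.pi * scheme.qvalues * radius
        t_norm = lambda_intra * scheme.tau / radius ** 2
        e = _sphere_diffraction(q_tilde)
        qt = np.where(q_tilde < 1e-8, 1e-8, q_tilde)
        for n in range(CALLAGHAN_N_ORDERS):
            alpha = _sphere_neumann_roots(n, CALLAGHAN_N_ROOTS)[:, None]
            jp = spherical_jn(n, qt, derivative=True)
            denom = np.maximum((qt ** 2 - alpha ** 2) ** 2, 1e-24)
            coef = 6.0 * (2 * n + 1) * alpha ** 2 / (alpha ** 2 - n * (n + 1))
            e = e + (coef * (qt * jp) ** 2 / denom
                     * np.exp(-alpha ** 2 * t_norm)).sum(axis=0)
        return np.clip(e, 0.0, 1.0)


class S4SphereGaussianPhase(CompartmentModel):
    """Sphere under the Gaussian-phase approximation (finite pulses)."""

    _parameters = {
        "lambda_intra": (1, "m^2/s", DIFFUSIVITY_BOUNDS),
        "diameter": (1, "m", DIAMETER_BOUNDS),
    }

    def _attenuation(self, scheme, lambda_intra, diameter):
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        roots = _sphere_neumann_roots(1, GAUSSIAN_PHASE_N_ROOTS)
        ln_e = _gaussian_phase_log(
            scheme.gradient_strengths, scheme.delta, scheme.Delta,
            lambda_intra, diameter / 2.0, roots, planar_offset=2.0)
        return np.exp(ln_e)


_MODEL_IDS = {
    "G1": G1Ball, "G2": G2Zeppelin, "G3": G3TemporalZeppelin,
    "C1": C1Stick, "C2": C2CylinderStejskalTanner,
    "C3": C3CylinderCallaghan, "C4": C4CylinderGaussianPhase,
    "S1": S1Dot, "S2": S2SphereStejskalTanner,
    "S3": S3SphereCallaghan, "S4": S4SphereGaussianPhase,
}


def model_from_id(model_id: str) -> CompartmentModel:
    """Instantiate a compartment model from its short id (e.g. 'C1')."""
    try:
        return _MODEL_IDS[model_id]()
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}; "
                         f"choose from {sorted(_MODEL_IDS)}") from None
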