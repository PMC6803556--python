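"""Distributed composite models.

Two composite kinds wrap one or more compartment models:

* :class:`ParameterDistributedModel` integrates a scalar parameter (typically
  the cylinder/sphere diameter) over a Gamma distribution, with the geometric
  volume weighting N(xi) — plate xi, cylinder pi xi^2, sphere (4/3) pi xi^3 —
  because larger geometries hold proportionally more spins;
* :class:`SphericalDistributedModel` disperses axially symmetric kernels over
  orientation with a Watson or Bingham distribution, evaluated as a per-shell
  spherical convolution in the SH domain. All kernels share the same
  distribution; their own orientations are replaced by the distribution's.

Both are themselves compartment models (sub-MC-models), so they can be
combined, nested (e.g. Gamma-diameter cylinders dispersed by a Watson), and
linked (equality and tortuosity constraints live at this level).
"""

from __future__ import annotations

import warnings

import numpy as np

from .acquisition import cluster_shells
from .compartments import MU_BOUNDS, CompartmentModel
from .distributions import (
    bingham_density,
    gamma_density,
    watson_rotational_harmonics,
)
from .parameters import ParameterRegistry
from .shm import (
    convolution_scaling,
    kernel_sh_coefficients,
    real_sh_basis,
    sh_degrees,
    sh_fit_matrix,
)
from .sphere import angles_to_unit_vector

__all__ = [
    "SD1Watson",
    "SD2Bingham",
    "SphericalDistributedModel",
    "ParameterDistributedModel",
    "distribute_parameter",
    "distribute_orientation",
]

GAMMA_QUAD_POINTS = 35          # grid over the central 99.7 % Gamma mass
DEFAULT_SH_ORDER = 14           # dispersion convolution order


class SD1Watson:
    """Parameter spec of the Watson orientation distribution."""

    name = "SD1Watson"
    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "odi": (1, "-", (0.02, 0.99)),
    }


class SD2Bingham:
    """Parameter spec of the Bingham orientation distribution."""

    name = "SD2Bingham"
    _parameters = {
        "mu": (2, "rad", MU_BOUNDS),
        "psi": (1, "rad", (0.0, np.pi)),
        "odi": (1, "-", (0.02, 0.99)),
        "beta": (1, "-", (0.0, 1.0)),
    }


def _shells_of(scheme):
    if hasattr(scheme, "shells") and hasattr(scheme, "shell_indices"):
        return scheme.shells, scheme.shell_indices
    indices, shells = cluster_shells(scheme)
    return shells, indices


class _CompositeModel(CompartmentModel):
    """Shared registry plumbing for distributed models."""

    registry: ParameterRegistry

    @property
    def _parameters(self):
        # effective (externally visible) parameters: the registry's free set
        return {n: (e.cardinality, e.unit, e.bounds)
                for n, e in self.registry.entries.items()
                if e.status == "free"}

    # the three link/fix operations of the distributed-model level ------
    def set_fixed_parameter(self, name, value):
        self.registry.fix(name, value)
        return self

    def set_equal_parameter(self, target, source):
        self.registry.link_equal(target, source)
        return self

    def set_tortuous_parameter(self, lambda_perp_name, lambda_par_name,
                               fraction_name):
        """Impose lambda_perp = (1 - f_intra) * lambda_par inside this model."""
        self.registry.link_tortuous(
            lambda_perp_name, lambda_par_name, fraction_name)
        return self

    def _fractions(self, full, n_sub):
        if n_sub == 1:
            return np.array([1.0])
        f = np.array([float(full[f"partial_volume_{i}"])
                      for i in range(n_sub - 1)])
        if np.any(f < 0) or f.sum() > 1 + 1e-9:
            raise ValueError("sub-model fractions must be a simplex point")
        return np.append(f, max(1.0 - f.sum(), 0.0))


class SphericalDistributedModel(_CompositeModel):
    """Watson/Bingham-dispersed mixture of axially symmetric kernels."""

    is_anisotropic = True

    @property
    def is_axially_symmetric(self):
        return self.distribution == "watson"

    @property
    def orientation_parameter(self):
        return f"{self._dist_prefix()}_mu"

    def __init__(self, models, distribution: str = "watson",
                 sh_order: int = DEFAULT_SH_ORDER):
        if distribution not in ("watson", "bingham"):
            raise ValueError("distribution must be 'watson' or 'bingham'")
        if sh_order % 2:
            raise ValueError("sh_order must be even")
        self.distribution = distribution
        self.sh_order = sh_order
        self.models = list(models)
        self._identity = False
        if not any(m.is_anisotropic for m in self.models):
            warnings.warn("no anisotropic kernel to disperse; the spherical "
                          "distribution acts as the identity", stacklevel=2)
            self._identity = True
        spec = SD1Watson() if distribution == "watson" else SD2Bingham()
        self._dist_spec = spec
        self.registry = ParameterRegistry.from_models(self.models + [spec])
        # kernels are z-aligned; their own orientations are removed
        for prefix, model in self.registry.sub_models[:-1]:
            orient = model.orientation_parameter
            if orient is not None and f"{prefix}_{orient}" in \
                    self.registry.entries:
                self.registry.fix(f"{prefix}_{orient}", np.array([0.0, 0.0]))
        for i in range(len(self.models) - 1):
            self.registry.add(f"partial_volume_{i}", 1, "-", (0.0, 1.0))

    @property
    def name(self):
        return ("SD1WatsonDistributed" if self.distribution == "watson"
                else "SD2BinghamDistributed")

    # -- evaluation ------------------------------------------------------
    def _dist_prefix(self):
        return self.registry.sub_models[-1][0]

    def _kernel_rh(self, shells, full):
        kwargs = self.registry.scatter(full)
        fractions = self._fractions(full, len(self.models))
        rh = 0.0
        for f, (prefix, model), kw in zip(
                fractions, self.registry.sub_models, kwargs):
            kw = dict(kw)
            kw.pop(model.orientation_parameter or "mu", None)
            rh = rh + f * model.rotational_harmonics(
                shells, self.sh_order, **kw)
        return rh

    def _distribution_sh(self, full):
        p = self._dist_prefix()
        mu = np.asarray(full[f"{p}_mu"], dtype=float)
        odi = float(full[f"{p}_odi"])
        muv = angles_to_unit_vector(mu) if mu.shape == (2,) else mu
        if self.distribution == "watson":
            w_l = watson_rotational_harmonics(odi, self.sh_order)
            return kernel_sh_coefficients(w_l, muv, self.sh_order)
        pinv, grid = sh_fit_matrix(self.sh_order)
        dens = bingham_density(grid, mu, float(full[f"{p}_psi"]), odi,
                               float(full[f"{p}_beta"]))
        return pinv @ dens

    def _attenuation(self, scheme, **params):
        full = self.registry.resolve(params)
        shells, shell_idx = _shells_of(scheme)
        if self._identity:
            kwargs = self.registry.scatter(full)
            fractions = self._fractions(full, len(self.models))
            return sum(f * m._attenuation(scheme, **kw) for f, (_, m), kw in
                       zip(fractions, self.registry.sub_models, kwargs))
        rh_mix = self._kernel_rh(shells, full)
        coeffs = self._distribution_sh(full)
        ls, _ = sh_degrees(self.sh_order)
        conv = (convolution_scaling(self.sh_order) * coeffs
                * rh_mix[:, ls // 2])            # (n_shells, n_coef)
        from .shm import scheme_sh_basis
        basis = scheme_sh_basis(scheme, self.sh_order)
        return np.einsum("ij,ij->i", basis, conv[shell_idx])

    def _spherical_mean_analytic(self, shells, **params):
        # dispersion preserves the spherical mean: mixture of kernel means
        full = self.registry.resolve(
            {**params, f"{self._dist_prefix()}_mu": np.zeros(2)}
            if f"{self._dist_prefix()}_mu" not in params else params)
        kwargs = self.registry.scatter(full)
        fractions = self._fractions(full, len(self.models))
        out = 0.0
        for f, (_, model), kw in zip(
                fractions, self.registry.sub_models, kwargs):
            kw.pop(model.orientation_parameter or "mu", None)
            out = out + f * model.spherical_mean(shells, **kw)
        return out

    def spherical_mean(self, scheme, **params):
        params = dict(params)
        dist_mu = f"{self._dist_prefix()}_mu"
        params.setdefault(dist_mu, np.zeros(2))
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        return self._spherical_mean_analytic(shells, **params)

    def rotational_harmonics(self, scheme, sh_order, **params):
        if self.distribution == "bingham":
            raise ValueError(
                "a Bingham-dispersed model is not axially symmetric and has "
                "no rotational-harmonics representation")
        params = dict(params)
        params.pop(f"{self._dist_prefix()}_mu", None)
        full = self.registry.resolve(
            {**params, f"{self._dist_prefix()}_mu": np.zeros(2)})
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        rh_mix = self._kernel_rh(shells, full)[:, :sh_order // 2 + 1]
        w_l = watson_rotational_harmonics(
            float(full[f"{self._dist_prefix()}_odi"]), sh_order)
        ls = np.arange(0, sh_order + 1, 2)
        return np.sqrt(4 * np.pi / (2 * ls + 1)) * w_l * rh_mix


class ParameterDistributedModel(_CompositeModel):
    """Gamma-integrated scalar parameter (axon-diameter distribution etc.)."""

    def __init__(self, models, distributed_parameter: str,
                 volume_norm: str | None = None,
                 diameter_mean_convention: str = "alpha*beta"):
        self.models = list(models)
        self.registry = ParameterRegistry.from_models(self.models)
        if distributed_parameter not in self.registry.entries:
            raise ValueError(
                f"unknown parameter {distributed_parameter!r}; available: "
                f"{sorted(self.registry.entries)}")
        if self.registry.cardinality(distributed_parameter) != 1:
            raise ValueError("only cardinality-1 parameters can be distributed")
        self._target = distributed_parameter
        del self.registry.entries[distributed_parameter]
        if volume_norm is None:
            local = distributed_parameter.split("_")[-1]
            owner = distributed_parameter.split("_")[0]
            if local == "diameter":
                volume_norm = "cylinder" if owner.startswith("C") else "sphere"
            else:
                volume_norm = "none"
        if volume_norm not in ("none", "plate", "cylinder", "sphere"):
            raise ValueError(f"unknown volume norm {volume_norm!r}")
        self.volume_norm = volume_norm
        if diameter_mean_convention not in ("alpha*beta", "2*alpha*beta"):
            raise ValueError("unknown diameter mean convention")
        self.diameter_mean_convention = diameter_mean_convention
        self.registry.add("PD1Gamma_1_alpha", 1, "-", (1.1, 30.0))
        self.registry.add("PD1Gamma_1_beta", 1, "m", (2e-8, 3e-6))
        for i in range(len(self.models) - 1):
            self.registry.add(f"partial_volume_{i}", 1, "-", (0.0, 1.0))

    name = property(lambda self: "PD1GammaDistributed")

    @property
    def is_anisotropic(self):
        return any(m.is_anisotropic for m in self.models)

    @property
    def orientation_parameter(self):
        for prefix, model in self.registry.sub_models:
            if model.is_anisotropic:
                name = f"{prefix}_mu"
                if name in self.registry.entries and \
                        self.registry.entries[name].status == "free":
                    return name
        return None

    def mean_distributed_value(self, alpha, beta):
        """Reported mean of the distributed quantity under the configured
        convention (alpha*beta, or 2*alpha*beta for a radius-type reading)."""
        factor = 1.0 if self.diameter_mean_convention == "alpha*beta" else 2.0
        return factor * alpha * beta

    def _quadrature(self, alpha, beta):
        from scipy.stats import gamma as gamma_dist

        lo, hi = gamma_dist.ppf([0.0015, 0.9985], a=alpha, scale=beta)
        xi = np.linspace(max(lo, 1e-12), hi, GAMMA_QUAD_POINTS)
        pdf = gamma_density(xi, alpha, beta)
        norm = {"none": np.ones_like(xi), "plate": xi,
                "cylinder": np.pi * xi ** 2,
                "sphere": (4.0 / 3.0) * np.pi * xi ** 3}[self.volume_norm]
        w = pdf * norm
        # trapezoid weights on the xi grid, then the printed normalization
        dx = np.gradient(xi)
        w = w * dx
        return xi, w / w.sum()

    def _quad_apply(self, fn, **params):
        full = self.registry.resolve(params)
        alpha = float(full["PD1Gamma_1_alpha"])
        beta = float(full["PD1Gamma_1_beta"])
        fractions = self._fractions(full, len(self.models))
        xi, w = self._quadrature(alpha, beta)
        out = 0.0
        for x, wx in zip(xi, w):
            full_x = dict(full)
            full_x[self._target] = x
            kwargs = self.registry.scatter(full_x)
            val = sum(f * fn(model, kw) for f, (_, model), kw in
                      zip(fractions, self.registry.sub_models, kwargs))
            out = out + wx * val
        return out

    def _fill_orientations(self, params):
        """Free sub-model orientations default to +z when irrelevant
        (spherical-mean / rotational-harmonics evaluation)."""
        filled = dict(params)
        for prefix, m in self.registry.sub_models:
            orient = m.orientation_parameter
            if orient is None:
                continue
            name = f"{prefix}_{orient}"
            if name in self.registry.entries and \
                    self.registry.entries[name].status == "free":
                filled.setdefault(name, np.zeros(2))
        return filled

    def _attenuation(self, scheme, **params):
        return self._quad_apply(
            lambda m, kw: m._attenuation(scheme, **kw), **params)

    def _spherical_mean_analytic(self, shells, **params):
        return self._quad_apply(
            lambda m, kw: m.spherical_mean(
                shells, **{k: v for k, v in kw.items()
                           if k != (m.orientation_parameter or "mu")}),
            **self._fill_orientations(params))

    def rotational_harmonics(self, scheme, sh_order, **params):
        params = dict(params)
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        # quadrature of the z-aligned kernels' rotational harmonics
        filled = self._fill_orientations(params)
        return self._quad_apply(
            lambda m, kw: m.rotational_harmonics(
                shells, sh_order,
                **{k: v for k, v in kw.items()
                   if k != (m.orientation_parameter or "mu")}),
            **filled)


def distribute_parameter(models, parameter_name, volume_norm=None,
                         **kwargs) -> ParameterDistributedModel:
    """Gamma-distribute a named cardinality-1 parameter of the given models."""
    return ParameterDistributedModel(models, parameter_name,
                                     volume_norm=volume_norm, **kwargs)


def distribute_orientation(models, distribution_family="watson",
                           sh_order=DEFAULT_SH_ORDER) -> SphericalDistributedModel:
    """Disperse the orientation of the given kernels with a Watson/Bingham."""
    return SphericalDistributedModel(models, distribution_family, sh_order)
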