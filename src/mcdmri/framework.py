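"""Multi-compartment model assembly: MC, MC-SM and MC-SH flavors.

A :class:`MultiCompartmentModel` aggregates compartment/distributed models
into one fittable object. Parameters are registered under prefixed names
``<ModelName>_<enumeration>_<param>`` plus volume fractions
``partial_volume_<i>``; parameters can be fixed (globally or voxel-wise for
cascading), set equal across sub-models, or tied by a tortuosity rule
(distributed-model level only — at the MC level volume fractions must stay
linear so that linear-in-fractions optimizers remain applicable).

Flavors:

* ``MC``     — signal is the fraction-weighted sum of sub-model attenuations
               per measurement;
* ``MC-SM``  — per-shell spherical means; orientation parameters are
               meaningless and removed from the registry;
* ``MC-SH``  — kernels are convolved with a non-parametric FOD in spherical
               harmonics; kernel orientations are replaced by ``sh_coeff``.
               Only one anisotropic kernel may carry a free fraction; more
               are allowed only with fixed fractions, in which case they are
               mixed into a single effective kernel.

Optionally, per-model S0 responses turn the predicted attenuation into a
signal-scale prediction for multi-tissue fitting. ``fit`` returns a
:class:`~mcdmri.optimizers.FitResults` carrying parameter maps, goodness of
fit and a summary table.
"""

from __future__ import annotations

import json

import numpy as np

from .acquisition import AcquisitionScheme
from .parameters import ParameterRegistry

__all__ = ["MultiCompartmentModel", "model_to_spec", "model_from_spec"]

_FLAVORS = ("MC", "MC-SM", "MC-SH")


class MultiCompartmentModel:
    def __init__(self, models, flavor: str = "MC", sh_order: int = 8,
                 S0_responses=None, fixed_anisotropic_fractions=None):
        if flavor not in _FLAVORS:
            raise ValueError(f"flavor must be one of {_FLAVORS}")
        self.models = list(models)
        self.flavor = flavor
        self.sh_order = int(sh_order)
        if self.sh_order % 2:
            raise ValueError("sh_order must be even")
        if S0_responses is not None:
            S0_responses = [float(s) for s in S0_responses]
            if len(S0_responses) != len(self.models):
                raise ValueError("one S0 response per model required")
        self.S0_responses = S0_responses
        self.registry = ParameterRegistry.from_models(self.models)
        self._aniso_idx = [i for i, m in enumerate(self.models)
                           if m.is_anisotropic]
        self.fixed_anisotropic_fractions = fixed_anisotropic_fractions

        if flavor in ("MC-SM", "MC-SH"):
            # orientations are meaningless (SM) / replaced by the FOD (SH)
            for prefix, model in self.registry.sub_models:
                orient = model.orientation_parameter
                if orient is not None:
                    name = f"{prefix}_{orient}"
                    if name in self.registry.entries:
                        del self.registry.entries[name]

        if flavor == "MC-SH":
            if len(self._aniso_idx) == 0:
                raise ValueError("MC-SH requires an anisotropic kernel")
            if len(self._aniso_idx) > 1:
                if fixed_anisotropic_fractions is None:
                    raise ValueError(
                        "only one anisotropic convolution kernel may have a "
                        "free volume fraction; pass "
                        "fixed_anisotropic_fractions to mix several")
                if len(fixed_anisotropic_fractions) != len(self._aniso_idx):
                    raise ValueError("one fixed fraction per anisotropic "
                                     "kernel required")
            from .shm import n_coefficients
            self.registry.add("sh_coeff", n_coefficients(self.sh_order),
                              "-", (None, None))
            for i, m in enumerate(self.models):
                if not m.is_anisotropic:
                    self.registry.add(f"partial_volume_{i}", 1, "-",
                                      (0.0, 1.0))
        else:
            if len(self.models) > 1:
                for i in range(len(self.models)):
                    self.registry.add(f"partial_volume_{i}", 1, "-",
                                      (0.0, 1.0))
            if flavor == "MC-SM":
                for m in self.models:
                    if not hasattr(m, "spherical_mean"):
                        raise ValueError(
                            f"{m.name} cannot produce a spherical mean")

    # ------------------------------------------------------------------
    @property
    def parameter_names(self):
        return list(self.registry.entries)

    @property
    def free_parameter_names(self):
        return self.registry.free_names

    @property
    def parameter_cardinality(self):
        return {n: e.cardinality for n, e in self.registry.entries.items()}

    @property
    def n_fractions(self):
        return sum(1 for n in self.registry.entries
                   if n.startswith("partial_volume"))

    # -- fixing and linking ---------------------------------------------
    def set_parameter_bounds(self, name, lower, upper):
        """Adjust the optimization range of a cardinality-1 parameter."""
        e = self.registry._require(name)
        if e.cardinality != 1:
            raise ValueError("bounds adjustment supports scalar parameters")
        e.bounds = (float(lower), float(upper))
        return self

    def fix_parameter(self, name, value):
        """Fix globally (scalar/pair) or voxel-wise (array map, cascading)."""
        self.registry.fix(name, value)
        return self

    def link_equal(self, name_a, name_b):
        """Constrain name_a to track name_b."""
        self.registry.link_equal(name_a, name_b)
        return self

    def link_tortuous(self, perp_name, par_name, fraction_name):
        if self.flavor == "MC":
            raise ValueError(
                "tortuosity links are rejected at the MC level: they would "
                "make a volume fraction non-linear; apply the constraint "
                "inside the distributed model instead")
        self.registry.link_tortuous(perp_name, par_name, fraction_name)
        return self

    # -- evaluation ------------------------------------------------------
    def _fractions_from(self, full):
        if self.flavor == "MC-SH":
            raise RuntimeError("MC-SH fractions live in sh_coeff")
        if len(self.models) == 1:
            return np.array([1.0])
        return np.array([float(full[f"partial_volume_{i}"])
                         for i in range(len(self.models))])

    def evaluate(self, scheme, full_params: dict) -> np.ndarray:
        """Model prediction for one voxel in the flavor's data space.

        MC: per-measurement; MC-SM: per-shell; MC-SH: per-measurement with
        sh_coeff/partial volumes taken from ``full_params``.
        """
        if self.flavor == "MC-SH":
            x = self._sh_solution_vector(full_params)
            return self.csd_design_matrix(scheme, full_params) @ x
        fractions = self._fractions_from(full_params)
        s0 = self.S0_responses or [1.0] * len(self.models)
        kwargs = self.registry.scatter(full_params)
        out = 0.0
        for f, amp, (_, model), kw in zip(
                fractions, s0, self.registry.sub_models, kwargs):
            if self.flavor == "MC":
                out = out + f * amp * model.attenuation(scheme, **kw)
            else:
                kw = {k: v for k, v in kw.items()
                      if k != model.orientation_parameter}
                out = out + f * amp * model.spherical_mean(scheme, **kw)
        return out

    # -- MC-SH machinery -------------------------------------------------
    def _iso_indices(self):
        return [i for i, m in enumerate(self.models) if not m.is_anisotropic]

    def _sh_solution_vector(self, full):
        parts = [np.asarray(full["sh_coeff"], dtype=float)]
        for i in self._iso_indices():
            parts.append(np.atleast_1d(
                float(full[f"partial_volume_{i}"])))
        return np.concatenate(parts)

    def anisotropic_kernel_rh(self, scheme, full_params):
        """Per-shell rotational harmonics of the (possibly mixed) anisotropic
        kernel at the given kernel parameters."""
        kwargs = self.registry.scatter(full_params)
        rh = 0.0
        if len(self._aniso_idx) == 1:
            weights = [1.0]
        else:
            weights = self.fixed_anisotropic_fractions
        for w, i in zip(weights, self._aniso_idx):
            prefix, model = self.registry.sub_models[i]
            kw = {k: v for k, v in kwargs[i].items()
                  if k != model.orientation_parameter}
            rh = rh + w * model.rotational_harmonics(
                scheme, self.sh_order, **kw)
        return rh

    def csd_design_matrix(self, scheme: AcquisitionScheme, full_params):
        """Columns: SH coefficients of the FOD, then isotropic fractions,
        each weighted by its S0 response when responses are set."""
        from .shm import (convolution_scaling, scheme_sh_basis, sh_degrees)

        rh = self.anisotropic_kernel_rh(scheme, full_params)
        ls, _ = sh_degrees(self.sh_order)
        basis = scheme_sh_basis(scheme, self.sh_order)
        per_meas = rh[scheme.shell_indices][:, ls // 2]
        aniso_block = basis * convolution_scaling(self.sh_order) * per_meas
        s0 = self.S0_responses or [1.0] * len(self.models)
        aniso_s0 = s0[self._aniso_idx[0]]
        blocks = [aniso_s0 * aniso_block]
        kwargs = self.registry.scatter(full_params)
        for i in self._iso_indices():
            _, model = self.registry.sub_models[i]
            blocks.append(
                (s0[i] * model.attenuation(scheme, **kwargs[i]))[:, None])
        return np.hstack(blocks)

    # -- simulation -------------------------------------------------------
    def simulate_signal(self, scheme, parameter_sets) -> np.ndarray:
        """Simulate voxels from a dict of parameter values.

        Values may be scalars/pairs (shared) or arrays with leading voxel
        dimensions. Output is (voxels..., n_measurements) for MC/MC-SH and
        (voxels..., n_shells) for MC-SM; with S0 responses set the output is
        a signal, otherwise an attenuation.
        """
        free = self.free_parameter_names
        missing = [n for n in free if n not in parameter_sets]
        if missing:
            raise ValueError(f"missing parameter values for {missing}")
        # voxel shape from the first array-valued entry
        vox_shape = ()
        for n in free:
            v = np.asarray(parameter_sets[n], dtype=float)
            card = self.registry.cardinality(n)
            expected_tail = (card,) if card > 1 else ()
            if v.shape != expected_tail:
                vox_shape = v.shape[:len(v.shape) - len(expected_tail)]
                break
        n_vox = int(np.prod(vox_shape)) if vox_shape else 1

        def value_at(name, j):
            v = np.asarray(parameter_sets[name], dtype=float)
            card = self.registry.cardinality(name)
            tail = (card,) if card > 1 else ()
            if v.shape == tail:
                return v if card > 1 else float(v)
            flatv = v.reshape((n_vox,) + tail)
            return flatv[j] if card > 1 else float(flatv[j])

        outs = []
        for j in range(n_vox):
            full = self.registry.resolve(
                {n: value_at(n, j) for n in free})
            outs.append(self.evaluate(scheme, full))
        out = np.stack(outs)
        return out.reshape(vox_shape + out.shape[1:]) if vox_shape else out[0]

    # presets may mark compositions that need specific acquisition features
    requires_multiple_diffusion_times: bool = False

    # -- fitting -----------------------------------------------------------
    def fit(self, scheme, data, method: str | None = None, **options):
        """Fit the model voxel-wise; returns a FitResults object.

        method defaults to 'brute2fine' (MC/MC-SM) or 'csd' (MC-SH).
        """
        import warnings

        from . import optimizers

        if self.requires_multiple_diffusion_times:
            timings = {(s.delta, s.Delta) for s in scheme.shells
                       if not s.is_b0}
            if len(timings) < 2:
                warnings.warn(
                    "this composition estimates restricted-geometry sizes, "
                    "which the signal is only sensitive to across multiple "
                    "(delta, Delta) combinations; the provided scheme has "
                    "a single pulse timing", stacklevel=2)
        return optimizers.fit(self, scheme, data, method=method, **options)

    # -- serialization ------------------------------------------------------
    def to_spec(self) -> dict:
        return {
            "flavor": self.flavor,
            "sh_order": self.sh_order,
            "S0_responses": self.S0_responses,
            "models": [model_to_spec(m) for m in self.models],
            "parameters": self.registry.as_spec(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_spec(), indent=2)

    def __repr__(self):
        return (f"MultiCompartmentModel({self.flavor}, "
                f"models={[m.name for m in self.models]}, "
                f"free={self.free_parameter_names})")


# ---------------------------------------------------------------------------
# (de)serialization of model compositions

def model_to_spec(model) -> dict:
    from .compartments import CompartmentModel
    from .distributed import ParameterDistributedModel, SphericalDistributedModel

    if isinstance(model, SphericalDistributedModel):
        return {
            "kind": "spherical_distributed",
            "distribution": model.distribution,
            "sh_order": model.sh_order,
            "models": [model_to_spec(m) for m in model.models],
            "parameters": model.registry.as_spec(),
        }
    if isinstance(model, ParameterDistributedModel):
        return {
            "kind": "parameter_distributed",
            "distributed_parameter": model._target,
            "volume_norm": model.volume_norm,
            "models": [model_to_spec(m) for m in model.models],
            "parameters": model.registry.as_spec(),
        }
    if isinstance(model, CompartmentModel):
        return {"kind": "compartment", "class": type(model).__name__}
    raise TypeError(f"cannot serialize {model!r}")


def _apply_param_spec(registry, spec):
    for name, info in spec.items():
        if name not in registry.entries:
            continue
        if info["status"] == "fixed":
            registry.fix(name, np.asarray(info["value"])
                         if isinstance(info["value"], list) else info["value"])
        elif info["status"] == "linked":
            link = info["link"]
            if link[0] == "equal":
                registry.link_equal(name, link[1])
            elif link[0] == "tortuous":
                registry.link_tortuous(name, link[1], link[2])
            elif link[0] == "scaled":
                registry.link_scaled(name, link[1], link[2])


def model_from_spec(spec: dict):
    from . import compartments
    from .distributed import ParameterDistributedModel, SphericalDistributedModel

    kind = spec.get("kind", "multi_compartment")
    if kind == "compartment":
        return getattr(compartments, spec["class"])()
    if kind == "spherical_distributed":
        m = SphericalDistributedModel(
            [model_from_spec(s) for s in spec["models"]],
            spec["distribution"], spec["sh_order"])
        _apply_param_spec(m.registry, spec["parameters"])
        return m
    if kind == "parameter_distributed":
        m = ParameterDistributedModel(
            [model_from_spec(s) for s in spec["models"]],
            spec["distributed_parameter"], volume_norm=spec["volume_norm"])
        _apply_param_spec(m.registry, spec["parameters"])
        return m
    raise ValueError(f"unknown model spec kind {kind!r}")


def mc_model_from_spec(spec: dict) -> MultiCompartmentModel:
    mc = MultiCompartmentModel(
        [model_from_spec(s) for s in spec["models"]],
        flavor=spec["flavor"], sh_order=spec["sh_order"],
        S0_responses=spec.get("S0_responses"))
    _apply_param_spec(mc.registry, spec["parameters"])
    return mc
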