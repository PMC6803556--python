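"""Voxel-wise fitting of multi-compartment models.

Four strategies cover the three model flavors:

* ``brute2fine`` (MC, MC-SM) — exhaustive sampling of the free parameters on
  an equispaced grid inside the optimization bounds (orientations on a
  hemisphere point set), followed by bounded quasi-Newton (L-BFGS-B)
  refinement from the best grid point. The unity constraint on volume
  fractions is enforced by the nested transform between the unit cube and
  the simplex.
* ``mix`` (MC, MC-SM) — separates linear volume fractions from the
  non-linear kernel parameters: differential evolution searches the
  non-linear space while fractions are solved by non-negative least squares
  at every candidate; a local refinement of all parameters follows.
* ``csd_tournier`` / ``csd`` (MC-SH) — the classic iteratively reweighted
  Tikhonov scheme penalizing (not forbidding) negative FOD amplitudes, and
  a hard-constrained quadratic program (FOD >= 0 on a dense grid,
  non-negative isotropic fractions, optional unity constraint).
* ``ss3t`` (MC-SH, 3 tissues, single shell + b0) — the alternating partial
  convex optimization schedule with a fixed iteration count.

A secondary ``multi_tissue_fit`` re-estimates volume fractions against the
raw signal with S0-weighted compartments, removing the bias of
attenuation-only fitting when tissues differ in S0.

All optimizers are deterministic under a fixed seed and fit voxels
independently. Fitting returns a :class:`FitResults` with per-voxel
parameter maps, mean squared residual and R^2, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize, nnls

from .shm import real_sh_basis, sh_eval
from .sphere import hemisphere, symmetric_sphere, unit_vector_to_angles

logger = logging.getLogger(__name__)

__all__ = [
    "fit",
    "FitResults",
    "fractions_to_nested",
    "nested_to_fractions",
    "fit_brute2fine",
    "fit_mix",
    "fit_csd_tournier",
    "fit_csd_constrained",
    "fit_ss3t",
    "multi_tissue_fit",
]

DEFAULT_NS = 5                 # grid points per scalar parameter
DEFAULT_ORIENTATION_GRID = 30  # hemisphere points for orientation search
GRID_BUDGET = 50_000           # brute-force candidate budget before warning
LBFGSB_OPTIONS = {"maxiter": 300, "ftol": 1e-14, "gtol": 1e-10}


# ---------------------------------------------------------------------------
# nested volume fractions: invertible map cube <-> simplex

def fractions_to_nested(fractions) -> np.ndarray:
    """Simplex point (f_1..f_N, sum 1) -> (N-1) nested coordinates in [0, 1]:
    f_1 = x_1, f_2 = (1 - x_1) x_2, ..., f_N = prod(1 - x_i)."""
    f = np.asarray(fractions, dtype=float)
    x = np.empty(len(f) - 1)
    rest = 1.0
    for i in range(len(f) - 1):
        x[i] = f[i] / rest if rest > 1e-15 else 0.0
        rest -= f[i]
    return np.clip(x, 0.0, 1.0)


def nested_to_fractions(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    f = np.empty(len(x) + 1)
    rest = 1.0
    for i, xi in enumerate(x):
        f[i] = rest * xi
        rest *= (1.0 - xi)
    f[-1] = rest
    return f


# ---------------------------------------------------------------------------
# data preparation

def _voxelize(data):
    data = np.asarray(data, dtype=float)
    vox_shape = data.shape[:-1]
    return data.reshape(-1, data.shape[-1]), vox_shape


def normalize_attenuation(data_flat, scheme):
    """Divide each voxel by its mean b0 signal; returns (attenuation, S0)."""
    if scheme.b0_mask.any():
        s0 = data_flat[:, scheme.b0_mask].mean(axis=1)
    else:
        s0 = np.ones(len(data_flat))
    safe = np.where(s0 > 0, s0, 1.0)
    return data_flat / safe[:, None], s0


def shell_means(data_flat, scheme):
    """Per-shell arithmetic mean over directions (estimated spherical mean)."""
    out = np.empty((len(data_flat), scheme.n_shells))
    for s in scheme.shells:
        members = scheme.shell_indices == s.shell_id
        out[:, s.shell_id] = data_flat[:, members].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# free-parameter vector codec (unit-box scaling, nested fractions)

class _Codec:
    """Maps the model's free parameters to a scaled vector in [0, 1]^d."""

    def __init__(self, model):
        self.model = model
        free = model.free_parameter_names
        self.fraction_names = [n for n in free
                               if n.startswith("partial_volume")]
        self.scalar_names = [n for n in free
                             if not n.startswith("partial_volume")]
        self.entries = []  # (name, component_index, lo, hi)
        for name in self.scalar_names:
            card = model.registry.cardinality(name)
            bounds = model.registry.bounds(name)
            if card == 1:
                self.entries.append((name, None, *bounds))
            else:
                for c in range(card):
                    self.entries.append((name, c, *bounds[c]))
        # fixed fraction mass (scalar fixes only)
        fixed_mass = 0.0
        for n, e in model.registry.entries.items():
            if n.startswith("partial_volume") and e.status == "fixed" \
                    and np.ndim(e.value) == 0:
                fixed_mass += float(e.value)
        self.free_mass = max(1.0 - fixed_mass, 0.0)
        self.n_nested = max(len(self.fraction_names) - 1, 0)
        self.n_dim = len(self.entries) + self.n_nested

    def to_params(self, x) -> dict:
        """Scaled vector -> dict of physical free-parameter values."""
        out: dict = {}
        for (name, comp, lo, hi), xi in zip(self.entries, x):
            val = lo + xi * (hi - lo)
            if comp is None:
                out[name] = val
            else:
                out.setdefault(name, np.zeros(
                    self.model.registry.cardinality(name)))
                out[name][comp] = val
        if self.fraction_names:
            if self.n_nested:
                nested = np.clip(x[len(self.entries):], 0.0, 1.0)
                fr = nested_to_fractions(nested) * self.free_mass
            else:
                fr = np.array([self.free_mass])
            for name, f in zip(self.fraction_names, fr):
                out[name] = float(f)
        return out

    def to_vector(self, params: dict) -> np.ndarray:
        x = np.empty(self.n_dim)
        for j, (name, comp, lo, hi) in enumerate(self.entries):
            val = params[name] if comp is None else params[name][comp]
            x[j] = (val - lo) / (hi - lo)
        if self.n_nested:
            fr = np.array([params[n] for n in self.fraction_names])
            total = self.free_mass if self.free_mass > 0 else 1.0
            x[len(self.entries):] = fractions_to_nested(fr / total)
        return np.clip(x, 0.0, 1.0)


def _voxel_fixed_overrides(model, vox_shape, j):
    """Per-voxel values for array-valued (cascaded) fixed parameters."""
    out = {}
    n_vox = int(np.prod(vox_shape)) if vox_shape else 1
    for name, e in model.registry.entries.items():
        if e.status != "fixed" or np.ndim(e.value) == 0:
            continue
        card = e.cardinality
        val = np.asarray(e.value, dtype=float)
        tail = (card,) if card > 1 else ()
        if val.shape == tail:
            continue
        expected = vox_shape + tail
        if val.shape != expected:
            raise ValueError(
                f"voxel-wise fixed map for {name} has shape {val.shape}, "
                f"expected {expected}")
        flat = val.reshape((n_vox,) + tail)
        out[name] = flat[j] if card > 1 else float(flat[j])
    return out


def _resolve(model, free_params, overrides):
    values = dict(free_params)
    values.update(overrides)
    return model.registry.resolve(values)


# ---------------------------------------------------------------------------
# results object

class FitResults:
    """Per-voxel fitted parameters, goodness of fit and reconstructions."""

    def __init__(self, model, scheme, fitted_parameters, mse, r2,
                 vox_shape, optimizer, S0=None, flags=None):
        self.model = model
        self.scheme = scheme
        self.fitted_parameters = fitted_parameters
        self.mse = mse
        self.r2 = r2
        self.vox_shape = vox_shape
        self.optimizer = optimizer
        self.S0 = S0
        self.flags = flags if flags is not None else \
            np.zeros(vox_shape, dtype=bool)

    # -- reconstruction ------------------------------------------------
    def _full_params_flat(self, j):
        free = {}
        n_vox = int(np.prod(self.vox_shape)) if self.vox_shape else 1
        for name in self.model.free_parameter_names:
            card = self.model.registry.cardinality(name)
            tail = (card,) if card > 1 else ()
            arr = np.asarray(self.fitted_parameters[name])
            flat = arr.reshape((n_vox,) + tail)
            free[name] = flat[j] if card > 1 else float(flat[j])
        overrides = _voxel_fixed_overrides(self.model, self.vox_shape, j)
        return _resolve(self.model, free, overrides)

    def predict(self, scheme=None) -> np.ndarray:
        scheme = scheme if scheme is not None else self.scheme
        n_vox = int(np.prod(self.vox_shape)) if self.vox_shape else 1
        out = [self.model.evaluate(scheme, self._full_params_flat(j))
               for j in range(n_vox)]
        out = np.stack(out)
        return out.reshape(self.vox_shape + out.shape[1:])

    def fod(self, directions) -> np.ndarray:
        """Evaluate the fitted FOD (MC-SH models) at unit directions."""
        if "sh_coeff" not in self.fitted_parameters:
            raise ValueError("model has no FOD (sh_coeff) parameter")
        coeffs = self.fitted_parameters["sh_coeff"]
        flat = coeffs.reshape(-1, coeffs.shape[-1])
        vals = np.stack([sh_eval(c, directions) for c in flat])
        return vals.reshape(self.vox_shape + (len(np.atleast_2d(directions)),))

    def fod_peaks(self, n_peaks=2, grid_n=362, min_separation_deg=25.0):
        """Dominant FOD peak directions per voxel: dense-grid maxima followed
        by local refinement of the SH amplitude on the sphere."""
        from scipy.optimize import minimize as _minimize

        from .sphere import angles_to_unit_vector as _a2v
        from .sphere import unit_vector_to_angles as _v2a

        grid = hemisphere(grid_n)
        amp = self.fod(grid)
        flat_amp = amp.reshape(-1, grid_n)
        coeffs = self.fitted_parameters["sh_coeff"].reshape(
            -1, self.fitted_parameters["sh_coeff"].shape[-1])
        peaks = np.zeros((len(flat_amp), n_peaks, 3))
        for v, a in enumerate(flat_amp):
            a = a.copy()
            for p in range(n_peaks):
                i = int(np.argmax(a))
                if a[i] <= 0:
                    break
                ang0 = _v2a(grid[i])
                res = _minimize(
                    lambda ang: -float(
                        sh_eval(coeffs[v], _a2v(ang)[None, :])[0]),
                    ang0, method="Nelder-Mead",
                    options={"xatol": 1e-5, "fatol": 1e-12})
                peaks[v, p] = _a2v(res.x)
                sep = np.abs(grid @ grid[i]) > np.cos(
                    np.deg2rad(min_separation_deg))
                a[sep] = -np.inf
        return peaks.reshape(self.vox_shape + (n_peaks, 3))

    @property
    def volume_fractions(self) -> dict:
        """Normalized volume fractions per sub-model."""
        out = {}
        if self.model.flavor == "MC-SH":
            aniso = self.fitted_parameters["sh_coeff"][..., 0] * \
                np.sqrt(4 * np.pi)
            parts = {"anisotropic": aniso}
            for i in self.model._iso_indices():
                name = f"partial_volume_{i}"
                if name in self.fitted_parameters:
                    parts[name] = self.fitted_parameters[name]
                else:
                    e = self.model.registry.entries[name]
                    parts[name] = np.broadcast_to(
                        np.asarray(e.value, float), aniso.shape)
            total = sum(parts.values())
            total = np.where(total > 0, total, 1.0)
            return {k: v / total for k, v in parts.items()}
        n = len(self.model.models)
        if n == 1:
            return {"partial_volume_0": np.ones(self.vox_shape)}
        for i in range(n):
            name = f"partial_volume_{i}"
            if name in self.fitted_parameters:
                out[name] = self.fitted_parameters[name]
            else:
                e = self.model.registry.entries[name]
                out[name] = np.broadcast_to(
                    np.asarray(e.value, float),
                    self.vox_shape if self.vox_shape else ())
        return out

    def summary(self) -> str:
        rows = []
        for name, arr in self.fitted_parameters.items():
            a = np.asarray(arr, dtype=float)
            card = self.model.registry.cardinality(name) \
                if name in self.model.registry.entries else 1
            if card > 1 and name != "sh_coeff":
                for c in range(a.shape[-1]):
                    comp = a[..., c]
                    rows.append((f"{name}[{c}]", np.median(comp),
                                 np.percentile(comp, 25),
                                 np.percentile(comp, 75)))
            elif name == "sh_coeff":
                frac = a[..., 0] * np.sqrt(4 * np.pi)
                rows.append(("fod_volume_fraction", np.median(frac),
                             np.percentile(frac, 25),
                             np.percentile(frac, 75)))
            else:
                rows.append((name, np.median(a), np.percentile(a, 25),
                             np.percentile(a, 75)))
        df = pd.DataFrame(rows, columns=["parameter", "median", "q25", "q75"])
        lines = [
            f"{type(self.model).__name__} ({self.model.flavor}) fitted with "
            f"{self.optimizer}",
            f"voxels: {int(np.prod(self.vox_shape)) if self.vox_shape else 1}"
            f", median MSE: {np.median(self.mse):.3e}, "
            f"median R^2: {np.median(self.r2):.4f}",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.flags.any():
            lines.append(f"WARNING: {int(self.flags.sum())} voxels flagged "
                         "as not converged")
        return "\n".join(lines)


def _gof(y, yhat):
    resid = y - yhat
    mse = float(np.mean(resid ** 2))
    denom = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / denom if denom > 0 else 1.0
    return mse, r2


def _pack_results(model, scheme, vox_shape, per_voxel_params, mse, r2,
                  optimizer, S0=None, flags=None):
    fitted = {}
    n_vox = len(per_voxel_params)
    for name in model.free_parameter_names:
        card = model.registry.cardinality(name)
        tail = (card,) if card > 1 else ()
        arr = np.empty((n_vox,) + tail)
        for j, p in enumerate(per_voxel_params):
            arr[j] = p[name]
        fitted[name] = arr.reshape(vox_shape + tail)
    return FitResults(
        model, scheme, fitted,
        np.asarray(mse).reshape(vox_shape),
        np.asarray(r2).reshape(vox_shape), vox_shape, optimizer, S0=S0,
        flags=None if flags is None else np.asarray(flags).reshape(vox_shape))


# ---------------------------------------------------------------------------
# brute2fine

def _target_data(model, scheme, data):
    """Flattened voxel data in the model flavor's space, plus S0 map.

    MC-SM models accept either per-measurement data (reduced to shell means
    here) or data already given per shell.
    """
    flat, vox_shape = _voxelize(data)
    if model.flavor == "MC-SM" and flat.shape[1] == scheme.n_shells \
            and scheme.n_shells != scheme.n_measurements:
        return flat, None, vox_shape  # already spherical means
    if flat.shape[1] != scheme.n_measurements:
        raise ValueError("data and scheme measurement counts differ")
    if model.S0_responses is not None:
        return flat, None, vox_shape  # signal-based fit
    atten, s0 = normalize_attenuation(flat, scheme)
    if model.flavor == "MC-SM":
        return shell_means(atten, scheme), s0, vox_shape
    return atten, s0, vox_shape


def _build_grid(codec, Ns, orientation_grid, rng):
    axes = []
    for name, comp, lo, hi in codec.entries:
        if comp is not None:  # orientation component: handled jointly below
            continue
        axes.append((name, np.linspace(0, 1, Ns + 2)[1:-1]))
    mu_names = sorted({name for name, comp, *_ in codec.entries
                       if comp is not None})
    mu_grid = unit_vector_to_angles(hemisphere(orientation_grid))
    nested_axis = np.linspace(0, 1, Ns + 2)[1:-1]

    shapes = [len(v) for _, v in axes] + [orientation_grid] * len(mu_names) \
        + [len(nested_axis)] * codec.n_nested
    total = int(np.prod(shapes)) if shapes else 1
    mesh = np.meshgrid(*([v for _, v in axes]
                         + [np.arange(orientation_grid)] * len(mu_names)
                         + [nested_axis] * codec.n_nested),
                       indexing="ij")
    mesh = [m.ravel() for m in mesh] if mesh else []
    if total > GRID_BUDGET:
        warnings.warn(
            f"brute-force grid of {total} candidates exceeds the budget of "
            f"{GRID_BUDGET}; subsampling", stacklevel=2)
        keep = rng.choice(total, GRID_BUDGET, replace=False)
        mesh = [m[keep] for m in mesh]
        total = GRID_BUDGET

    # assemble scaled vectors
    x = np.empty((total, codec.n_dim))
    col = 0
    ax_i = 0
    for j, (name, comp, lo, hi) in enumerate(codec.entries):
        if comp is None:
            x[:, j] = mesh[ax_i]
            ax_i += 1
    for mu_name in mu_names:
        idx = mesh[ax_i].astype(int)
        ax_i += 1
        cols = [j for j, (n, comp, *_ ) in enumerate(codec.entries)
                if n == mu_name]
        for ci, j in enumerate(cols):
            lo, hi = codec.entries[j][2], codec.entries[j][3]
            x[:, j] = (mu_grid[idx, ci] - lo) / (hi - lo)
    for k in range(codec.n_nested):
        x[:, len(codec.entries) + k] = mesh[ax_i]
        ax_i += 1
    return x


def fit_brute2fine(model, scheme, data, Ns: int = DEFAULT_NS,
                   orientation_grid: int = DEFAULT_ORIENTATION_GRID,
                   seed: int = 0, **_):
    if model.flavor == "MC-SH":
        raise ValueError("brute2fine applies to MC and MC-SM models")
    y_all, s0, vox_shape = _target_data(model, scheme, data)
    codec = _Codec(model)
    rng = np.random.default_rng(seed)
    grid = _build_grid(codec, Ns, orientation_grid, rng)

    has_voxel_maps = any(
        e.status == "fixed" and np.ndim(e.value) > 0 and
        np.asarray(e.value).shape != ((e.cardinality,) if e.cardinality > 1
                                      else ())
        for e in model.registry.entries.values())

    n_out = y_all.shape[1]

    def predict(x, overrides):
        # parameter combinations violating a model's physical constraints
        # (e.g. lambda_perp > lambda_par) are treated as infinitely bad
        try:
            full = _resolve(model, codec.to_params(x), overrides)
            return model.evaluate(scheme, full)
        except ValueError:
            return np.full(n_out, np.inf)

    shared_pred = None
    if not has_voxel_maps:
        shared_pred = np.stack([predict(x, {}) for x in grid])

    per_voxel, mses, r2s = [], [], []
    for j, y in enumerate(y_all):
        overrides = _voxel_fixed_overrides(model, vox_shape, j) \
            if has_voxel_maps else {}
        if shared_pred is not None:
            with np.errstate(invalid="ignore"):
                sse = np.nansum((shared_pred - y) ** 2, axis=1)
                sse[~np.isfinite(shared_pred).all(axis=1)] = np.inf
        else:
            sse = np.array([((predict(x, overrides) - y) ** 2).sum()
                            for x in grid])
        x0 = grid[int(np.argmin(sse))]

        def objective(x):
            pred = predict(x, overrides)
            if not np.all(np.isfinite(pred)):
                return 1e10
            return float(((pred - y) ** 2).sum())

        if codec.n_dim:
            res = minimize(objective, x0, method="L-BFGS-B",
                           bounds=[(0.0, 1.0)] * codec.n_dim,
                           options=LBFGSB_OPTIONS)
            x_best = res.x if res.fun <= objective(x0) else x0
        else:
            x_best = x0
        params = codec.to_params(x_best)
        yhat = predict(x_best, overrides)
        mse, r2 = _gof(y, yhat)
        per_voxel.append(params)
        mses.append(mse)
        r2s.append(r2)
    return _pack_results(model, scheme, vox_shape, per_voxel, mses, r2s,
                         "brute2fine", S0=None if s0 is None
                         else s0.reshape(vox_shape))


# ---------------------------------------------------------------------------
# MIX

def _linear_blocks(model, scheme, full_wo_fractions):
    """Per-model predictions (columns of the linear sub-problem)."""
    kwargs = model.registry.scatter(full_wo_fractions)
    s0 = model.S0_responses or [1.0] * len(model.models)
    cols = []
    for amp, (_, sub), kw in zip(s0, model.registry.sub_models, kwargs):
        if model.flavor == "MC":
            cols.append(amp * sub.attenuation(scheme, **kw))
        else:
            kw = {k: v for k, v in kw.items()
                  if k != sub.orientation_parameter}
            cols.append(amp * sub.spherical_mean(scheme, **kw))
    return np.column_stack(cols)


def fit_mix(model, scheme, data, seed: int = 0, de_maxiter: int = 60,
            de_popsize: int = 15, **_):
    if model.flavor == "MC-SH":
        raise ValueError("MIX applies to MC and MC-SM models")
    # MIX relies on fractions entering linearly
    for n, e in model.registry.entries.items():
        if e.status == "linked" and e.link[0] == "tortuous" and \
                e.link[2].startswith("partial_volume"):
            raise ValueError(
                "MIX requires linear volume fractions; a tortuosity link on "
                "a fraction makes them non-linear — use brute2fine")
    y_all, s0, vox_shape = _target_data(model, scheme, data)
    codec = _Codec(model)
    nonlin_dim = len(codec.entries)
    n_models = len(model.models)

    def blocks_for(x_nonlin, overrides):
        params = codec.to_params(
            np.concatenate([x_nonlin, np.full(codec.n_nested, 0.5)]))
        for n in codec.fraction_names:
            params.pop(n, None)
        full = _resolve(model, {**params,
                                **{n: 1.0 / n_models
                                   for n in codec.fraction_names}},
                        overrides)
        return _linear_blocks(model, scheme, full)

    per_voxel, mses, r2s, flags = [], [], [], []
    for j, y in enumerate(y_all):
        overrides = _voxel_fixed_overrides(model, vox_shape, j)

        def stage1_obj(x_nonlin):
            try:
                phi = blocks_for(x_nonlin, overrides)
            except ValueError:
                return 1e10
            w, rnorm = nnls(phi, y)
            return rnorm ** 2

        if nonlin_dim > 0:
            de = differential_evolution(
                stage1_obj, bounds=[(0.0, 1.0)] * nonlin_dim,
                seed=seed + j, maxiter=de_maxiter, popsize=de_popsize,
                recombination=0.7, mutation=(0.5, 1.0), strategy="rand1bin",
                tol=1e-10, polish=False)
            x_nonlin, converged = de.x, de.success
        else:
            x_nonlin, converged = np.empty(0), True
        phi = blocks_for(x_nonlin, overrides)
        w, _ = nnls(phi, y)
        total = w.sum()
        fr = w / total if total > 0 else np.full(n_models, 1.0 / n_models)

        if codec.n_nested or nonlin_dim:
            x0 = np.concatenate([
                x_nonlin,
                fractions_to_nested(fr)[:codec.n_nested]
                if codec.n_nested else np.empty(0)])

            def objective(x):
                try:
                    full = _resolve(model, codec.to_params(x), overrides)
                    pred = model.evaluate(scheme, full)
                except ValueError:
                    return 1e10
                return float(((pred - y) ** 2).sum())

            res = minimize(objective, x0, method="L-BFGS-B",
                           bounds=[(0.0, 1.0)] * codec.n_dim,
                           options=LBFGSB_OPTIONS)
            x_best = res.x if res.fun <= objective(x0) else x0
            params = codec.to_params(x_best)
            full = _resolve(model, params, overrides)
            yhat = model.evaluate(scheme, full)
        else:
            params = {}
            yhat = phi @ w
        for name, f in zip(codec.fraction_names, fr):
            params.setdefault(name, float(f))
        mse, r2 = _gof(y, yhat)
        per_voxel.append(params)
        mses.append(mse)
        r2s.append(r2)
        flags.append(not converged)
    return _pack_results(model, scheme, vox_shape, per_voxel, mses, r2s,
                         "mix", S0=None if s0 is None
                         else s0.reshape(vox_shape), flags=flags)


# ---------------------------------------------------------------------------
# MC-SH fitting

def _csd_setup(model, scheme, data):
    if model.flavor != "MC-SH":
        raise ValueError("CSD optimizers require an MC-SH model")
    flat, vox_shape = _voxelize(data)
    if model.S0_responses is None:
        y_all, s0 = normalize_attenuation(flat, scheme)
    else:
        y_all, s0 = flat, None
    # kernel parameters must be fixed or resolvable; sh_coeff and isotropic
    # fractions are solved by the convex optimizer
    solved = {"sh_coeff"} | {f"partial_volume_{i}"
                             for i in model._iso_indices()}
    unresolved = [n for n in model.free_parameter_names if n not in solved]
    return y_all, s0, vox_shape, unresolved


def _kernel_full_params(model, unresolved, overrides, j, vox_shape):
    """Resolve kernel parameters for voxel j (cascaded maps supported)."""
    values = dict(overrides)
    missing = [n for n in unresolved if n not in values]
    if missing:
        raise ValueError(
            f"MC-SH kernel parameters must be fixed before fitting: {missing}")
    placeholder = {"sh_coeff": np.zeros(
        model.registry.cardinality("sh_coeff"))}
    for i in model._iso_indices():
        placeholder[f"partial_volume_{i}"] = 0.0
    return model.registry.resolve({**values, **placeholder})


def _constraint_grid(order):
    grid = symmetric_sphere(362)[:362]  # hemisphere of the symmetric set
    return real_sh_basis(order, grid)


def fit_csd_tournier(model, scheme, data, reg_weight: float = 1.0,
                     n_iter: int = 50, **_):
    y_all, s0, vox_shape, unresolved = _csd_setup(model, scheme, data)
    free_iso = [i for i in model._iso_indices()
                if model.registry.entries[f"partial_volume_{i}"].status
                == "free"]
    if free_iso:
        raise ValueError(
            "the Tournier07 scheme cannot handle multiple kernels unless "
            "their volume fractions are fixed")
    n_coef = model.registry.cardinality("sh_coeff")
    b_grid = _constraint_grid(model.sh_order)

    per_voxel, mses, r2s = [], [], []
    for j, y in enumerate(y_all):
        overrides = _voxel_fixed_overrides(model, vox_shape, j)
        full = _kernel_full_params(model, unresolved, overrides, j, vox_shape)
        design = model.csd_design_matrix(scheme, full)
        a = design[:, :n_coef]
        iso_order = model._iso_indices()
        iso_part = 0.0
        for k in range(n_coef, design.shape[1]):
            i = iso_order[k - n_coef]
            iso_part = iso_part + design[:, k] * float(
                model.registry.entries[f"partial_volume_{i}"].value)
        y_eff = y - iso_part
        lam = reg_weight * np.linalg.norm(a) / max(
            np.linalg.norm(b_grid) / np.sqrt(b_grid.shape[0]), 1e-12) / \
            np.sqrt(a.shape[0])
        ata = a.T @ a
        aty = a.T @ y_eff
        c = np.linalg.solve(ata + 1e-8 * np.trace(ata) / n_coef *
                            np.eye(n_coef), aty)
        for _i in range(n_iter):
            fod = b_grid @ c
            thresh = 0.1 * max(fod.mean(), 0.0)
            neg = fod < thresh
            l_rows = b_grid[neg]
            lhs = ata + lam ** 2 * (l_rows.T @ l_rows)
            c_new = np.linalg.solve(lhs, aty)
            if np.allclose(c_new, c, rtol=1e-8, atol=1e-12):
                c = c_new
                break
            c = c_new
        params = {"sh_coeff": c}
        yhat = a @ c + iso_part
        mse, r2 = _gof(y, yhat)
        per_voxel.append(params)
        mses.append(mse)
        r2s.append(r2)
    return _pack_results(model, scheme, vox_shape, per_voxel, mses, r2s,
                         "csd_tournier", S0=None if s0 is None
                         else s0.reshape(vox_shape))


def _solve_qp(design, y, n_coef, b_grid, unity=False, x0=None,
              max_iter=1500, tol=1e-7):
    """min ||design x - y||^2 s.t. b_grid x_sh >= 0, x_iso >= 0
    (and optionally sqrt(4 pi) c00 + sum x_iso = 1).

    Solved by ADMM on the inequality cone (robust to the rank-deficient
    designs that single-shell problems produce) with an active-set
    Newton polish for high-precision solutions.
    """
    from scipy.linalg import cho_factor, cho_solve

    n_total = design.shape[1]
    n_iso = n_total - n_coef
    g_rows = np.zeros((b_grid.shape[0] + n_iso, n_total))
    g_rows[:b_grid.shape[0], :n_coef] = b_grid
    for i in range(n_iso):
        g_rows[b_grid.shape[0] + i, n_coef + i] = 1.0
    u_eq = None
    if unity:
        u_eq = np.zeros(n_total)
        u_eq[0] = np.sqrt(4 * np.pi)
        u_eq[n_coef:] = 1.0

    p_mat = design.T @ design
    q_vec = design.T @ y
    gtg = g_rows.T @ g_rows
    ridge = 1e-12 * max(np.trace(p_mat), 1e-30) / n_total * np.eye(n_total)
    rho = 10.0 * max(np.trace(p_mat), 1e-12) / max(np.trace(gtg), 1e-12)

    def factorize(rho_):
        f = cho_factor(p_mat + rho_ * gtg + ridge)
        mu = cho_solve(f, u_eq) if u_eq is not None else None
        return f, mu

    factor, minv_u = factorize(rho)

    def x_step(rhs):
        minv_rhs = cho_solve(factor, rhs)
        if u_eq is None:
            return minv_rhs
        nu = (u_eq @ minv_rhs - 1.0) / (u_eq @ minv_u)
        return minv_rhs - nu * minv_u

    x = np.zeros(n_total) if x0 is None else np.asarray(x0, dtype=float)
    z = np.clip(g_rows @ x, 0.0, None)
    dual = g_rows @ x - z
    converged = False
    for it in range(max_iter):
        x = x_step(q_vec + rho * g_rows.T @ (z - dual))
        gx = g_rows @ x
        z_new = np.clip(gx + dual, 0.0, None)
        dual = dual + gx - z_new
        prim_res = np.linalg.norm(gx - z_new)
        dual_res = rho * np.linalg.norm(g_rows.T @ (z_new - z))
        z = z_new
        scale = max(1.0, np.linalg.norm(z))
        if prim_res < tol * scale and gx.min() > -1e-9 * scale and \
                dual_res < 100 * tol * max(1.0, np.linalg.norm(q_vec)):
            converged = True
            break
        # residual balancing keeps the splitting well conditioned
        if it % 50 == 49:
            if prim_res > 10 * dual_res:
                rho *= 2.0
                dual /= 2.0
                factor, minv_u = factorize(rho)
            elif dual_res > 10 * prim_res:
                rho /= 2.0
                dual *= 2.0
                factor, minv_u = factorize(rho)
    # strict-feasibility projection: a c00 bump raises the FOD uniformly
    # (and tiny isotropic negatives are clipped); the objective change is
    # of the order of the residual infeasibility, i.e. negligible
    gx = g_rows @ x
    viol = float(gx.min())
    if -1e-4 < viol < 0:
        fod_viol = float((b_grid @ x[:n_coef]).min())
        if fod_viol < 0:
            x[0] += (-fod_viol) * np.sqrt(4 * np.pi) * (1 + 1e-9)
        x[n_coef:] = np.clip(x[n_coef:], 0.0, None)
        if unity:
            x = x / (u_eq @ x)
        if np.linalg.norm(g_rows @ x - np.clip(g_rows @ x, 0, None)) == 0 \
                and prim_res < 1e-5 * max(1.0, np.linalg.norm(z)):
            converged = True

    # active-set polish: equality-constrained exact solves, augmenting the
    # active set until the returned point is feasible to ~1e-9
    active = (g_rows @ x) < 1e-7 * max(1.0, float(np.abs(g_rows @ x).max()))
    best_x, best_obj = x, np.linalg.norm(design @ x - y)
    for _ in range(8):
        a_rows = g_rows[active]
        if u_eq is not None:
            a_rows = np.vstack([a_rows, u_eq])
        if not len(a_rows):
            x_pol = np.linalg.lstsq(design, y)[0]
        else:
            kkt = np.block([
                [2 * p_mat, a_rows.T],
                [a_rows, np.zeros((len(a_rows), len(a_rows)))]])
            rhs = np.concatenate([2 * q_vec, np.zeros(len(a_rows))])
            if unity:
                rhs[-1] = 1.0  # u_eq is the last active row
            try:
                x_pol = np.linalg.lstsq(kkt, rhs)[0][:n_total]
            except np.linalg.LinAlgError:
                break
        violations = g_rows @ x_pol
        if violations.min() >= -1e-9:
            obj = np.linalg.norm(design @ x_pol - y)
            if obj <= best_obj + 1e-12:
                best_x, best_obj = x_pol, obj
                converged = True
            break
        new_active = active | (violations < -1e-12)
        if new_active.sum() == active.sum():
            break
        active = new_active
    return best_x, converged


def fit_csd_constrained(model, scheme, data, unity_constraint=None, **_):
    """Hard-constrained CSD: FOD >= 0 on a dense grid, isotropic fractions
    >= 0, optional unity constraint (default on, except when tissue S0
    responses are given)."""
    if unity_constraint is None:
        unity_constraint = model.S0_responses is None
    y_all, s0, vox_shape, unresolved = _csd_setup(model, scheme, data)
    n_coef = model.registry.cardinality("sh_coeff")
    b_grid = _constraint_grid(model.sh_order)
    free_iso = [i for i in model._iso_indices()
                if model.registry.entries[f"partial_volume_{i}"].status
                == "free"]

    per_voxel, mses, r2s, flags = [], [], [], []
    for j, y in enumerate(y_all):
        overrides = _voxel_fixed_overrides(model, vox_shape, j)
        full = _kernel_full_params(model, unresolved, overrides, j, vox_shape)
        design_all = model.csd_design_matrix(scheme, full)
        # columns: sh block, then isotropic fractions in _iso_indices order
        iso_order = model._iso_indices()
        free_cols = list(range(n_coef)) + \
            [n_coef + iso_order.index(i) for i in free_iso]
        fixed_cols = [k for k in range(design_all.shape[1])
                      if k not in free_cols]
        y_eff = y.astype(float)
        for k in fixed_cols:
            i = iso_order[k - n_coef]
            y_eff = y_eff - design_all[:, k] * float(
                model.registry.entries[f"partial_volume_{i}"].value)
        design = design_all[:, free_cols]
        x, ok = _solve_qp(design, y_eff, n_coef, b_grid,
                          unity=unity_constraint)
        params = {"sh_coeff": x[:n_coef]}
        for pos, i in enumerate(free_iso):
            params[f"partial_volume_{i}"] = float(x[n_coef + pos])
        yhat = design @ x + (y - y_eff)
        mse, r2 = _gof(y, yhat)
        per_voxel.append(params)
        mses.append(mse)
        r2s.append(r2)
        flags.append(not ok)
    return _pack_results(model, scheme, vox_shape, per_voxel, mses, r2s,
                         "csd", S0=None if s0 is None
                         else s0.reshape(vox_shape), flags=flags)


# ---------------------------------------------------------------------------
# secondary multi-tissue fraction correction

def multi_tissue_fit(model, scheme, data, fitted_nonlinear_params=None,
                     fitted_results=None):
    """Re-fit volume fractions against the raw signal with S0-weighted
    compartments (non-negative least squares per voxel); returns normalized
    volume fractions of shape (voxels..., n_models)."""
    if model.S0_responses is None:
        raise ValueError("multi-tissue fitting requires S0 responses")
    flat, vox_shape = _voxelize(data)
    n_vox = len(flat)
    n_models = len(model.models)

    def full_for(j):
        if fitted_results is not None:
            return fitted_results._full_params_flat(j)
        values = {}
        for name, v in (fitted_nonlinear_params or {}).items():
            card = model.registry.cardinality(name)
            tail = (card,) if card > 1 else ()
            arr = np.asarray(v, dtype=float)
            if arr.shape == tail:
                values[name] = arr if card > 1 else float(arr)
            else:
                values[name] = arr.reshape((n_vox,) + tail)[j]
        for i in range(n_models):
            values.setdefault(f"partial_volume_{i}", 1.0 / n_models)
        overrides = _voxel_fixed_overrides(model, vox_shape, j)
        return _resolve(model, values, overrides)

    fractions = np.zeros((n_vox, n_models))
    for j in range(n_vox):
        full = full_for(j)
        kwargs = model.registry.scatter(full)
        cols = []
        for s0_i, (_, sub), kw in zip(model.S0_responses,
                                      model.registry.sub_models, kwargs):
            cols.append(s0_i * sub.attenuation(scheme, **kw))
        b = np.column_stack(cols)
        w, _ = nnls(b, flat[j])
        total = w.sum()
        fractions[j] = w / total if total > 0 else 0.0
    return fractions.reshape(vox_shape + (n_models,))


# ---------------------------------------------------------------------------
# SS3T: single-shell 3-tissue alternating schedule

def fit_ss3t(model, scheme, data, n_iterations: int = 4, **_):
    """Alternating partial convex fits on single-shell + b0 signal data.

    The model must combine two isotropic responses and one anisotropic
    response with S0 responses set. Schedule: fix f_WM = 0 and fit the
    isotropic fractions; then alternately (a) fix f_CSF and fit the FOD and
    f_GM under the non-negativity constraints, (b) fix the FOD and re-fit
    both isotropic fractions; repeated for the fixed iteration count.
    """
    if model.flavor != "MC-SH" or model.S0_responses is None:
        raise ValueError("SS3T requires an MC-SH model with S0 responses")
    iso_idx = model._iso_indices()
    if len(iso_idx) != 2 or len(model._aniso_idx) != 1:
        raise ValueError("SS3T expects exactly 2 isotropic responses and 1 "
                         "anisotropic response")
    nonzero = [s for s in scheme.shells if not s.is_b0]
    if len(nonzero) != 1:
        raise ValueError("SS3T requires exactly one non-zero shell plus b0")

    flat, vox_shape = _voxelize(data)
    y_all = flat
    n_coef = model.registry.cardinality("sh_coeff")
    b_grid = _constraint_grid(model.sh_order)
    solved = {"sh_coeff"} | {f"partial_volume_{i}" for i in iso_idx}
    unresolved = [n for n in model.free_parameter_names if n not in solved]

    # canonical column order: [sh_coeff, iso fractions in iso_idx order]
    per_voxel, mses, r2s, flags = [], [], [], []
    for j, y in enumerate(y_all):
        overrides = _voxel_fixed_overrides(model, vox_shape, j)
        full = _kernel_full_params(model, unresolved, overrides, j, vox_shape)
        design = model.csd_design_matrix(scheme, full)
        a_sh = design[:, :n_coef]
        col_gm = design[:, n_coef + 0]
        col_csf = design[:, n_coef + 1]

        # init: f_WM = 0, fit isotropic fractions only
        w, _ = nnls(np.column_stack([col_gm, col_csf]), y)
        f_gm, f_csf = float(w[0]), float(w[1])
        c = np.zeros(n_coef)
        ok = True
        for _i in range(n_iterations):
            # (a) fix f_CSF: fit FOD (non-negative) and f_GM (>= 0)
            design_a = np.column_stack([a_sh, col_gm])
            x0 = np.append(c, f_gm)
            x, ok_a = _solve_qp(design_a, y - f_csf * col_csf, n_coef,
                                b_grid, unity=False, x0=x0)
            c, f_gm = x[:n_coef], float(x[n_coef])
            # (b) fix the FOD: re-fit both isotropic fractions
            w, _ = nnls(np.column_stack([col_gm, col_csf]), y - a_sh @ c)
            f_gm, f_csf = float(w[0]), float(w[1])
            ok = ok and ok_a
        params = {"sh_coeff": c,
                  f"partial_volume_{iso_idx[0]}": f_gm,
                  f"partial_volume_{iso_idx[1]}": f_csf}
        yhat = a_sh @ c + f_gm * col_gm + f_csf * col_csf
        mse, r2 = _gof(y, yhat)
        per_voxel.append(params)
        mses.append(mse)
        r2s.append(r2)
        flags.append(not ok)
    return _pack_results(model, scheme, vox_shape, per_voxel, mses, r2s,
                         "ss3t", flags=flags)


# ---------------------------------------------------------------------------
# dispatcher

_METHODS = {
    "brute2fine": fit_brute2fine,
    "mix": fit_mix,
    "csd": fit_csd_constrained,
    "csd_tournier": fit_csd_tournier,
    "ss3t": fit_ss3t,
}


def fit(model, scheme, data, method: str | None = None, **options):
    """Fit a multi-compartment model; see the module docstring for methods."""
    if method is None:
        method = "csd" if model.flavor == "MC-SH" else "brute2fine"
    if method not in _METHODS:
        raise ValueError(f"unknown optimizer {method!r}; "
                         f"choose from {sorted(_METHODS)}")
    return _METHODS[method](model, scheme, data, **options)
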