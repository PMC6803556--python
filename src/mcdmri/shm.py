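"""Real spherical-harmonics machinery.

Everything here works in the real, antipodally symmetric (even-degree) SH
basis with descoteaux-style (l, m) ordering, m running from -l to l. The
basis convention is recorded in ``SH_BASIS_CONVENTION`` so a dialect swap
stays a one-line change. Key facts used throughout:

* c_00 * sqrt(4 pi) is the spherical mean of the expanded function;
* an axially symmetric function has only m = 0 ("rotational harmonics")
  coefficients in its aligned frame, one set r_l per acquisition shell;
* spherical convolution of an FOD with a z-aligned kernel multiplies
  coefficients degree-wise by sqrt(4 pi / (2l + 1)) * r_l (Funk-Hecke).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

SH_BASIS_CONVENTION = "real-symmetric-descoteaux"

__all__ = [
    "n_coefficients",
    "sh_degrees",
    "real_sh_basis",
    "sh_fit",
    "sh_eval",
    "rotational_harmonics_transform",
    "sh_convolve",
    "kernel_sh_coefficients",
    "convolution_scaling",
    "gauss_legendre_sphere",
    "sh_fit_matrix",
]


def n_coefficients(order: int) -> int:
    """Number of real even-degree SH coefficients up to ``order``."""
    _check_order(order)
    return (order + 1) * (order + 2) // 2


def _check_order(order: int):
    if order < 0 or order % 2:
        raise ValueError("sh order must be even and non-negative")


@lru_cache(maxsize=32)
def sh_degrees(order: int):
    """(l, m) pairs of the basis, as two integer arrays."""
    _check_order(order)
    ls, ms = [], []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def _cart_to_polar(directions):
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    return theta, phi


def real_sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real symmetric SH basis at unit ``directions``."""
    theta, phi = _cart_to_polar(directions)
    ls, ms = sh_degrees(order)
    out = np.empty((len(theta), len(ls)))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            out[:, j] = np.sqrt(2.0) * y.imag
        elif m == 0:
            out[:, j] = y.real
        else:
            out[:, j] = np.sqrt(2.0) * y.real
    return out


def sh_fit(samples: np.ndarray, directions: np.ndarray, order: int) -> np.ndarray:
    """Least-squares SH coefficients of samples given on sphere directions."""
    basis = real_sh_basis(order, directions)
    coef, *_ = np.linalg.lstsq(basis, np.asarray(samples, dtype=float))
    return coef


def sh_eval(coefficients: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Evaluate an SH expansion; order inferred from the coefficient count."""
    coefficients = np.asarray(coefficients, dtype=float)
    order = order_from_ncoef(coefficients.shape[-1])
    basis = real_sh_basis(order, directions)
    return basis @ coefficients


def order_from_ncoef(ncoef: int) -> int:
    order = int(round((np.sqrt(8 * ncoef + 1) - 3) / 2))
    if n_coefficients(order) != ncoef:
        raise ValueError(f"{ncoef} is not a valid even-basis coefficient count")
    return order


# ---------------------------------------------------------------------------
# quadrature caches

@lru_cache(maxsize=8)
def _gauss_legendre(n_nodes: int = 64):
    """Nodes/weights for integrating over u = cos(theta) in [-1, 1]."""
    u, w = np.polynomial.legendre.leggauss(n_nodes)
    theta = np.arccos(u)
    return u, w, theta


@lru_cache(maxsize=32)
def _y_l0_at_nodes(order: int, n_nodes: int = 64):
    _, _, theta = _gauss_legendre(n_nodes)
    ls = np.arange(0, order + 1, 2)
    return np.stack(
        [sph_harm_y(l, 0, theta, 0.0).real for l in ls])  # (n_l, n_nodes)


@lru_cache(maxsize=8)
def gauss_legendre_sphere(n_polar: int = 48, n_azimuth: int = 96):
    """Product quadrature (directions, weights) exact for high-degree
    spherical polynomials; used as the brute-force convolution oracle grid."""
    u, wu, theta = _gauss_legendre(n_polar)
    phi = 2 * np.pi * np.arange(n_azimuth) / n_azimuth
    wphi = 2 * np.pi / n_azimuth
    st = np.sin(theta)
    dirs = np.stack(
        [np.outer(st, np.cos(phi)), np.outer(st, np.sin(phi)),
         np.outer(u, np.ones_like(phi))], axis=-1).reshape(-1, 3)
    weights = (wu[:, None] * wphi * np.ones_like(phi)).ravel()
    return dirs, weights


# ---------------------------------------------------------------------------
# rotational harmonics and spherical convolution

def rotational_harmonics_transform(kernel_sampler, shells, order: int,
                                   n_nodes: int = 64) -> np.ndarray:
    """Per-shell m = 0 coefficients r_{s,l} of a z-aligned axisymmetric kernel.

    ``kernel_sampler(shell, directions)`` must return the kernel values at
    unit directions for that shell. Integration is Gauss-Legendre in
    cos(theta), exact for band-limited kernels:

        r_{s,l} = 2 pi * integral_{-1}^{1} K_s(theta) Y_l0(theta) du.
    """
    _check_order(order)
    u, w, theta = _gauss_legendre(n_nodes)
    dirs = np.column_stack(
        [np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    y_l0 = _y_l0_at_nodes(order, n_nodes)
    out = np.empty((len(shells), y_l0.shape[0]))
    for s, shell in enumerate(shells):
        vals = np.asarray(kernel_sampler(shell, dirs), dtype=float)
        out[s] = 2 * np.pi * (y_l0 * (w * vals)) .sum(axis=1)
    return out


def convolution_scaling(order: int) -> np.ndarray:
    """Funk-Hecke degree-wise factor sqrt(4 pi / (2l + 1)), one per (l, m)."""
    ls, _ = sh_degrees(order)
    return np.sqrt(4 * np.pi / (2 * ls + 1))


def sh_convolve(fod_coefficients: np.ndarray,
                kernel_rh: np.ndarray) -> np.ndarray:
    """Spherical convolution in SH space, shell by shell.

    Parameters
    ----------
    fod_coefficients : (n_coef,) FOD in the full real symmetric basis.
    kernel_rh : (n_shells, n_l) per-shell rotational harmonics r_{s,l}.

    Returns
    -------
    (n_shells, n_coef) SH coefficients of the predicted signal per shell.
    """
    fod_coefficients = np.asarray(fod_coefficients, dtype=float)
    kernel_rh = np.atleast_2d(np.asarray(kernel_rh, dtype=float))
    order = order_from_ncoef(len(fod_coefficients))
    ls, _ = sh_degrees(order)
    n_l_needed = order // 2 + 1
    if kernel_rh.shape[1] < n_l_needed:
        pad = np.zeros((kernel_rh.shape[0], n_l_needed - kernel_rh.shape[1]))
        kernel_rh = np.hstack([kernel_rh, pad])
    scale = convolution_scaling(order)
    return scale * kernel_rh[:, ls // 2] * fod_coefficients


def kernel_sh_coefficients(rh_per_shell: np.ndarray, mu_vector: np.ndarray,
                           order: int) -> np.ndarray:
    """Full-basis SH coefficients of an axisymmetric function oriented along
    ``mu_vector``, from its z-aligned rotational harmonics (addition theorem):

        c_{lm} = sqrt(4 pi / (2l + 1)) * r_l * Y_lm(mu).
    """
    basis_mu = real_sh_basis(order, np.asarray(mu_vector, float)[None, :])[0]
    ls, _ = sh_degrees(order)
    rh = np.asarray(rh_per_shell, dtype=float)
    return convolution_scaling(order) * rh[..., ls // 2] * basis_mu


def scheme_sh_basis(scheme, order: int) -> np.ndarray:
    """SH design matrix at a scheme's directions, memoized on the scheme."""
    cache = getattr(scheme, "_sh_basis_cache", None)
    if cache is None:
        try:
            cache = scheme._sh_basis_cache = {}
        except AttributeError:  # plain probe tables: no caching
            return real_sh_basis(order, scheme.directions)
    if order not in cache:
        cache[order] = real_sh_basis(order, scheme.directions)
    return cache[order]


# cached pseudo-inverse for density fitting on the standard dense grid
@lru_cache(maxsize=16)
def sh_fit_matrix(order: int, grid_key: str = "icosphere4"):
    from .sphere import icosphere

    if grid_key != "icosphere4":
        raise ValueError("unknown grid key")
    grid = icosphere(4)
    basis = real_sh_basis(order, grid)
    return np.linalg.pinv(basis), grid
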