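"""Parametric distributions: Gamma (scalar parameters), Watson and Bingham
(orientations on the sphere).

The Watson/Bingham concentration is exposed through the orientation
dispersion index ODI = (2/pi) * arctan(1/kappa) (NODDI convention): ODI -> 0
is a spike along mu, ODI = 1 is the uniform density 1/(4 pi). The Bingham
adds a secondary dispersion fraction ``beta`` in [0, 1] (kappa_2 = beta *
kappa_1 <= kappa_1) and a roll angle psi about mu.

Watson normalization uses the exact confluent hypergeometric constant
4 pi M(1/2, 3/2, kappa); the Bingham constant has no such closed form in
scipy and is integrated numerically on a product Gauss grid (accurate to
~1e-8 for the ODI range of interest).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import hyp1f1, sph_harm_y
from scipy.stats import gamma as _gamma_dist

from .sphere import angles_to_unit_vector
from .shm import _gauss_legendre

__all__ = [
    "kappa_to_odi",
    "odi_to_kappa",
    "watson_density",
    "watson_rotational_harmonics",
    "bingham_density",
    "gamma_density",
]


def kappa_to_odi(kappa):
    """ODI = (2/pi) arctan(1/kappa); strictly decreasing bijection."""
    return (2.0 / np.pi) * np.arctan2(1.0, kappa)


def odi_to_kappa(odi):
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi > 1):
        raise ValueError("odi must lie in (0, 1]")
    out = 1.0 / np.tan(np.pi / 2.0 * odi)
    return float(out) if out.ndim == 0 else out


def _watson_norm(kappa: float) -> float:
    # integral of exp(kappa (mu.n)^2) over the sphere
    return 4 * np.pi * hyp1f1(0.5, 1.5, kappa)


def _resolve_mu(mu):
    mu = np.asarray(mu, dtype=float)
    if mu.shape == (2,):
        return angles_to_unit_vector(mu)
    if mu.shape == (3,):
        return mu / np.linalg.norm(mu)
    raise ValueError("mu must be (theta, phi) or a 3-vector")


def watson_density(directions, mu, odi):
    """Watson density W(n) = exp(kappa (mu.n)^2) / Z, integrating to 1."""
    kappa = odi_to_kappa(odi)
    muv = _resolve_mu(mu)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    return np.exp(kappa * (directions @ muv) ** 2) / _watson_norm(kappa)


@lru_cache(maxsize=256)
def _watson_rh_cached(kappa: float, order: int, n_nodes: int) -> tuple:
    u, w, theta = _gauss_legendre(n_nodes)
    dens = np.exp(kappa * u ** 2) / _watson_norm(kappa)
    ls = np.arange(0, order + 1, 2)
    y = np.stack([sph_harm_y(l, 0, theta, 0.0).real for l in ls])
    return tuple(2 * np.pi * (y * (w * dens)).sum(axis=1))


def watson_rotational_harmonics(odi, order, n_nodes: int = 128) -> np.ndarray:
    """m = 0 SH coefficients of the z-aligned Watson density (exact 1-D
    quadrature; the density is axially symmetric)."""
    kappa = float(odi_to_kappa(odi))
    return np.array(_watson_rh_cached(round(kappa, 12), order, n_nodes))


def _bingham_axes(mu, psi):
    """Primary axis mu and secondary axis (perpendicular, rolled by psi)."""
    muv = _resolve_mu(mu)
    # reference perpendicular frame
    helper = np.array([0.0, 0.0, 1.0])
    if abs(muv[2]) > 0.999999:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(muv, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(muv, e1)
    mu2 = np.cos(psi) * e1 + np.sin(psi) * e2
    return muv, mu2


@lru_cache(maxsize=256)
def _bingham_norm(kappa1: float, kappa2: float, n_polar: int = 128,
                  n_azimuth: int = 256) -> float:
    # Z = int exp(kappa1 cos^2 th + kappa2 sin^2 th cos^2 ph) dOmega
    u, w, _ = _gauss_legendre(n_polar)
    phi = 2 * np.pi * np.arange(n_azimuth) / n_azimuth
    arg = kappa1 * u[:, None] ** 2 + kappa2 * (1 - u[:, None] ** 2) * \
        np.cos(phi)[None, :] ** 2
    return float((w @ np.exp(arg)).sum() * 2 * np.pi / n_azimuth)


def bingham_density(directions, mu, psi, odi, beta):
    """Bingham density B(n) = exp(k1 (mu.n)^2 + k2 (mu2.n)^2) / Z with
    k1 from ODI as in the Watson and k2 = beta * k1 (beta in [0, 1])."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1] (kappa_2 <= kappa_1)")
    kappa1 = float(odi_to_kappa(odi))
    kappa2 = beta * kappa1
    muv, mu2 = _bingham_axes(mu, psi)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    arg = kappa1 * (directions @ muv) ** 2 + kappa2 * (directions @ mu2) ** 2
    return np.exp(arg) / _bingham_norm(round(kappa1, 12), round(kappa2, 12))


def gamma_density(xi, alpha, beta):
    """Gamma pdf with shape alpha and scale beta over xi > 0."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma shape and scale must be positive")
    return _gamma_dist.pdf(np.asarray(xi, dtype=float), a=alpha, scale=beta)
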