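"""Non-parametric tissue response models estimated from segmented voxels.

A tissue response captures the *measured* per-shell signal shape of one
tissue type (white matter, gray matter, CSF, ...) plus its non-weighted
amplitude S0, without assuming a biophysical model. Each selected voxel's
signal is expressed in per-shell rotational harmonics (m = 0 SH
coefficients); coefficients are averaged across voxels on the raw signal,
and the mean b0 intensity is carried separately as S0, so the response
separates shape (attenuation kernel) from amplitude (for multi-tissue
fitting).

The isotropic response (TR1) keeps only l = 0; the anisotropic response
(TR2) first rotates each voxel's gradient directions so that the voxel's
principal diffusion direction (log-linear tensor fit) points along z, making
the averaged kernel z-aligned with a free orientation ``mu`` at use time.

``select_three_tissue_voxels`` is a documented heuristic stand-in for
unsupervised three-tissue segmentation: it ranks voxels by tensor FA, mean
diffusivity and b0 intensity to pick white-matter (high FA), CSF (fast
decay, bright b0) and gray-matter (low FA, moderate decay) candidates. It is
validated on phantoms only.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import sph_harm_y

from .acquisition import AcquisitionScheme
from .compartments import MU_BOUNDS, CompartmentModel

logger = logging.getLogger(__name__)

__all__ = [
    "TR1IsotropicResponse",
    "TR2AnisotropicResponse",
    "estimate_isotropic_response",
    "estimate_anisotropic_response",
    "select_three_tissue_voxels",
    "dti_fit",
]


# ---------------------------------------------------------------------------
# DTI helper (log-linear least squares)

DTI_MAX_B = 1.5e9  # tensor fits use the standard DTI regime [s/m^2]


def dti_fit(data, scheme: AcquisitionScheme, max_b: float | None = DTI_MAX_B):
    """Per-voxel log-linear diffusion-tensor fit.

    Restricted to measurements with b <= max_b (the mono-exponential DTI
    regime; high-b data sit on the noise floor and bias the tensor) whenever
    diffusion-weighted shells remain below that cut. Returns
    (tensors (..., 3, 3), fa (...), md (...), s0 (...)).
    """
    data = np.asarray(data, dtype=float)
    if max_b is not None:
        keep = scheme.bvalues <= max_b
        if keep.any() and (scheme.bvalues[keep] > 10e6).any() \
                and not keep.all():
            scheme = scheme.subset(keep)
            data = data[..., keep]
    n = scheme.directions
    design = np.column_stack([
        np.ones(len(n)),
        -scheme.bvalues * n[:, 0] ** 2,
        -scheme.bvalues * n[:, 1] ** 2,
        -scheme.bvalues * n[:, 2] ** 2,
        -2 * scheme.bvalues * n[:, 0] * n[:, 1],
        -2 * scheme.bvalues * n[:, 0] * n[:, 2],
        -2 * scheme.bvalues * n[:, 1] * n[:, 2],
    ])
    flat = data.reshape(-1, data.shape[-1])
    log_s = np.log(np.clip(flat, 1e-10, None))
    coef, *_ = np.linalg.lstsq(design, log_s.T)
    coef = coef.T  # (n_vox, 7)
    dxx, dyy, dzz, dxy, dxz, dyz = coef[:, 1:7].T
    tensors = np.empty((len(flat), 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = dxx, dyy, dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    evals = np.linalg.eigvalsh(tensors)
    md = evals.mean(axis=1)
    num = np.sqrt(((evals - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((evals ** 2).sum(axis=1))
    fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    s0 = np.exp(coef[:, 0])
    shape = data.shape[:-1]
    return (tensors.reshape(shape + (3, 3)), fa.reshape(shape),
            md.reshape(shape), s0.reshape(shape))


def _y_l0(ls, cos_theta):
    theta = np.arccos(np.clip(np.abs(cos_theta), 0.0, 1.0))
    return np.stack([sph_harm_y(l, 0, theta, 0.0).real for l in ls], axis=-1)


def _per_voxel_rh(signal, scheme, sh_order, axis_per_voxel=None):
    """Rotational harmonics of each voxel's raw signal, per shell.

    ``axis_per_voxel`` gives the per-voxel z-axis (principal direction); if
    None the laboratory z-axis is used (isotropic case, l = 0 only).
    """
    ls = np.arange(0, sh_order + 1, 2)
    n_vox = signal.shape[0]
    out = np.empty((n_vox, len(scheme.shells), len(ls)))
    for s, shell in enumerate(scheme.shells):
        members = scheme.shell_indices == shell.shell_id
        dirs = scheme.directions[members]
        sig = signal[:, members]
        # b0 shells carry no orientation contrast; represent them (and
        # isotropic targets) by the mean alone
        if axis_per_voxel is None or shell.is_b0:
            out[:, s, :] = 0.0
            out[:, s, 0] = sig.mean(axis=1) * np.sqrt(4 * np.pi)
        else:
            # cap the fitted degrees by the direction count per shell
            n_fit = min(len(ls), max(1, len(dirs) // 3))
            for v in range(n_vox):
                basis = _y_l0(ls[:n_fit], dirs @ axis_per_voxel[v])
                coef, *_ = np.linalg.lstsq(basis, sig[v])
                out[v, s, :] = 0.0
                out[v, s, :n_fit] = coef
    return out


# ---------------------------------------------------------------------------
# response model classes

class _TissueResponse(CompartmentModel):
    """Shared shell-matching logic for measured responses."""

    def __init__(self, shells, rotational_harmonics_, S0):
        self._shells = list(shells)
        self.rotational_harmonics_ = np.atleast_2d(
            np.asarray(rotational_harmonics_, dtype=float))
        self.S0 = float(S0)

    @property
    def sh_order(self):
        return 2 * (self.rotational_harmonics_.shape[1] - 1)

    def _match_shells(self, shells):
        """Map requested shells onto the stored estimation shells."""
        idx = []
        for shell in shells:
            cand = [i for i, s in enumerate(self._shells)
                    if abs(s.b - shell.b) < 50e6
                    and abs(s.delta - shell.delta) < 1e-4
                    and abs(s.Delta - shell.Delta) < 1e-4]
            if not cand:
                raise ValueError(
                    f"no stored response shell matches b={shell.b:.3g} s/m^2 "
                    f"(delta={shell.delta}, Delta={shell.Delta})")
            idx.append(cand[0])
        return np.array(idx, dtype=int)

    def _norm_rh(self, shells, sh_order):
        """Attenuation-normalized r_{s,l} on the requested shells/order."""
        idx = self._match_shells(shells)
        rh = self.rotational_harmonics_[idx] / self.S0
        n_l = sh_order // 2 + 1
        if rh.shape[1] >= n_l:
            return rh[:, :n_l]
        return np.pad(rh, ((0, 0), (0, n_l - rh.shape[1])))

    def rotational_harmonics(self, scheme, sh_order, **params):
        shells = scheme.shells if hasattr(scheme, "shells") else list(scheme)
        return self._norm_rh(shells, sh_order)

    def _spherical_mean_analytic(self, shells, **params):
        return self._norm_rh(shells, 0)[:, 0] / np.sqrt(4 * np.pi)


class TR1IsotropicResponse(_TissueResponse):
    """Measured isotropic response: per-shell mean attenuation + S0."""

    _parameters = {}

    def __init__(self, shells, rotational_harmonics_, S0):
        rh = np.atleast_2d(np.asarray(rotational_harmonics_, dtype=float))
        super().__init__(shells, rh[:, :1], S0)

    def _attenuation(self, scheme):
        from .distributed import _shells_of

        shells, idx = _shells_of(scheme)
        per_shell = self._norm_rh(shells, 0)[:, 0] / np.sqrt(4 * np.pi)
        return per_shell[idx]


class TR2AnisotropicResponse(_TissueResponse):
    """Measured axially symmetric response with free orientation mu."""

    _parameters = {"mu": (2, "rad", MU_BOUNDS)}
    is_anisotropic = True

    def _attenuation(self, scheme, mu):
        from .distributed import _shells_of

        muv = self._mu_vector(mu)
        shells, idx = _shells_of(scheme)
        rh = self._norm_rh(shells, self.sh_order)
        ls = np.arange(0, self.sh_order + 1, 2)
        basis = _y_l0(ls, scheme.directions @ muv)
        return np.einsum("ij,ij->i", basis, rh[idx])


# ---------------------------------------------------------------------------
# estimation

def _masked_signal(data, voxel_mask, scheme):
    data = np.asarray(data, dtype=float)
    voxel_mask = np.asarray(voxel_mask, dtype=bool)
    if data.shape[:-1] != voxel_mask.shape:
        raise ValueError("data grid and mask shapes differ")
    if data.shape[-1] != scheme.n_measurements:
        raise ValueError("data and scheme measurement counts differ")
    sig = data[voxel_mask]
    if sig.size == 0:
        raise ValueError("empty voxel mask")
    return sig


def estimate_isotropic_response(data, voxel_mask, scheme) -> TR1IsotropicResponse:
    """Average the l = 0 rotational harmonics of the masked voxels."""
    sig = _masked_signal(data, voxel_mask, scheme)
    rh = _per_voxel_rh(sig, scheme, 0).mean(axis=0)
    s0 = float(sig[:, scheme.b0_mask].mean()) if scheme.b0_mask.any() \
        else float(rh[0, 0] / np.sqrt(4 * np.pi))
    return TR1IsotropicResponse(scheme.shells, rh, s0)


def estimate_anisotropic_response(data, voxel_mask, scheme,
                                  sh_order: int = 8) -> TR2AnisotropicResponse:
    """Align each voxel to its tensor principal direction, average the
    rotational harmonics. Degenerate tensors are skipped (logged)."""
    sig = _masked_signal(data, voxel_mask, scheme)
    tensors, fa, _, _ = dti_fit(sig, scheme)
    evals, evecs = np.linalg.eigh(tensors)
    axes = evecs[:, :, -1]
    degenerate = ~np.isfinite(fa) | (evals[:, -1] <= 0)
    if degenerate.any():
        logger.warning("skipping %d voxels with degenerate tensors",
                       int(degenerate.sum()))
        sig, axes = sig[~degenerate], axes[~degenerate]
        if len(sig) == 0:
            raise ValueError("all voxels had degenerate tensors")
    rh = _per_voxel_rh(sig, scheme, sh_order, axes).mean(axis=0)
    s0 = float(sig[:, scheme.b0_mask].mean()) if scheme.b0_mask.any() \
        else float(rh[0, 0] / np.sqrt(4 * np.pi))
    return TR2AnisotropicResponse(scheme.shells, rh, s0)


def select_three_tissue_voxels(data, scheme, n_wm=50, n_gm=50, n_csf=50):
    """Heuristic WM/GM/CSF candidate selection from tensor statistics.

    Ranks voxels by FA and signal decay: top-FA voxels become white-matter
    candidates; among the rest, the fastest-decaying bright-b0 voxels become
    CSF; the lowest-FA voxels with moderate decay become gray matter.
    Returns three boolean masks over the voxel grid.
    """
    data = np.asarray(data, dtype=float)
    grid_shape = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    n_vox = len(flat)
    if n_wm + n_gm + n_csf > n_vox:
        raise ValueError(
            f"requested {n_wm + n_gm + n_csf} candidates from {n_vox} voxels")
    _, fa, md, s0 = dti_fit(flat, scheme)
    if np.allclose(flat, flat[0]):
        logger.warning("all voxels identical; tissue classes are degenerate")
    order_fa = np.argsort(-fa, kind="stable")
    wm_idx = order_fa[:n_wm]
    remaining = np.setdiff1d(np.arange(n_vox), wm_idx)
    # CSF: fast decay and bright b0 -> rank by MD and S0 jointly
    csf_score = (np.argsort(np.argsort(md[remaining]))
                 + np.argsort(np.argsort(s0[remaining])))
    csf_idx = remaining[np.argsort(-csf_score, kind="stable")[:n_csf]]
    remaining = np.setdiff1d(remaining, csf_idx)
    # gray matter: low FA with moderate decay — exclude CSF-like leftovers
    # whose diffusivity approaches the selected CSF population
    md_cut = 0.5 * (np.median(md[csf_idx]) + np.median(md[remaining]))
    moderate = remaining[md[remaining] < md_cut]
    if len(moderate) < n_gm:
        moderate = remaining
    gm_idx = moderate[np.argsort(fa[moderate], kind="stable")[:n_gm]]

    def mask_of(idx):
        m = np.zeros(n_vox, dtype=bool)
        m[idx] = True
        return m.reshape(grid_shape)

    return mask_of(wm_idx), mask_of(gm_idx), mask_of(csf_idx)
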