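"""One-call builders for well-known multi-compartment models.

Each preset assembles compartments, distributions, links and default fixes
into a ready-to-fit :class:`~mcdmri.framework.MultiCompartmentModel`:

====================  =====================================================
name                  composition
====================  =====================================================
ivim                  2 x Ball (blood / tissue water, bounded diffusivities)
ivim_fixed_dstar      as ivim with the blood diffusivity fixed to 7e-9 m^2/s
axcaliber             Ball + Gamma-distributed Gaussian-phase cylinders
ball_and_sticks(n)    Ball + n Sticks
noddi_watson          Ball(CSF) + Watson * (Stick + tortuous Zeppelin)
noddi_bingham         Ball(CSF) + Bingham * (Stick + tortuous Zeppelin)
noddix(n)             Ball(CSF) + n Watson-dispersed bundles
mc_mdi                spherical-mean Stick + tortuous Zeppelin
smt                   spherical-mean Zeppelin
smt_noddi             spherical-mean NODDI composition
csd                   single-kernel constrained spherical deconvolution
mt_csd                multi-tissue CSD from measured tissue responses
ss3t                  as mt_csd, fitted with the single-shell 3-tissue
                      alternating schedule
activeax              Ball + Zeppelin + Dot + Gaussian-phase cylinder
verdict               Gaussian-phase sphere + Ball + Stick
====================  =====================================================

Values that the source literature fixes (CSF and intra-axonal
diffusivities, IVIM bounds) are applied as defaults; diffusivity defaults
for activeax/verdict are package configuration values, not literature
claims. ``cascade`` fixes a model's parameters voxel-wise to the fitted
values of another model (e.g. the spherical-mean fit defining voxel-varying
convolution kernels for CSD).
"""

from __future__ import annotations

import numpy as np

from .compartments import (
    C1Stick,
    C4CylinderGaussianPhase,
    G1Ball,
    G2Zeppelin,
    S1Dot,
    S4SphereGaussianPhase,
)
from .distributed import ParameterDistributedModel, SphericalDistributedModel
from .framework import MultiCompartmentModel

__all__ = ["build_named_model", "cascade", "PRESET_NAMES"]

# literature default fixes
LAMBDA_PAR_WM = 1.7e-9     # intra-axonal parallel diffusivity [m^2/s]
LAMBDA_ISO_CSF = 3.0e-9    # free-water diffusivity [m^2/s]
LAMBDA_BLOOD_FIXED = 7e-9  # IVIM pseudo-diffusion fix [m^2/s]
IVIM_BLOOD_BOUNDS = (6e-9, 20e-9)
IVIM_TISSUE_BOUNDS = (0.5e-9, 6e-9)


def _dispersed_bundle(distribution: str, sh_order: int):
    bundle = SphericalDistributedModel(
        [C1Stick(), G2Zeppelin()], distribution, sh_order=sh_order)
    bundle.set_equal_parameter(
        "G2Zeppelin_1_lambda_par", "C1Stick_1_lambda_par")
    bundle.set_tortuous_parameter(
        "G2Zeppelin_1_lambda_perp", "G2Zeppelin_1_lambda_par",
        "partial_volume_0")
    bundle.set_fixed_parameter("C1Stick_1_lambda_par", LAMBDA_PAR_WM)
    return bundle


def build_named_model(name: str, n_bundles: int = 2, sh_order: int = 8,
                      dispersion_sh_order: int = 14,
                      responses=None) -> MultiCompartmentModel:
    """Build a preset model by name (see the module docstring).

    ``responses`` (mt_csd / ss3t / csd): mapping with keys 'wm', 'gm', 'csf'
    (or just 'wm' for csd) holding estimated tissue response models.
    """
    name = name.lower()

    if name in ("ivim", "ivim_fixed_dstar"):
        mc = MultiCompartmentModel([G1Ball(), G1Ball()])
        mc.set_parameter_bounds("G1Ball_1_lambda_iso", *IVIM_BLOOD_BOUNDS)
        mc.set_parameter_bounds("G1Ball_2_lambda_iso", *IVIM_TISSUE_BOUNDS)
        if name == "ivim_fixed_dstar":
            mc.fix_parameter("G1Ball_1_lambda_iso", LAMBDA_BLOOD_FIXED)
        return mc

    if name == "axcaliber":
        cylinders = ParameterDistributedModel(
            [C4CylinderGaussianPhase()],
            "C4CylinderGaussianPhase_1_diameter", volume_norm="cylinder")
        cylinders.set_fixed_parameter(
            "C4CylinderGaussianPhase_1_lambda_par", LAMBDA_PAR_WM)
        cylinders.set_fixed_parameter(
            "C4CylinderGaussianPhase_1_lambda_intra", LAMBDA_PAR_WM)
        mc = MultiCompartmentModel([G1Ball(), cylinders])
        mc.requires_multiple_diffusion_times = True
        return mc

    if name == "ball_and_sticks":
        return MultiCompartmentModel(
            [G1Ball()] + [C1Stick() for _ in range(max(n_bundles, 1))])

    if name in ("noddi_watson", "noddi_bingham"):
        dist = "watson" if name == "noddi_watson" else "bingham"
        bundle = _dispersed_bundle(dist, dispersion_sh_order)
        mc = MultiCompartmentModel([G1Ball(), bundle])
        mc.fix_parameter("G1Ball_1_lambda_iso", LAMBDA_ISO_CSF)
        return mc

    if name == "noddix":
        bundles = [_dispersed_bundle("watson", dispersion_sh_order)
                   for _ in range(max(n_bundles, 1))]
        mc = MultiCompartmentModel([G1Ball()] + bundles)
        mc.fix_parameter("G1Ball_1_lambda_iso", LAMBDA_ISO_CSF)
        return mc

    if name == "mc_mdi":
        mc = MultiCompartmentModel([C1Stick(), G2Zeppelin()], flavor="MC-SM")
        mc.link_equal("G2Zeppelin_1_lambda_par", "C1Stick_1_lambda_par")
        mc.link_tortuous("G2Zeppelin_1_lambda_perp",
                         "G2Zeppelin_1_lambda_par", "partial_volume_0")
        return mc

    if name == "smt":
        return MultiCompartmentModel([G2Zeppelin()], flavor="MC-SM")

    if name == "smt_noddi":
        bundle = _dispersed_bundle("watson", dispersion_sh_order)
        # dispersion does not affect spherical means; keep it determinate
        bundle.set_fixed_parameter("SD1Watson_1_odi", 0.5)
        mc = MultiCompartmentModel([G1Ball(), bundle], flavor="MC-SM")
        mc.fix_parameter("G1Ball_1_lambda_iso", LAMBDA_ISO_CSF)
        return mc

    if name == "csd":
        if responses is not None and "wm" in responses:
            kernel = responses["wm"]
            return MultiCompartmentModel([kernel], flavor="MC-SH",
                                         sh_order=sh_order)
        mc = MultiCompartmentModel([C1Stick()], flavor="MC-SH",
                                   sh_order=sh_order)
        mc.fix_parameter("C1Stick_1_lambda_par", LAMBDA_PAR_WM)
        return mc

    if name in ("mt_csd", "ss3t"):
        if responses is None or not {"wm", "gm", "csf"} <= set(responses):
            raise ValueError(
                f"{name} requires tissue responses with keys wm/gm/csf")
        wm, gm, csf = responses["wm"], responses["gm"], responses["csf"]
        return MultiCompartmentModel(
            [wm, gm, csf], flavor="MC-SH", sh_order=sh_order,
            S0_responses=[wm.S0, gm.S0, csf.S0])

    if name == "activeax":
        cylinder = C4CylinderGaussianPhase()
        mc = MultiCompartmentModel(
            [G1Ball(), G2Zeppelin(), S1Dot(), cylinder])
        mc.fix_parameter("G1Ball_1_lambda_iso", LAMBDA_ISO_CSF)
        mc.fix_parameter("C4CylinderGaussianPhase_1_lambda_par",
                         LAMBDA_PAR_WM)
        mc.fix_parameter("C4CylinderGaussianPhase_1_lambda_intra",
                         LAMBDA_PAR_WM)
        mc.link_equal("G2Zeppelin_1_lambda_par",
                      "C4CylinderGaussianPhase_1_lambda_par")
        mc.link_equal("G2Zeppelin_1_mu", "C4CylinderGaussianPhase_1_mu")
        return mc

    if name == "verdict":
        mc = MultiCompartmentModel([S4SphereGaussianPhase(), G1Ball(),
                                    C1Stick()])
        # configuration defaults (supplementary-style fixes, not literature)
        mc.fix_parameter("S4SphereGaussianPhase_1_lambda_intra", 0.9e-9)
        mc.fix_parameter("G1Ball_1_lambda_iso", 2.0e-9)
        mc.set_parameter_bounds("C1Stick_1_lambda_par", 0.5e-9, 8e-9)
        return mc

    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


PRESET_NAMES = (
    "ivim", "ivim_fixed_dstar", "axcaliber", "ball_and_sticks",
    "noddi_watson", "noddi_bingham", "noddix", "mc_mdi", "smt", "smt_noddi",
    "csd", "mt_csd", "ss3t", "activeax", "verdict",
)


def cascade(from_fitted, to_model: MultiCompartmentModel,
            parameter_pairs: dict) -> MultiCompartmentModel:
    """Fix ``to_model`` parameters voxel-wise to values fitted by another
    model: ``parameter_pairs`` maps target name -> source name in the fitted
    results (cross-framework parameter cascading)."""
    for target, source in parameter_pairs.items():
        if source not in from_fitted.fitted_parameters:
            raise ValueError(f"source parameter {source!r} not in the fitted "
                             "results")
        value = np.asarray(from_fitted.fitted_parameters[source], dtype=float)
        card = to_model.registry.cardinality(target)
        tail = (card,) if card > 1 else ()
        if value.shape != from_fitted.vox_shape + tail:
            raise ValueError(
                f"fitted map for {source!r} has shape {value.shape}, "
                f"expected {from_fitted.vox_shape + tail}")
        to_model.fix_parameter(target, value)
    return to_model
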