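"""Standard-format I/O: NIfTI volumes, FSL bval/bvec gradient tables with a
pulse-timing sidecar, single-file scheme tables, and fitted parameter maps.

Disk conventions follow the field: b-values on disk are s/mm^2 (FSL), all
in-memory values are SI; volumes are written float32, processed float64;
the NIfTI affine is passed through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionScheme, build_scheme_from_bvalues

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_scheme_table",
    "write_scheme_table",
    "write_maps",
    "read_timing_sidecar",
]


def read_timing_sidecar(path) -> dict:
    """Sidecar with delta/Delta (and optionally TE), all in seconds.

    JSON mapping, or a plain-text file with `name value` lines.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = {}
        for line in text.splitlines():
            parts = line.split()
            if len(parts) >= 2:
                raw[parts[0].strip(":")] = [float(v) for v in parts[1:]] \
                    if len(parts) > 2 else float(parts[1])
    out = {}
    for key in ("delta", "Delta", "TE"):
        if key in raw:
            v = raw[key]
            out[key] = np.asarray(v, dtype=float) if np.ndim(v) else float(v)
    if "delta" not in out or "Delta" not in out:
        raise ValueError(f"timing sidecar {path} must define delta and Delta "
                         "(seconds)")
    return out


def read_dwi(nifti_path, bval_path, bvec_path, timing_sidecar):
    """Load a 4-D DWI volume with its FSL gradient table.

    Returns (data (x, y, z, N) float64, AcquisitionScheme, affine).
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    bvals_smm2 = np.loadtxt(bval_path)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if data.shape[-1] != len(bvals_smm2):
        raise ValueError(
            f"image has {data.shape[-1]} volumes but gradient table has "
            f"{len(bvals_smm2)} entries")
    timing = read_timing_sidecar(timing_sidecar)
    scheme = build_scheme_from_bvalues(
        bvals_smm2 * 1e6, bvecs, timing["delta"], timing["Delta"],
        TE=timing.get("TE"))
    return data, scheme, img.affine


def write_dwi(path, data, affine=None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def write_scheme_table(path, scheme: AcquisitionScheme):
    """Single-file table: header then b[s/m^2] nx ny nz delta[s] Delta[s] TE[s]."""
    te = scheme.TE if scheme.TE is not None else \
        np.full(scheme.n_measurements, np.nan)
    table = np.column_stack([
        scheme.bvalues, scheme.directions, scheme.delta, scheme.Delta, te])
    header = "b[s/m^2] nx ny nz delta[s] Delta[s] TE[s]"
    np.savetxt(str(path), table, header=header, fmt="%.8e")


def read_scheme_table(path) -> AcquisitionScheme:
    table = np.loadtxt(str(path))
    table = np.atleast_2d(table)
    te = table[:, 6]
    return build_scheme_from_bvalues(
        table[:, 0], table[:, 1:4], table[:, 4], table[:, 5],
        TE=None if np.isnan(te).all() else te)


def write_maps(fitted, out_dir, affine=None) -> list[str]:
    """One NIfTI per fitted parameter (components split for pairs) plus MSE
    and R^2 maps. Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written = []

    def save(name, arr):
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(
            np.asarray(arr, dtype=np.float32), affine), str(p))
        written.append(str(p))

    for name, arr in fitted.fitted_parameters.items():
        card = fitted.model.registry.cardinality(name) \
            if name in fitted.model.registry.entries else 1
        if name == "sh_coeff" or card == 1:
            save(name, arr)
        else:
            for c in range(card):
                save(f"{name}_{c}", np.asarray(arr)[..., c])
    save("mse", fitted.mse)
    save("r2", fitted.r2)
    return written
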