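"""Readers and writers for the standard on-disk formats.

Gradient tables (FSL bvals/bvecs and the MRtrix 4-column dialect), per-voxel
coil-tensor deviation fields (9-component NIfTI, HCP "grad_dev" style), DWI
volumes, and FOD volumes stored as order-8 real even-SH coefficient maps with
a JSON sidecar recording the basis convention.  Writer/reader pairs are exact
inverses on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import AcquisitionScheme
from .sh import BASIS_TAG

__all__ = [
    "read_gradient_table",
    "write_gradient_table",
    "read_coil_field",
    "write_coil_field",
    "read_dwi",
    "write_dwi",
    "read_fod_volume",
    "write_fod_volume",
]

# HCP grad_dev stores dL column-major: [xx, yx, zx, xy, yy, zy, xz, yz, zz],
# i.e. component k maps to row k % 3, column k // 3.
_ORDERINGS = {
    "column-major": [(k % 3, k // 3) for k in range(9)],
    "row-major": [(k // 3, k % 3) for k in range(9)],
}


def _parse_float_table(path: Path, expect_cols: int | None = None) -> np.ndarray:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            row = [float(tok) for tok in line.replace(",", " ").split()]
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-numeric entry ({e})") from None
        if expect_cols is not None and len(row) != expect_cols:
            raise ValueError(
                f"{path}:{ln}: expected {expect_cols} columns, got {len(row)}")
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty gradient table")
    return np.array(rows)


def read_gradient_table(path, dialect: str = "fsl",
                        bval_path=None, flip=(1, 1, 1)) -> AcquisitionScheme:
    """Read a gradient table.

    dialect='fsl' : ``path`` is the bvecs file (3 rows x m columns) and
    ``bval_path`` the bvals file (defaults to the sibling with suffix
    ``.bval``/``.bvals``).  dialect='mrtrix' : single 4-column file
    ``gx gy gz b``.  ``flip`` applies per-axis sign flips on read.
    """
    path = Path(path)
    flip = np.asarray(flip, dtype=float)
    if dialect == "fsl":
        bvecs = _parse_float_table(path)
        if bvecs.shape[0] != 3:
            raise ValueError(f"{path}: FSL bvecs must have 3 rows, got {bvecs.shape[0]}")
        if bval_path is None:
            for suffix in (".bval", ".bvals"):
                cand = path.with_suffix(suffix)
                if cand.exists():
                    bval_path = cand
                    break
            else:
                raise FileNotFoundError(f"no bvals file found next to {path}")
        bvals = _parse_float_table(Path(bval_path)).ravel()
        if bvals.shape[0] != bvecs.shape[1]:
            raise ValueError(
                f"bvals count {bvals.shape[0]} != bvecs columns {bvecs.shape[1]}")
        dirs = bvecs.T * flip
    elif dialect == "mrtrix":
        table = _parse_float_table(path, expect_cols=4)
        dirs = table[:, :3] * flip
        bvals = table[:, 3]
    else:
        raise ValueError(f"unknown gradient-table dialect {dialect!r}")
    dirs[bvals == 0] = 0.0
    return AcquisitionScheme(dirs, bvals)


def write_gradient_table(scheme: AcquisitionScheme, path, dialect: str = "fsl",
                         bval_path=None) -> None:
    path = Path(path)
    if dialect == "fsl":
        np.savetxt(path, scheme.directions.T, fmt="%.12g")
        if bval_path is None:
            bval_path = path.with_suffix(".bval")
        np.savetxt(Path(bval_path), scheme.bvals[None, :], fmt="%.12g")
    elif dialect == "mrtrix":
        np.savetxt(path, np.column_stack([scheme.directions, scheme.bvals]),
                   fmt="%.12g")
    else:
        raise ValueError(f"unknown gradient-table dialect {dialect!r}")


def read_coil_field(path, ordering: str = "column-major") -> np.ndarray:
    """Read a per-voxel coil-tensor deviation volume (9 components) and
    return the (X, Y, Z, 3, 3) field of full tensors ``L = I + dL``."""
    if ordering not in _ORDERINGS:
        raise ValueError(f"unknown component ordering {ordering!r}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 9:
        raise ValueError(
            f"{path}: coil field must be 4D with 9 components, got {data.shape}")
    field = np.zeros(data.shape[:3] + (3, 3))
    for k, (r, c) in enumerate(_ORDERINGS[ordering]):
        field[..., r, c] = data[..., k]
    field += np.eye(3)
    return field


def write_coil_field(field: np.ndarray, path, ordering: str = "column-major",
                     affine: np.ndarray | None = None) -> None:
    """Write an (X, Y, Z, 3, 3) coil tensor field as a 9-component deviation
    (dL = L - I) NIfTI volume."""
    if ordering not in _ORDERINGS:
        raise ValueError(f"unknown component ordering {ordering!r}")
    field = np.asarray(field, dtype=float)
    if field.ndim != 5 or field.shape[-2:] != (3, 3):
        raise ValueError(f"coil field must be (X,Y,Z,3,3), got {field.shape}")
    dl = field - np.eye(3)
    data = np.zeros(field.shape[:3] + (9,))
    for k, (r, c) in enumerate(_ORDERINGS[ordering]):
        data[..., k] = dl[..., r, c]
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)),
             str(path))


def write_dwi(volume: np.ndarray, scheme: AcquisitionScheme, prefix,
              affine: np.ndarray | None = None) -> None:
    """Write a 4D DWI volume as ``<prefix>.nii`` with FSL-style
    ``<prefix>.bvec``/``<prefix>.bval`` gradient files."""
    prefix = Path(prefix)
    volume = np.asarray(volume, dtype=float)
    if volume.shape[-1] != len(scheme):
        raise ValueError(
            f"volume has {volume.shape[-1]} measurements, scheme {len(scheme)}")
    nib.save(nib.Nifti1Image(volume, affine if affine is not None else np.eye(4)),
             str(prefix.with_suffix(".nii")))
    write_gradient_table(scheme, prefix.with_suffix(".bvec"),
                         bval_path=prefix.with_suffix(".bval"))


def read_dwi(prefix) -> tuple[np.ndarray, AcquisitionScheme]:
    prefix = Path(prefix)
    img = nib.load(str(prefix.with_suffix(".nii")))
    scheme = read_gradient_table(prefix.with_suffix(".bvec"),
                                 bval_path=prefix.with_suffix(".bval"))
    return np.asarray(img.dataobj, dtype=float), scheme


def write_fod_volume(fods: np.ndarray, path, basis: str = BASIS_TAG,
                     affine: np.ndarray | None = None) -> None:
    """Write a (..., 45) order-8 SH FOD volume with a JSON basis sidecar."""
    path = Path(path)
    fods = np.asarray(fods, dtype=float)
    nib.save(nib.Nifti1Image(fods, affine if affine is not None else np.eye(4)),
             str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"sh_basis": basis,
                                   "n_coeffs": int(fods.shape[-1])}))


def read_fod_volume(path, expect_basis: str = BASIS_TAG) -> np.ndarray:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tag = meta.get("sh_basis")
        if tag != expect_basis:
            raise ValueError(
                f"{path}: FOD stored in basis {tag!r}, expected {expect_basis!r};"
                " convert with sh.basis_conversion first")
    else:
        raise ValueError(f"{path}: missing basis sidecar {sidecar.name}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float)
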