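"""NIfTI and sidecar I/O.

Images travel as NIfTI-1 with the affine preserved from input to output
(float32 for intensities, int16 for label maps).  K-space volumes are
stored as paired real/imaginary float32 NIfTI files plus a JSON sidecar
documenting shape, axis semantics and the DC index.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import InputError
from .physics_synth import QuantitativeMapSet

__all__ = [
    "load_volume",
    "save_volume",
    "save_labels",
    "load_maps",
    "save_kspace",
    "load_kspace",
]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns ``(data, affine)`` with float data."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # nibabel raises several header error types
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, np.asarray(img.affine)


def save_volume(path: str | Path, data: np.ndarray,
                affine: np.ndarray | None = None) -> None:
    """Write an intensity volume as float32 NIfTI."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def save_labels(path: str | Path, labels: np.ndarray,
                affine: np.ndarray | None = None) -> None:
    """Write a label map as int16 NIfTI (bit-exact round trip)."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine),
             str(path))


def load_maps(t1_path: str | Path, t2_path: str | Path,
              pd_path: str | Path) -> tuple[QuantitativeMapSet, np.ndarray]:
    """Read co-registered T1/T2/PD maps from three NIfTI files.

    The three affines must agree (tolerance 1e-5); a mismatch is rejected
    with a message naming the offending files.
    """
    t1, a1 = load_volume(t1_path)
    t2, a2 = load_volume(t2_path)
    pd_, a3 = load_volume(pd_path)
    for other_path, other in ((t2_path, a2), (pd_path, a3)):
        if not np.allclose(a1, other, atol=1e-5):
            raise InputError(
                f"affine mismatch between {t1_path} and {other_path}; "
                "maps must be co-registered on one grid"
            )
    return QuantitativeMapSet(t1=t1, t2=t2, pd=pd_), a1


def load_maps_4d(path: str | Path) -> tuple[QuantitativeMapSet, np.ndarray]:
    """Read a 4-D NIfTI whose 4th axis stacks [T1, T2, PD]."""
    data, affine = load_volume(path)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise InputError(
            f"expected a 4-D volume with 3 components, got shape {data.shape}"
        )
    return QuantitativeMapSet(t1=data[..., 0], t2=data[..., 1],
                              pd=data[..., 2]), affine


def save_kspace(base: str | Path, k: np.ndarray,
                affine: np.ndarray | None = None) -> None:
    """Write complex k-space as ``<base>_real.nii`` / ``<base>_imag.nii``
    plus ``<base>.json`` describing layout."""
    base = Path(base)
    k = np.asarray(k)
    save_volume(base.with_name(base.name + "_real.nii"), k.real, affine)
    save_volume(base.with_name(base.name + "_imag.nii"), k.imag, affine)
    sidecar = {
        "shape": list(k.shape),
        "axes": ["slice", "phase_encode", "readout"],
        "dc_index": [int(k.shape[1]) // 2, int(k.shape[2]) // 2],
        "convention": "centered orthonormal 2-D DFT per slice",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_kspace(base: str | Path) -> np.ndarray:
    base = Path(base)
    re, _ = load_volume(base.with_name(base.name + "_real.nii"))
    im, _ = load_volume(base.with_name(base.name + "_imag.nii"))
    if re.shape != im.shape:
        raise InputError("real/imag k-space components differ in shape")
    return re + 1j * im
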