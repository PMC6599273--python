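"""NIfTI volume and mask I/O.

Volumes are stored in memory with axis order (z, y, x); NIfTI files use
(x, y, z), so arrays are transposed on the way in and out and the affine
encodes the voxel spacing.  Masks are written as 0/1 uint8 with the same
affine as their source volume.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import CTVolume

__all__ = ["write_volume", "read_volume", "write_mask", "read_mask"]


def _affine(spacing_zyx: tuple[float, float, float]) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    return np.diag([sx, sy, sz, 1.0])


def write_volume(volume: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.ascontiguousarray(volume.data.T).astype(np.float32),
                          _affine(volume.spacing))
    img.header["descrip"] = f"day={volume.acquisition_day:g}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, patient_id: int = -1,
                timepoint: int = -1, acquisition_day: float = 0.0) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(data=data, spacing=spacing, acquisition_day=acquisition_day,
                    patient_id=patient_id, timepoint=timepoint)


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float],
               path: str | Path) -> None:
    img = nib.Nifti1Image(np.ascontiguousarray(mask.T).astype(np.uint8),
                          _affine(spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T.astype(bool)
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[2]), float(zooms[1]), float(zooms[0]))
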