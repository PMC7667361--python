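"""Thin NIfTI-1 read/write helpers (nibabel-backed)."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .types import BoldSeries


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file, returning ``(data, affine)``.

    Raises ``IOError`` naming the file for anything nibabel cannot parse.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"could not read NIfTI file {path!r}: {exc}") from exc
    return np.asarray(data), np.asarray(img.affine)


def write_nifti(volume: np.ndarray, affine: np.ndarray, path, dtype=None) -> Path:
    """Write a 3D/4D volume as NIfTI-1; returns the path written."""
    volume = np.asarray(volume)
    if dtype is not None:
        volume = volume.astype(dtype)
    if volume.dtype == bool:
        volume = volume.astype(np.uint8)
    elif volume.dtype in (np.int64, np.uint64):
        volume = volume.astype(np.int32)  # NIfTI-1 has no 64-bit int
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(volume, np.asarray(affine, dtype=float)).to_filename(str(path))
    return path


def read_bold(path, tr: float | None = None) -> BoldSeries:
    """Load a 4D NIfTI as a :class:`BoldSeries`.

    ``tr`` overrides the header pixdim[4] (used when the header carries no
    meaningful timing).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else 0.0
    if tr <= 0:
        raise ValueError(f"no valid TR in header of {path!r}; pass tr explicitly")
    return BoldSeries(data=np.asarray(data, dtype=np.float32), affine=np.asarray(img.affine), tr=tr)


def write_bold(series: BoldSeries, path) -> Path:
    """Write a :class:`BoldSeries` as 4D NIfTI-1 with TR in pixdim[4]."""
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float32), series.affine)
    img.header["pixdim"][4] = series.tr
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img.to_filename(str(path))
    return path
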