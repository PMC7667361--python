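"""Core in-memory containers shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BoldSeries:
    """A 4D BOLD series: spatial grid ``(x, y, z)`` by time, plus geometry.

    Parameters
    ----------
    data:
        4D array ``(x, y, z, t)`` of signal values (arbitrary units).
    affine:
        4x4 voxel-index-to-mm (world) transform, NIfTI convention.
    tr:
        Repetition time in seconds (sampling interval of the time axis).
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD series must contain at least one volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy_with(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data=data, affine=self.affine.copy(), tr=self.tr)


def voxel_coords_mm(indices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of voxel indices ``(n, 3)`` under ``affine``."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    return indices @ affine[:3, :3].T + affine[:3, 3]


def check_motion_trace(motion: np.ndarray) -> np.ndarray:
    """Validate a rigid-body motion trace: ``(n_volumes, 6)``.

    Columns are three translations (mm) then three rotations (radians).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion trace must have shape (n_volumes, 6), got {motion.shape}")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    return motion


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for a synthetic cohort.

    ``masks`` holds 3D boolean arrays for each planted region
    (``lfcd_decrease``, ``sfcd_decrease``, ``sfcd_increase``); ``effects``
    the corresponding group-level effect magnitudes; ``severity`` the
    per-subject effect-scaling factor (0 for controls) that the clinical
    scores are generated from.
    """

    masks: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    severity: np.ndarray = None
    network_id: np.ndarray = None
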