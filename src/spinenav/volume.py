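"""Minimal regular-grid volume container with world/index mapping and NIfTI I/O.

World coordinates are millimetres in the package-wide LPS convention; the
voxel at index ``(0, 0, 0)`` has its *center* at ``origin`` and axes are
axis-aligned (no oblique direction cosines — the synthetic scanner writes
axis-aligned volumes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar or label volume on an isotropic or anisotropic grid."""

    array: np.ndarray
    spacing: np.ndarray  # (3,) mm per axis
    origin: np.ndarray  # (3,) mm, center of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError("volume array must be 3-dimensional")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, float).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape  # type: ignore[return-value]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for (n, 3) world points (mm)."""
        return (np.atleast_2d(points_mm) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.atleast_2d(indices) * self.spacing + self.origin

    def sample_linear(self, points_mm: np.ndarray, cval: float = 0.0) -> np.ndarray:
        """Trilinear interpolation at world points; outside → ``cval``."""
        idx = self.world_to_index(points_mm).T
        return ndimage.map_coordinates(
            self.array.astype(float), idx, order=1, mode="constant", cval=cval
        )

    def sample_nearest_labels(self, points_mm: np.ndarray, cval: int = 0) -> np.ndarray:
        """Label lookup at world points by rounding to the nearest voxel."""
        idx = np.rint(self.world_to_index(points_mm)).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.full(len(idx), cval, dtype=self.array.dtype)
        ii = idx[inside]
        out[inside] = self.array[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points_mm)
        return np.all((idx > -0.5) & (idx < np.array(self.shape) - 0.5), axis=1)

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write as NIfTI; the affine carries spacing and origin (LPS mm)."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asanyarray(self.array), affine), str(path))

    @staticmethod
    def load(path: str | Path) -> "Volume":
        img = nib.load(str(path))
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise ValueError("only axis-aligned volumes are supported")
        return Volume(
            np.asanyarray(img.dataobj), np.diag(aff[:3, :3]).copy(), aff[:3, 3].copy()
        )
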