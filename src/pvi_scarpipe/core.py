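"""Image container and coordinate conventions.

All volumes are 3D scalar grids indexed ``data[i, j, k]`` with a NIfTI-style
affine mapping voxel indices to world millimetres.  World axes follow patient
axes: x right->left, y posterior->anterior, z inferior->superior.  Every
physical length in the package is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ImageVolume:
    """A 3D scalar image with physical geometry, tagged by modality/time-point.

    Parameters
    ----------
    data
        Voxel values, shape (ni, nj, nk), float.
    affine
        4x4 voxel-index -> world-mm map (NIfTI convention).
    modality
        Free-form tag, conventionally ``"t2w"`` or ``"lge"``.
    timepoint
        Conventionally ``"pre"``, ``"24h"`` or ``"30d"``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = ""
    timepoint: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (N, 3) or (3,) to world mm coordinates."""
        arr = np.asarray(ijk, dtype=float)
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        arr = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        out = np.atleast_2d(arr) @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def sample_world(self, points_mm: np.ndarray, order: int = 1,
                     cval: float = 0.0) -> np.ndarray:
        """Interpolate voxel values at world-mm points (trilinear by default)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        vox = np.atleast_2d(self.world_to_voxel(pts))
        return ndimage.map_coordinates(self.data, vox.T, order=order,
                                       mode="constant", cval=cval)

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)          # (3, ni, nj, nk)
        ijk = np.moveaxis(idx, 0, -1)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def with_data(self, data: np.ndarray, **tags) -> "ImageVolume":
        kw = dict(modality=self.modality, timepoint=self.timepoint,
                  subject_id=self.subject_id)
        kw.update(tags)
        return ImageVolume(np.asarray(data), self.affine.copy(), **kw)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=atol))


def make_affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def save_nifti(vol: ImageVolume, path: str) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, path)


def load_nifti(path: str, modality: str = "", timepoint: str = "",
               subject_id: str = "") -> ImageVolume:
    img = nib.load(path)
    return ImageVolume(np.asarray(img.get_fdata(), dtype=float), img.affine,
                       modality=modality, timepoint=timepoint,
                       subject_id=subject_id)
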