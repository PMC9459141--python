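"""Masked grayscale volumes: the unit of radiomic feature extraction.

A TRUS video clip is treated as a single 3D stack (frames along the third
axis), so the same machinery serves genuinely volumetric images and stacked
2D cine loops alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class ROIVolume:
    """A 3D grayscale image with an aligned binary region-of-interest mask.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Grayscale voxel values (float).
    mask : ndarray of bool, same shape
        True marks voxels inside the region of interest. Must contain at
        least two foreground voxels.
    spacing : tuple of float
        Per-axis voxel size in mm. Purely descriptive here: no resampling
        is performed.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D, got {self.intensities.ndim} dims"
            )
        if self.intensities.shape != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{self.intensities.shape}"
            )
        if int(self.mask.sum()) < 2:
            raise ValueError("mask must contain at least 2 foreground voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def masked_values(self) -> np.ndarray:
        """Intensities of the foreground voxels, 1D."""
        return self.intensities[self.mask]


def save_nifti_pair(roi: ROIVolume, image_path: str | Path, mask_path: str | Path) -> None:
    """Write image and mask as a NIfTI pair sharing the same affine."""
    affine = np.diag([*roi.spacing, 1.0])
    nib.save(nib.Nifti1Image(roi.intensities.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine), str(mask_path))


def load_nifti_pair(image_path: str | Path, mask_path: str | Path) -> ROIVolume:
    """Read an image/mask NIfTI pair into an :class:`ROIVolume`.

    The mask is binarised at > 0. Voxel spacing is taken from the image
    header; image and mask grids must agree voxel-for-voxel.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if mask.ndim == 4 and mask.shape[3] == 1:
        mask = mask[..., 0]
    if data.shape != mask.shape:
        raise ValueError(
            f"image grid {data.shape} does not match mask grid {mask.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIVolume(data, mask, spacing)
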