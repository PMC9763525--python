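"""Voxel-image and label-mask containers with NIfTI-1 round trips.

Thin carriers for 3-D activity-concentration grids (Bq/mL) and aligned
integer VOI masks. Files are written as compressed NIfTI-1 through nibabel
so that images can be inspected with standard neuroimaging tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelImage", "LabelMask"]


@dataclass
class VoxelImage:
    """A 3-D activity-concentration grid.

    Parameters
    ----------
    values
        3-D array of activity concentration, Bq/mL.
    voxel_size
        Isotropic voxel edge length in mm, or a length-3 sequence.
    origin
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        else:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        sx, sy, sz = self.voxel_size
        return sx * sy * sz / 1000.0

    def total_activity(self) -> float:
        """Total activity in the grid, Bq (concentration x voxel volume)."""
        return float(self.values.sum() * self.voxel_volume_ml)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(self.values.astype(np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelImage":
        img = nib.load(str(path))
        affine = img.affine
        voxel_size = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(v) for v in affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), voxel_size, origin)


@dataclass
class LabelMask:
    """Integer VOI labels aligned with a :class:`VoxelImage`.

    Label 0 means unlabelled. ``legend`` maps label -> region name and
    ``volumes_ml`` optionally records the analytic (ground-truth) volume of
    each labelled region, when known by construction.
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    volumes_ml: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one labelled region."""
        return self.labels == label

    def check_aligned(self, image: VoxelImage) -> None:
        if self.labels.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.labels.shape} does not match image shape "
                f"{image.values.shape}"
            )

    def save(self, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
        affine = np.diag(list(voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))
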