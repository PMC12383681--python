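"""Core in-memory containers shared by every pipeline stage.

Coordinate convention: volumes are indexed ``(x, y, z)`` in 0-based voxel
space; the *axial* plane fixes axis 2, *sagittal* fixes axis 0 and
*coronal* fixes axis 1.  Spacing is a millimetre triple aligned to the
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = ["ImageVolume", "LesionSample", "PatchSet"]

#: PET intensity units: raw activity concentration vs. standardized uptake value.
UNITS_BQML = "kBq/mL"
UNITS_SUV = "SUV"
UNITS_HU = "HU"


@dataclass
class ImageVolume:
    """One 3D modality grid with voxel spacing and acquisition metadata.

    Parameters
    ----------
    voxels:
        3D float array of intensities (HU for CT, kBq/mL or SUV for PET).
    spacing:
        Voxel size in mm along each axis; strictly positive.
    modality:
        ``"CT"`` or ``"PET"``.
    units:
        ``"HU"``, ``"kBq/mL"`` or ``"SUV"``.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    modality: str
    units: str = UNITS_HU

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D voxel grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.modality not in ("CT", "PET"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, **changes) -> "ImageVolume":
        """Copy of this volume with new voxel data (and optional field changes)."""
        return replace(self, voxels=voxels, **changes)


@dataclass
class LesionSample:
    """Paired PET/CT volumes, lesion mask, class label and clinical metadata.

    The unit of analysis is the lesion (nodule), not the patient.  ``label``
    is 1 for the DLBCL-like class and 0 for the IDC-like class.
    """

    lesion_id: str
    ct: ImageVolume
    pet: ImageVolume
    mask: np.ndarray
    label: int
    site: str
    weight_kg: float
    dose_MBq: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.ct.shape or self.mask.shape != self.pet.shape:
            raise ValueError("mask and volumes must share a voxel grid")
        if self.ct.spacing != self.pet.spacing:
            raise ValueError("CT and PET spacing differ")
        if not self.mask.any():
            raise ValueError("lesion mask is empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.weight_kg <= 0 or self.dose_MBq <= 0:
            raise ValueError("weight and dose must be positive")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.ct.spacing


PLANES = ("axial", "sagittal", "coronal")
#: axis fixed by each orthogonal plane
PLANE_AXIS = {"axial": 2, "sagittal": 0, "coronal": 1}

CT_PATCH_SIZE = 64
PET_PATCH_SIZE = 128


@dataclass
class PatchSet:
    """Six 2D lesion patches: 3 orthogonal planes x 2 modalities.

    CT patches are 64x64 and PET patches 128x128, min-max scaled to [0, 1].
    ``slice_index`` records the source slice per (modality, plane).
    """

    lesion_id: str
    patches: dict = field(default_factory=dict)  # (modality, plane) -> 2D array
    slice_index: dict = field(default_factory=dict)  # (modality, plane) -> int

    def validate(self) -> None:
        if len(self.patches) != 6:
            raise ValueError(f"expected 6 patches, got {len(self.patches)}")
        for (modality, plane), patch in self.patches.items():
            if plane not in PLANES:
                raise ValueError(f"unknown plane {plane!r}")
            want = CT_PATCH_SIZE if modality == "CT" else PET_PATCH_SIZE
            if patch.shape != (want, want):
                raise ValueError(
                    f"{modality}/{plane} patch has shape {patch.shape}, want ({want}, {want})"
                )

    def get(self, modality: str, plane: str) -> np.ndarray:
        return self.patches[(modality, plane)]
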