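"""The eight clinic features (CFs): routine PET metabolic parameters.

Long/short axis (mm), volume (cm3), SUVmin/SUVmean/SUVmax, metabolic tumor
volume (MTV, cm3) and total lesion glycolysis (TLG, g).  MTV uses the
common 41%-of-SUVmax threshold by default; TLG = SUVmean inside the MTV
region x MTV, an identity that holds exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import ImageVolume, UNITS_SUV

__all__ = ["ClinicalFeatureVector", "compute_clinical_features", "CF_NAMES"]

MTV_THRESHOLD_FRACTION = 0.41

CF_NAMES = [
    "CF_LongAxis",
    "CF_ShortAxis",
    "CF_Volume",
    "CF_SUVmin",
    "CF_SUVmean",
    "CF_SUVmax",
    "CF_MTV",
    "CF_TLG",
]


@dataclass(frozen=True)
class ClinicalFeatureVector:
    long_axis: float  # mm
    short_axis: float  # mm
    volume: float  # cm3
    suv_min: float
    suv_mean: float
    suv_max: float
    mtv: float  # cm3
    tlg: float  # g

    def as_dict(self) -> dict:
        return dict(
            zip(
                CF_NAMES,
                (
                    self.long_axis,
                    self.short_axis,
                    self.volume,
                    self.suv_min,
                    self.suv_mean,
                    self.suv_max,
                    self.mtv,
                    self.tlg,
                ),
            )
        )


def _pca_axis_lengths(mask: np.ndarray, spacing: Sequence[float]) -> tuple:
    """Peak-to-peak extents of masked voxel centres along PCA axes, + 1 voxel.

    Adding the mean voxel width accounts for voxels being cells rather than
    points, so a single voxel reports its physical size and a digitized
    sphere of radius r reports ~2r.
    """
    coords = np.argwhere(mask) * np.asarray(spacing)
    coords = coords - coords.mean(axis=0)
    voxel = float(np.mean(spacing))
    if len(coords) == 1:
        return voxel, voxel
    # principal axes of the voxel-centre cloud
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    proj = coords @ vt.T
    extents = np.sort(proj.max(axis=0) - proj.min(axis=0))[::-1]
    return float(extents[0] + voxel), float(extents[-1] + voxel)


def compute_clinical_features(
    pet_suv: ImageVolume,
    mask: np.ndarray,
    spacing: Sequence[float] | None = None,
    mtv_threshold: float | None = MTV_THRESHOLD_FRACTION,
) -> ClinicalFeatureVector:
    """Compute the CF vector for one lesion.

    Parameters
    ----------
    pet_suv:
        PET volume in SUV units.
    mask:
        Binary lesion mask aligned to the PET grid.
    mtv_threshold:
        Fraction of SUVmax defining the MTV region; ``None`` switches to
        whole-mask MTV.
    """
    if pet_suv.units != UNITS_SUV:
        raise ValueError("PET volume must be in SUV units")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = spacing or pet_suv.spacing
    voxel_cm3 = float(np.prod(spacing)) / 1000.0

    values = pet_suv.voxels[mask]
    suv_min = float(values.min())
    suv_mean = float(values.mean())
    suv_max = float(values.max())
    volume = float(mask.sum()) * voxel_cm3
    long_axis, short_axis = _pca_axis_lengths(mask, spacing)

    if suv_max <= 0:
        warnings.warn("SUVmax <= 0; MTV and TLG set to 0", stacklevel=2)
        mtv, tlg = 0.0, 0.0
    else:
        if mtv_threshold is None:
            region = mask
        else:
            region = mask & (pet_suv.voxels >= mtv_threshold * suv_max)
        mtv = float(region.sum()) * voxel_cm3
        tlg = float(pet_suv.voxels[region].mean()) * mtv if mtv > 0 else 0.0

    return ClinicalFeatureVector(
        long_axis=long_axis,
        short_axis=short_axis,
        volume=volume,
        suv_min=suv_min,
        suv_mean=suv_mean,
        suv_max=suv_max,
        mtv=mtv,
        tlg=tlg,
    )
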