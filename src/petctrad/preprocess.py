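"""Volume harmonization and 2.5D patch preparation.

CT volumes are resampled to isotropic 1 mm voxels and clamped to the
[-200, 300] HU window; PET volumes are resampled likewise and converted
from activity concentration to body-weight SUV.  For the 2.5D stage, the
central slice (largest in-plane tumor area) is taken in each of the three
orthogonal planes and cropped to a square, margin-padded, min-max-scaled
patch: 64x64 for CT and 128x128 for PET.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .types import (
    CT_PATCH_SIZE,
    PET_PATCH_SIZE,
    PLANE_AXIS,
    PLANES,
    ImageVolume,
    LesionSample,
    PatchSet,
    UNITS_BQML,
    UNITS_SUV,
)

__all__ = [
    "resample_isotropic",
    "resample_mask",
    "window_ct",
    "to_suv",
    "central_orthogonal_slices",
    "crop_patch",
    "make_patch_set",
    "preprocess_sample",
]

CT_WINDOW = (-200.0, 300.0)


def _zoom_factors(spacing, target):
    return tuple(s / t for s, t in zip(spacing, target))


def resample_isotropic(
    volume: ImageVolume, target_spacing: float = 1.0
) -> ImageVolume:
    """Trilinear resample of an intensity volume to isotropic voxels."""
    if any(n == 0 for n in volume.shape):
        raise ValueError("zero-extent axis")
    target = (target_spacing,) * 3
    if volume.spacing == target:
        return volume
    out = ndimage.zoom(volume.voxels, _zoom_factors(volume.spacing, target), order=1, mode="nearest")
    return volume.with_voxels(out, spacing=target)


def resample_mask(mask: np.ndarray, spacing, target_spacing: float = 1.0) -> np.ndarray:
    """Nearest-neighbour resample so the mask stays binary."""
    target = (target_spacing,) * 3
    if tuple(spacing) == target:
        return mask.astype(bool)
    out = ndimage.zoom(mask.astype(np.uint8), _zoom_factors(spacing, target), order=0, mode="nearest")
    return out.astype(bool)


def window_ct(volume: ImageVolume, lo: float = CT_WINDOW[0], hi: float = CT_WINDOW[1]) -> ImageVolume:
    """Clamp CT intensities to [lo, hi] HU; idempotent."""
    if volume.modality != "CT":
        raise ValueError("window_ct expects a CT volume")
    if lo >= hi:
        raise ValueError(f"invalid window [{lo}, {hi}]")
    return volume.with_voxels(np.clip(volume.voxels, lo, hi))


def to_suv(volume: ImageVolume, weight_kg: float, dose_MBq: float) -> ImageVolume:
    """Convert PET activity concentration to body-weight SUV.

    SUV(v) = C(v)[Bq/mL] * W[g] / D[Bq].  Refuses already-converted input so
    the conversion can never be applied twice.
    """
    if volume.modality != "PET":
        raise ValueError("to_suv expects a PET volume")
    if volume.units == UNITS_SUV:
        raise ValueError("volume is already in SUV units")
    if volume.units != UNITS_BQML:
        raise ValueError(f"unexpected PET units {volume.units!r}")
    if weight_kg <= 0 or dose_MBq <= 0:
        raise ValueError("weight and dose must be positive")
    c_bq_ml = volume.voxels * 1000.0  # kBq/mL -> Bq/mL
    suv = c_bq_ml * (weight_kg * 1000.0) / (dose_MBq * 1e6)
    return volume.with_voxels(suv, units=UNITS_SUV)


def central_orthogonal_slices(
    volume: ImageVolume, mask: np.ndarray
) -> Dict[str, Tuple[int, np.ndarray, np.ndarray]]:
    """Per orthogonal plane: the slice index with the largest in-plane mask area.

    Returns ``{plane: (index, slice_image, in_plane_mask)}``.  Ties break to
    the lowest index (np.argmax convention).
    """
    if not mask.any():
        raise ValueError("empty mask")
    out = {}
    for plane in PLANES:
        axis = PLANE_AXIS[plane]
        areas = mask.sum(axis=tuple(a for a in range(3) if a != axis))
        idx = int(np.argmax(areas))
        out[plane] = (
            idx,
            np.take(volume.voxels, idx, axis=axis),
            np.take(mask, idx, axis=axis),
        )
    return out


def crop_patch(slice_image: np.ndarray, in_plane_mask: np.ndarray, out_size: int) -> np.ndarray:
    """Square bounding-box crop around the mask, resized and scaled to [0, 1].

    The bounding box is padded to a square with a 10% margin; the crop is
    bilinearly resized to ``out_size`` and min-max scaled per patch.
    """
    if not in_plane_mask.any():
        raise ValueError("empty in-plane mask")
    rows = np.flatnonzero(in_plane_mask.any(axis=1))
    cols = np.flatnonzero(in_plane_mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    side = max(r1 - r0, c1 - c0, 3)  # degenerate 1-px boxes padded to 3
    side = int(np.ceil(side * 1.1))  # 10% margin

    # center the square on the bbox center; gather with zero padding so the
    # crop content depends only on the lesion, not on its position.
    rc = (r0 + r1 - 1) / 2.0
    cc = (c0 + c1 - 1) / 2.0
    rs = int(np.round(rc - side / 2.0 + 0.5))
    cs = int(np.round(cc - side / 2.0 + 0.5))
    crop = np.zeros((side, side), dtype=np.float64)
    rlo, rhi = max(rs, 0), min(rs + side, slice_image.shape[0])
    clo, chi = max(cs, 0), min(cs + side, slice_image.shape[1])
    crop[rlo - rs : rhi - rs, clo - cs : chi - cs] = slice_image[rlo:rhi, clo:chi]

    patch = resize(crop, (out_size, out_size), order=1, mode="edge", anti_aliasing=False)
    lo, hi = patch.min(), patch.max()
    if hi > lo:
        patch = (patch - lo) / (hi - lo)
    else:
        patch = np.zeros_like(patch)
    return patch


def make_patch_set(sample: LesionSample) -> PatchSet:
    """The six 2.5D patches of one preprocessed lesion (3 planes x 2 modalities)."""
    ps = PatchSet(lesion_id=sample.lesion_id)
    for modality, volume, size in (
        ("CT", sample.ct, CT_PATCH_SIZE),
        ("PET", sample.pet, PET_PATCH_SIZE),
    ):
        slices = central_orthogonal_slices(volume, sample.mask)
        for plane, (idx, img, msk) in slices.items():
            ps.patches[(modality, plane)] = crop_patch(img, msk, size)
            ps.slice_index[(modality, plane)] = idx
    ps.validate()
    return ps


def preprocess_sample(sample: LesionSample, target_spacing: float = 1.0) -> LesionSample:
    """Full harmonization of one lesion: resample, CT window, SUV conversion."""
    ct = window_ct(resample_isotropic(sample.ct, target_spacing))
    pet = resample_isotropic(sample.pet, target_spacing)
    pet = to_suv(pet, sample.weight_kg, sample.dose_MBq)
    mask = resample_mask(sample.mask, sample.spacing, target_spacing)
    if not mask.any():  # tiny lesion lost to nearest-neighbour: keep largest voxel
        mask = sample.mask
    return LesionSample(
        lesion_id=sample.lesion_id,
        ct=ct,
        pet=pet,
        mask=mask,
        label=sample.label,
        site=sample.site,
        weight_kg=sample.weight_kg,
        dose_MBq=sample.dose_MBq,
    )
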