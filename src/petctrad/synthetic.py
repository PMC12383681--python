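"""Phantom PET/CT cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
lesion classes that differ in PET intratumoral texture heterogeneity (the
planted analogue of GLDM Dependence Entropy) and in metabolic intensity
(SUV level), with overlapping CT appearance, plus a second acquisition
site applying an intensity scale and extra noise to stand in for an
external cohort.

Lesions are ellipsoids — deliberately simple so shape features remain
analytically checkable.  Texture is a Gaussian random field: white noise
smoothed to a target correlation length and renormalized.  A SHORTER
correlation length produces a more heterogeneous lesion and hence a
higher dependence entropy.

The full cohort is a pure function of its :class:`CohortConfig`; per-lesion
seeds are spawned from the master seed.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageVolume, LesionSample, UNITS_BQML, UNITS_HU

__all__ = [
    "ClassParams",
    "SiteShift",
    "CohortConfig",
    "make_lesion_texture",
    "make_case",
    "make_cohort",
    "generate_cohort",
    "DEFAULT_CLASS_PARAMS",
]

#: soft-tissue CT background (breast parenchyma/fat mix) and its noise, HU
CT_BACKGROUND_HU = -60.0
CT_BACKGROUND_SD = 12.0
#: PET background in SUV-equivalent units
PET_BACKGROUND_SUV = 1.0
PET_BACKGROUND_SD = 0.15

#: focal hot spots per lesion (Poisson rate) and their Gaussian width
HOT_SPOT_RATE = 3.0
HOT_SPOT_SIGMA_MM = 1.5

#: injected activity protocol, MBq per kg body weight
DOSE_MBQ_PER_KG = 3.7
#: cohort weight distribution, kg
WEIGHT_MEAN_KG = 59.0
WEIGHT_SD_KG = 8.7


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one lesion class.

    ``texture_corr_len`` is the Gaussian-random-field correlation length
    (mm) of the lesion texture; ``texture_amp`` is the field standard
    deviation as a fraction of the lesion's peak SUV.  When
    ``texture_corr_len_smooth`` is set, the lesion is a spatial half-half
    mixture of a rough field (at ``texture_corr_len``) and a smooth field
    (at the smooth scale) — the multi-scale, high-amplitude structure that
    plants an elevated GLDM dependence entropy in that class.
    """

    suv_peak_mean: float
    suv_peak_sd: float
    texture_corr_len: float
    texture_amp: float
    ct_density_mean: float
    ct_density_sd: float
    axis_range: Tuple[float, float]  # mm, ellipsoid semi-axes (min, max)
    #: second texture scale for the patchy (heterogeneous) class
    texture_corr_len_smooth: float | None = None
    #: per-lesion spread of the texture parameters (lognormal sd for the
    #: correlation length, normal sd for the amplitude); gives the classes
    #: overlapping within-class heterogeneity like real cohorts
    texture_corr_sd_log: float = 0.2
    texture_amp_sd: float = 0.075

    def __post_init__(self) -> None:
        if self.suv_peak_sd < 0 or self.ct_density_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.texture_corr_len <= 0:
            raise ValueError("texture_corr_len must be > 0")
        if self.texture_amp < 0:
            raise ValueError("texture_amp must be >= 0")
        if self.axis_range[0] > self.axis_range[1]:
            raise ValueError("axis_range min must be <= max")


@dataclass(frozen=True)
class SiteShift:
    """Acquisition-site effect: multiplicative intensity scale + additive noise."""

    name: str
    scale: float = 1.0
    noise_sd: float = 0.0  # SUV-equivalent for PET; HU for CT


# Default class parameters.  The DLBCL-like class is hotter and markedly more
# heterogeneous: higher-amplitude uptake texture mixing a rough and a smooth
# spatial scale (diffuse infiltration with metabolic niches).  The IDC-like
# class has milder, single-scale texture.  CT densities overlap heavily so CT
# carries little class signal.  Both classes get a shared focal-hot-spot
# nuisance so simple order statistics (SUV range/max) stay noisy.
DEFAULT_CLASS_PARAMS = {
    1: ClassParams(  # DLBCL-like
        suv_peak_mean=8.6,
        suv_peak_sd=1.8,
        texture_corr_len=1.3,
        texture_corr_len_smooth=4.7,
        texture_amp=0.53,
        ct_density_mean=42.0,
        ct_density_sd=8.0,
        axis_range=(5.0, 11.0),
    ),
    0: ClassParams(  # IDC-like
        suv_peak_mean=7.9,
        suv_peak_sd=1.8,
        texture_corr_len=1.35,
        texture_amp=0.28,
        ct_density_mean=38.0,
        ct_density_sd=8.0,
        axis_range=(5.0, 11.0),
    ),
}

#: the external site emulates a second scanner: global intensity scale plus
#: additive reconstruction noise (SUV-equivalent)
DEFAULT_SITES = (SiteShift("internal", 1.0, 0.0), SiteShift("external", 0.92, 0.23))


@dataclass(frozen=True)
class CohortConfig:
    """Fully determines a phantom cohort (two classes x sites)."""

    n_per_class_per_site: int = 50
    sites: Tuple[SiteShift, ...] = DEFAULT_SITES
    seed: int = 0
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    volume_shape: Tuple[int, int, int] = (40, 40, 40)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_per_class_per_site < 1:
            raise ValueError("n_per_class_per_site must be >= 1")
        if set(self.class_params) != {0, 1}:
            raise ValueError("exactly two classes (labels 0 and 1) are required")


def make_lesion_texture(
    shape_voxels: Sequence[int],
    corr_len_mm: float,
    amp: float,
    spacing: Sequence[float],
    seed,
) -> np.ndarray:
    """Zero-mean Gaussian random field with sd ``amp`` and correlation length ``corr_len_mm``.

    White noise is Gaussian-smoothed with sigma = corr_len/spacing per axis
    and renormalized to the requested amplitude.
    """
    shape = tuple(int(s) for s in shape_voxels)
    if any(s <= 0 for s in shape):
        raise ValueError(f"non-positive shape {shape}")
    if corr_len_mm <= 0:
        raise ValueError("corr_len_mm must be > 0")
    if amp < 0:
        raise ValueError("amp must be >= 0")
    if amp == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigmas = [corr_len_mm / s for s in spacing]
    field_ = ndimage.gaussian_filter(noise, sigma=sigmas, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ *= amp / sd
    return field_


def _ellipsoid_mask(
    shape: Tuple[int, int, int],
    center: np.ndarray,
    semi_axes_mm: np.ndarray,
    spacing: Sequence[float],
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = np.zeros(shape)
    for g, c, a, sp in zip(grids, center, semi_axes_mm, spacing):
        q += ((g - c) * sp / a) ** 2
    return q <= 1.0


def make_case(
    class_params: ClassParams,
    site_shift: SiteShift,
    spacing: Sequence[float],
    seed,
    volume_shape: Sequence[int] = (40, 40, 40),
    label: int = 1,
    lesion_id: str = "lesion",
) -> LesionSample:
    """Simulate one lesion: ellipsoid mask, textured PET uptake, CT density.

    The PET volume is synthesized in SUV-equivalent units (background ~ 1,
    lesion plateau ~ suv_peak x (1 + texture)) and then converted to an
    activity concentration consistent with the drawn patient weight and
    injected dose, so that body-weight SUV conversion round-trips.  The
    site effect scales intensities and adds noise; it never touches the
    mask or the label.
    """
    shape = tuple(int(s) for s in volume_shape)
    spacing = tuple(float(s) for s in spacing)
    rng = np.random.default_rng(seed)

    lo, hi = class_params.axis_range
    min_mm = np.array([2.0 * s for s in spacing])  # semi-axis >= 2 voxels
    for _attempt in range(100):
        semi_axes = rng.uniform(lo, hi, size=3)
        if np.all(semi_axes >= min_mm):
            break
        # degenerate ellipsoid: regenerate rather than emit a sliver mask
    else:
        semi_axes = np.maximum(min_mm, np.full(3, hi))

    extent_vox = semi_axes / np.asarray(spacing)
    center = np.array(
        [
            rng.uniform(e + 1, s - e - 2) if s - e - 2 > e + 1 else (s - 1) / 2.0
            for e, s in zip(extent_vox, shape)
        ]
    )
    mask = _ellipsoid_mask(shape, center, semi_axes, spacing)

    # PET in SUV-equivalent units; texture parameters drawn per lesion
    suv_peak = max(1.5, rng.normal(class_params.suv_peak_mean, class_params.suv_peak_sd))
    amp = max(0.03, rng.normal(class_params.texture_amp, class_params.texture_amp_sd))
    jitter = lambda c: c * np.exp(rng.normal(0.0, class_params.texture_corr_sd_log))
    if class_params.texture_corr_len_smooth is not None:
        # patchy two-scale mixture: rough and smooth niches split by an
        # independent coarse field
        patches = make_lesion_texture(shape, 8.0, 1.0, spacing, rng.integers(0, 2**31 - 1)) > 0
        rough = make_lesion_texture(
            shape, jitter(class_params.texture_corr_len), amp, spacing, rng.integers(0, 2**31 - 1)
        )
        smooth = make_lesion_texture(
            shape,
            jitter(class_params.texture_corr_len_smooth),
            amp,
            spacing,
            rng.integers(0, 2**31 - 1),
        )
        texture = np.where(patches, rough, smooth)
    else:
        texture = make_lesion_texture(
            shape, jitter(class_params.texture_corr_len), amp, spacing, rng.integers(0, 2**31 - 1)
        )
    lesion_uptake = suv_peak * (1.0 + texture)

    # focal hot spots (shared nuisance in both classes)
    voxels_in = np.argwhere(mask)
    for _ in range(rng.poisson(HOT_SPOT_RATE)):
        c = voxels_in[rng.integers(len(voxels_in))]
        blob = np.zeros(shape)
        blob[tuple(c)] = 1.0
        blob = ndimage.gaussian_filter(blob, HOT_SPOT_SIGMA_MM)
        blob /= blob.max()
        lesion_uptake = lesion_uptake + rng.uniform(0.3, 1.0) * suv_peak * blob

    pet_suv = PET_BACKGROUND_SUV + rng.normal(0.0, PET_BACKGROUND_SD, size=shape)
    pet_suv = np.where(mask, np.maximum(lesion_uptake, 0.2), pet_suv)
    pet_suv = np.maximum(pet_suv, 0.0)

    # CT in HU
    ct_density = rng.normal(class_params.ct_density_mean, class_params.ct_density_sd)
    ct = CT_BACKGROUND_HU + rng.normal(0.0, CT_BACKGROUND_SD, size=shape)
    ct = np.where(mask, ct_density + 0.3 * rng.normal(0.0, CT_BACKGROUND_SD, size=shape), ct)

    # site effect on intensities only
    pet_suv = pet_suv * site_shift.scale + rng.normal(0.0, site_shift.noise_sd, size=shape)
    pet_suv = np.maximum(pet_suv, 0.0)
    ct = ct * site_shift.scale + rng.normal(0.0, 10.0 * site_shift.noise_sd, size=shape)

    # clinical metadata and SUV -> activity concentration (kBq/mL):
    # SUV = C[Bq/mL] * W[g] / D[Bq]  =>  C[kBq/mL] = SUV * D[Bq] / W[g] / 1000
    weight_kg = float(np.clip(rng.normal(WEIGHT_MEAN_KG, WEIGHT_SD_KG), 38.0, 95.0))
    dose_MBq = DOSE_MBQ_PER_KG * weight_kg
    conc_kbq_ml = pet_suv * (dose_MBq * 1e6) / (weight_kg * 1000.0) / 1000.0

    return LesionSample(
        lesion_id=lesion_id,
        ct=ImageVolume(ct, spacing, "CT", UNITS_HU),
        pet=ImageVolume(conc_kbq_ml, spacing, "PET", UNITS_BQML),
        mask=mask,
        label=label,
        site=site_shift.name,
        weight_kg=weight_kg,
        dose_MBq=dose_MBq,
    )


def generate_cohort(config: CohortConfig) -> List[LesionSample]:
    """All lesions of a cohort, in memory, deterministically from the config."""
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_per_class_per_site * 2 * len(config.sites)
    children = ss.spawn(n_total)
    samples: List[LesionSample] = []
    i = 0
    for site in config.sites:
        for label in sorted(config.class_params):
            params = config.class_params[label]
            for k in range(config.n_per_class_per_site):
                lesion_id = f"{site.name}_c{label}_{k:03d}"
                samples.append(
                    make_case(
                        params,
                        site,
                        config.spacing,
                        children[i],
                        volume_shape=config.volume_shape,
                        label=label,
                        lesion_id=lesion_id,
                    )
                )
                i += 1
    return samples


def make_cohort(config: CohortConfig, out_dir: str, overwrite: bool = False) -> pd.DataFrame:
    """Write a cohort to disk (NIfTI pairs + masks) and return its manifest.

    The manifest CSV has one row per lesion with columns ``lesion_id, site,
    label, weight_kg, dose_MBq, ct_path, pet_path, mask_path``.
    """
    from . import io as wio

    if os.path.exists(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"output directory {out_dir!r} exists; pass overwrite=True")
    os.makedirs(out_dir, exist_ok=True)

    rows = []
    for sample in generate_cohort(config):
        paths = {}
        for kind, vol in (("ct", sample.ct), ("pet", sample.pet)):
            path = os.path.join(out_dir, f"{sample.lesion_id}_{kind}.nii.gz")
            wio.write_volume(vol, path)
            paths[f"{kind}_path"] = path
        mask_path = os.path.join(out_dir, f"{sample.lesion_id}_mask.nii.gz")
        wio.write_mask(sample.mask, sample.spacing, mask_path)
        rows.append(
            dict(
                lesion_id=sample.lesion_id,
                site=sample.site,
                label=sample.label,
                weight_kg=sample.weight_kg,
                dose_MBq=sample.dose_MBq,
                ct_path=paths["ct_path"],
                pet_path=paths["pet_path"],
                mask_path=mask_path,
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def manifest_checksum(manifest: pd.DataFrame) -> str:
    """Stable hash of manifest content plus all referenced voxel data."""
    h = hashlib.sha256()
    h.update(manifest.drop(columns=[c for c in manifest.columns if c.endswith("_path")]).to_csv(index=False).encode())
    from . import io as wio

    for _, row in manifest.iterrows():
        for col in ("ct_path", "pet_path", "mask_path"):
            vol = wio.read_volume(row[col], modality="CT")
            h.update(np.ascontiguousarray(vol.voxels).tobytes())
    return h.hexdigest()
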