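"""Traditional-image-feature (TIF) extraction for preprocessed lesions.

For each modality the configured filter bank is applied and every
resulting image contributes first-order plus the five matrix-family
feature sets; shape features come from the original mask only.  Feature
names follow the canonical grammar ``<MOD>_<FILTER>_<family>_<Feature>``
(e.g. ``PET_LBP-2D_gldm_DependenceEntropy``) and columns are emitted in a
deterministic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ..types import LesionSample
from .discretize import discretize
from .filters import apply_filter
from .firstorder import first_order_features
from .matrices import build_texture_matrix
from .shape import shape_features
from .texture_features import FAMILY_SIZES, texture_features

__all__ = ["FeatureConfig", "extract_tifs", "extract_cohort_tifs", "n_tif_columns"]

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")
N_FIRSTORDER = 18
N_SHAPE = 8


@dataclass(frozen=True)
class FeatureConfig:
    """Filter bank and discretization settings for TIF extraction.

    Defaults use the original image plus the LBP-2D transform — the two
    filters behind the headline dependence-entropy biomarkers.  The
    ``full()`` preset adds the wavelet bank and Laplacian-of-Gaussian.

    Discretization: fixed bin width on original images (0.25 SUV for PET,
    25 HU for CT), bin width 1 on integer LBP codes, and a fixed 32-bin
    count on wavelet/LoG outputs whose scale is lesion-dependent.
    """

    filters: Tuple[str, ...] = ("original", "lbp-2d")
    bin_width_pet: float = 0.25
    bin_width_ct: float = 25.0
    lbp_bin_width: float = 1.0
    filtered_bin_count: int = 32
    log_sigmas: Tuple[float, ...] = (2.0,)
    gldm_alpha: float = 0.0
    families: Tuple[str, ...] = TEXTURE_FAMILIES

    @classmethod
    def full(cls) -> "FeatureConfig":
        return cls(filters=("original", "lbp-2d", "wavelet", "log"))

    def discretization_for(self, modality: str, filter_token: str) -> Tuple[str, float]:
        if filter_token == "original":
            return "width", self.bin_width_pet if modality == "PET" else self.bin_width_ct
        if filter_token == "LBP-2D":
            return "width", self.lbp_bin_width
        return "count", float(self.filtered_bin_count)

    def n_images(self) -> int:
        """Number of filtered images per modality (original counts as one)."""
        n = 0
        for f in self.filters:
            if f == "original" or f == "lbp-2d":
                n += 1
            elif f == "wavelet":
                n += 8
            elif f == "log":
                n += len(self.log_sigmas)
        return n


def n_tif_columns(config: FeatureConfig) -> int:
    """Documented column-count formula for one cohort table.

    Per modality: shape (original mask only) + per filtered image
    (first-order + configured texture families); two modalities total.
    """
    per_image = N_FIRSTORDER + sum(FAMILY_SIZES[f] for f in config.families)
    return 2 * (N_SHAPE + config.n_images() * per_image)


def _image_features(
    volume: np.ndarray,
    mask: np.ndarray,
    modality: str,
    filter_token: str,
    config: FeatureConfig,
) -> Dict[str, float]:
    mode, param = config.discretization_for(modality, filter_token)
    values = volume[mask]
    feats: Dict[str, float] = {}
    fo_width = param if mode == "width" else max((values.max() - values.min()) / param, 1e-12)
    for name, val in first_order_features(values, bin_width=fo_width).items():
        feats[f"{modality}_{filter_token}_firstorder_{name}"] = val
    roi = discretize(volume, mask, mode=mode, param=param)
    for family in config.families:
        M = build_texture_matrix(roi, family, alpha=config.gldm_alpha)
        for name, val in texture_features(M).items():
            feats[f"{modality}_{filter_token}_{family}_{name}"] = val
    return feats


def extract_tifs(
    sample: LesionSample,
    config: FeatureConfig = FeatureConfig(),
    modalities: Tuple[str, ...] = ("CT", "PET"),
) -> Dict[str, float]:
    """All TIFs of one preprocessed lesion (PET in SUV, CT windowed, 1 mm grid)."""
    feats: Dict[str, float] = {}
    for modality, volume in (("CT", sample.ct), ("PET", sample.pet)):
        if modality not in modalities:
            continue
        for name, val in shape_features(sample.mask, sample.spacing).items():
            feats[f"{modality}_original_shape_{name}"] = val
        for filter_spec in config.filters:
            images = apply_filter(
                volume.voxels, filter_spec, spacing=sample.spacing, log_sigmas=config.log_sigmas
            )
            for token, img in images.items():
                feats.update(_image_features(img, sample.mask, modality, token, config))
    return {k: feats[k] for k in sorted(feats)}


def extract_cohort_tifs(
    samples: Sequence[LesionSample],
    config: FeatureConfig = FeatureConfig(),
    modalities: Tuple[str, ...] = ("CT", "PET"),
) -> pd.DataFrame:
    """TIF table for a cohort; non-finite entries are median-imputed with a warning.

    ``modalities`` can restrict extraction (e.g. PET only) for partial runs.
    """
    rows: List[Dict[str, float]] = []
    ids = []
    for s in samples:
        rows.append(extract_tifs(s, config, modalities=modalities))
        ids.append(s.lesion_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="lesion_id"))
    bad = ~np.isfinite(table.to_numpy())
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-finite feature values median-imputed", stacklevel=2
        )
        table = table.replace([np.inf, -np.inf], np.nan)
        table = table.apply(lambda c: c.fillna(c.median()), axis=0)
    table["label"] = [s.label for s in samples]
    table["site"] = [s.site for s in samples]
    return table
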