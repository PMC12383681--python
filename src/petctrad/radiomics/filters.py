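"""Image filter bank for filtered-image texture extraction.

Three filter types feed the texture pipeline alongside the original
volume:

* ``wavelet``: one-level separable stationary 3D wavelet decomposition
  (coif1), producing the 8 sub-band images LLL..HHH at the original grid
  so the lesion mask applies unchanged;
* ``log``: Laplacian-of-Gaussian at each configured sigma (mm);
* ``lbp-2d``: rotation-invariant uniform local binary patterns (P=8, R=1)
  computed slice-wise along the axial axis and restacked to a volume.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

__all__ = ["apply_filter", "wavelet_bands", "log_filtered", "lbp_2d"]

WAVELET = "coif1"


def wavelet_bands(volume: np.ndarray) -> Dict[str, np.ndarray]:
    """8 stationary wavelet sub-bands (keys 'LLL'..'HHH'), same shape as input."""
    x = np.asarray(volume, dtype=np.float64)
    pads = [(0, s % 2) for s in x.shape]  # swt needs even extents
    xp = np.pad(x, pads, mode="edge")
    coeffs = pywt.swtn(xp, WAVELET, level=1, norm=True)[0]
    out = {}
    for key, band in coeffs.items():
        name = key.replace("a", "L").replace("d", "H")
        out[name] = band[tuple(slice(0, s) for s in x.shape)]
    return out


def log_filtered(volume: np.ndarray, sigma_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Laplacian of Gaussian at scale sigma (mm), spacing-aware.

    The truncated derivative kernel has a small DC leak; subtracting the
    response to a unit volume makes constants map to exactly zero.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(volume, dtype=np.float64)
    sigmas = [sigma_mm / s for s in spacing]
    out = ndimage.gaussian_laplace(x, sigma=sigmas)
    dc = ndimage.gaussian_laplace(np.ones_like(x), sigma=sigmas)
    return out - x.mean() * dc


def lbp_2d(volume: np.ndarray, p: int = 8, r: float = 1.0) -> np.ndarray:
    """Rotation-invariant uniform LBP applied per axial slice (axis 2).

    Slices are edge-padded by R before coding so border pixels get
    well-defined neighbourhoods (a constant slice maps to a single code).
    """
    import warnings as _warnings

    x = np.asarray(volume, dtype=np.float64)
    pad = int(np.ceil(r))
    out = np.empty_like(x)
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*local_binary_pattern.*")
        for k in range(x.shape[2]):
            padded = np.pad(x[:, :, k], pad, mode="edge")
            codes = local_binary_pattern(padded, P=p, R=r, method="uniform")
            out[:, :, k] = codes[pad:-pad, pad:-pad]
    return out


def apply_filter(
    volume: np.ndarray,
    filter_spec: str,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    log_sigmas: Sequence[float] = (2.0,),
) -> Dict[str, np.ndarray]:
    """Apply one filter; returns ``{filter_token: filtered_volume}``.

    Filter tokens are the canonical feature-name components, e.g.
    ``wavelet-LLH`` or ``log-sigma-2-0-mm``.
    """
    if filter_spec == "original":
        return {"original": np.asarray(volume, dtype=np.float64)}
    if filter_spec == "wavelet":
        return {f"wavelet-{k}": v for k, v in wavelet_bands(volume).items()}
    if filter_spec == "log":
        out = {}
        for s in log_sigmas:
            token = "log-sigma-" + f"{s:g}".replace(".", "-") + "-mm"
            out[token] = log_filtered(volume, s, spacing)
        return out
    if filter_spec == "lbp-2d":
        return {"LBP-2D": lbp_2d(volume)}
    raise ValueError(f"unknown filter {filter_spec!r}")
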