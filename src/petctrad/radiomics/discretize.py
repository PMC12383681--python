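"""Gray-level discretization of masked intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Gray levels 1..Ng assigned to the masked voxels of a volume.

    ``levels`` matches the volume shape with 0 outside the mask; ``Ng`` is
    the number of occupied-or-lower levels (max assigned level).
    """

    levels: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(volume: np.ndarray, mask: np.ndarray, mode: str = "width", param: float = 0.25) -> DiscretizedROI:
    """Assign integer gray levels to masked voxels.

    mode="width": fixed bin width ``param``; level = floor((x - min)/w) + 1
    (the maximum value is clamped into the top bin).
    mode="count": fixed number of bins ``param``.
    A constant ROI yields the single level 1 (Ng = 1).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if param <= 0:
        raise ValueError("param must be > 0")
    x = np.asarray(volume, dtype=np.float64)
    vals = x[mask]
    lo, hi = vals.min(), vals.max()

    levels = np.zeros(x.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return DiscretizedROI(levels, mask, 1, np.array([lo, lo + param]))

    if mode == "width":
        w = float(param)
        lv = np.floor((vals - lo) / w).astype(np.int64) + 1
        ng = int(np.floor((hi - lo) / w)) + 1
        lv = np.minimum(lv, ng)  # clamp x == bin edge of top
        edges = lo + w * np.arange(ng + 1)
    elif mode == "count":
        ng = int(param)
        w = (hi - lo) / ng
        lv = np.floor((vals - lo) / w).astype(np.int64) + 1
        lv = np.minimum(lv, ng)
        edges = lo + w * np.arange(ng + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    levels[mask] = lv
    return DiscretizedROI(levels, mask, int(lv.max()), edges)
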