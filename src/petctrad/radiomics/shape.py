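"""Shape features of the binary lesion mask (voxel-based)."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = ["shape_features"]


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of mask faces exposed to background (face counting)."""
    area = 0.0
    voxel = float(np.prod(spacing))
    padded = np.pad(mask, 1)
    for axis in range(3):
        face = voxel / spacing[axis]
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * face
    return area


def shape_features(mask: np.ndarray, spacing: Sequence[float]) -> Dict[str, float]:
    """Volume, surface area, sphericity, diameters, axis lengths, elongation, flatness.

    Sphericity = pi^(1/3) (6V)^(2/3) / A.  Axis lengths follow the
    covariance-eigenvalue convention (4 sqrt(lambda)); elongation and
    flatness are square roots of eigenvalue ratios relative to the major
    axis.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxel = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel
    area = _surface_area(mask, spacing)

    coords = np.argwhere(mask) * spacing
    if n > 3:
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar) voxel sets
            hull_pts = coords
    else:
        hull_pts = coords
    max_diam = float(pdist(hull_pts).max()) if len(hull_pts) > 1 else float(spacing.mean())

    centered = coords - coords.mean(axis=0)
    if n > 1:
        ev = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1]
        ev = np.maximum(ev, 0.0)
    else:
        ev = np.zeros(3)
    major = float(4.0 * np.sqrt(ev[0]))
    minor = float(4.0 * np.sqrt(ev[1]))
    elongation = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0
    flatness = float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 1.0

    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "Sphericity": float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area),
        "Maximum3DDiameter": max_diam,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": elongation,
        "Flatness": flatness,
    }
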