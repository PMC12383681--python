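"""First-order intensity statistics (18 features, IBSI set)."""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy import stats

__all__ = ["first_order_features"]

EPS = 1e-16


def first_order_features(values: np.ndarray, bin_width: float = 0.25) -> Dict[str, float]:
    """The 18 first-order features of the masked intensities.

    ``bin_width`` controls the histogram used for Entropy and Uniformity;
    a constant ROI has entropy 0 and uniformity 1.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty value set")
    n = x.size
    mean = float(x.mean())
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized histogram for entropy/uniformity
    if x.max() == x.min():
        p_hist = np.array([1.0])
    else:
        nbins = int(np.floor((x.max() - x.min()) / bin_width)) + 1
        counts, _ = np.histogram(x, bins=nbins, range=(x.min(), x.min() + nbins * bin_width))
        p_hist = counts[counts > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    f: Dict[str, float] = {
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p_hist * np.log2(p_hist + EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "StandardDeviation": float(x.std()),
        "Skewness": float(stats.skew(x)) if x.std() > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x)) if x.std() > 0 else 0.0,  # excess
        "Variance": float(x.var()),
        "Uniformity": float(np.sum(p_hist**2)),
    }
    return f
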