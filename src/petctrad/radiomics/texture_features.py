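"""Texture features from the five matrix families.

Formulas follow the image biomarker standardization initiative (IBSI)
definitions.  Entropies use log base 2 with eps = 1e-16 inside the
logarithm so empty bins are well-defined.  Counts per family: GLCM 24,
GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .matrices import TextureMatrix

__all__ = ["texture_features", "FAMILY_SIZES"]

EPS = 1e-16

FAMILY_SIZES = {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(p * np.log2(p + EPS)))


def _glcm_features(M: TextureMatrix) -> Dict[str, float]:
    p = M.normalized()
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(px * i))
    mu_y = float(np.sum(py * i))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # diagonal and cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    hxy = _entropy(p)
    hx = _entropy(px)
    hy = _entropy(py)
    pxy_indep = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxy_indep + EPS)))
    hxy2 = float(-np.sum(pxy_indep * np.log2(pxy_indep + EPS)))

    da = float(np.sum(k_diff * p_diff))
    f: Dict[str, float] = {}
    f["Autocorrelation"] = float(np.sum(p * ii * jj))
    f["JointAverage"] = mu_x
    f["ClusterProminence"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 4))
    f["ClusterShade"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 3))
    f["ClusterTendency"] = float(np.sum(p * (ii + jj - mu_x - mu_y) ** 2))
    f["Contrast"] = float(np.sum(p * (ii - jj) ** 2))
    f["Correlation"] = (
        1.0 if sig_x * sig_y == 0 else (float(np.sum(p * ii * jj)) - mu_x * mu_y) / (sig_x * sig_y)
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy(p_diff)
    f["DifferenceVariance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    f["JointEnergy"] = float(np.sum(p**2))
    f["JointEntropy"] = hxy
    denom = max(hx, hy)
    f["Imc1"] = 0.0 if denom == 0 else (hxy - hxy1) / denom
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["Idm"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    f["Idmn"] = float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2)))
    f["Id"] = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    f["Idn"] = float(np.sum(p / (1.0 + np.abs(ii - jj) / ng)))
    off = ii != jj
    f["InverseVariance"] = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2))
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float(np.sum(k_sum * p_sum))
    f["SumEntropy"] = _entropy(p_sum)
    f["SumSquares"] = float(np.sum(p * (ii - mu_x) ** 2))
    # maximal correlation coefficient: sqrt of 2nd largest eigenvalue of Q
    if ng == 1:
        f["MCC"] = 1.0
    else:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        px_safe = np.where(px > 0, px, 1.0)
        py_safe = np.where(py > 0, py, 1.0)
        Q = (p / px_safe[:, None]) @ (p / py_safe[None, :]).T
        Q = np.nan_to_num(Q)
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        f["MCC"] = float(np.sqrt(max(0.0, ev[1]))) if len(ev) > 1 else 1.0
    return f


def _run_zone_features(M: TextureMatrix, prefix: dict) -> Dict[str, float]:
    """Shared GLRLM/GLSZM feature algebra over a level x size matrix."""
    P = M.P
    nz = M.Nz
    p = M.normalized()
    ng, ns = P.shape
    ii = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jj = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    pg = P.sum(axis=1)  # per gray level
    ps = P.sum(axis=0)  # per size/length
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))

    f: Dict[str, float] = {}
    f[prefix["small"]] = float(np.sum(P / jj**2) / nz)
    f[prefix["large"]] = float(np.sum(P * jj**2) / nz)
    f["GrayLevelNonUniformity"] = float(np.sum(pg**2) / nz)
    f["GrayLevelNonUniformityNormalized"] = float(np.sum(pg**2) / nz**2)
    f[prefix["nonuni"]] = float(np.sum(ps**2) / nz)
    f[prefix["nonuni"] + "Normalized"] = float(np.sum(ps**2) / nz**2)
    f[prefix["pct"]] = nz / (M.n_voxels * prefix.get("pct_div", 1))
    f["GrayLevelVariance"] = float(np.sum(p * (ii - mu_i) ** 2))
    f[prefix["var"]] = float(np.sum(p * (jj - mu_j) ** 2))
    f[prefix["ent"]] = _entropy(p)
    lg = "LowGrayLevelZoneEmphasis" if prefix["kind"] == "Z" else "LowGrayLevelRunEmphasis"
    hg = "HighGrayLevelZoneEmphasis" if prefix["kind"] == "Z" else "HighGrayLevelRunEmphasis"
    f[lg] = float(np.sum(P / ii**2) / nz)
    f[hg] = float(np.sum(P * ii**2) / nz)
    small, large = prefix["sl"]
    f[small + "LowGrayLevelEmphasis"] = float(np.sum(P / (ii**2 * jj**2)) / nz)
    f[small + "HighGrayLevelEmphasis"] = float(np.sum(P * ii**2 / jj**2) / nz)
    f[large + "LowGrayLevelEmphasis"] = float(np.sum(P * jj**2 / ii**2) / nz)
    f[large + "HighGrayLevelEmphasis"] = float(np.sum(P * ii**2 * jj**2) / nz)
    return f


def _glrlm_features(M: TextureMatrix) -> Dict[str, float]:
    # run percentage uses Np x n_directions since matrices are summed over
    # the 13 directions (each voxel belongs to one run per direction)
    return _run_zone_features(
        M,
        dict(
            kind="R",
            small="ShortRunEmphasis",
            large="LongRunEmphasis",
            nonuni="RunLengthNonUniformity",
            pct="RunPercentage",
            pct_div=M.params.get("n_directions", 13),
            var="RunVariance",
            ent="RunEntropy",
            sl=("ShortRun", "LongRun"),
        ),
    )


def _glszm_features(M: TextureMatrix) -> Dict[str, float]:
    return _run_zone_features(
        M,
        dict(
            kind="Z",
            small="SmallAreaEmphasis",
            large="LargeAreaEmphasis",
            nonuni="SizeZoneNonUniformity",
            pct="ZonePercentage",
            var="ZoneVariance",
            ent="ZoneEntropy",
            sl=("SmallArea", "LargeArea"),
        ),
    )


def _gldm_features(M: TextureMatrix) -> Dict[str, float]:
    P = M.P
    nz = M.Nz
    p = M.normalized()
    ng, nd = P.shape
    ii = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    jj = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))

    f: Dict[str, float] = {}
    f["SmallDependenceEmphasis"] = float(np.sum(P / jj**2) / nz)
    f["LargeDependenceEmphasis"] = float(np.sum(P * jj**2) / nz)
    f["GrayLevelNonUniformity"] = float(np.sum(pg**2) / nz)
    f["DependenceNonUniformity"] = float(np.sum(pd_**2) / nz)
    f["DependenceNonUniformityNormalized"] = float(np.sum(pd_**2) / nz**2)
    f["GrayLevelVariance"] = float(np.sum(p * (ii - mu_i) ** 2))
    f["DependenceVariance"] = float(np.sum(p * (jj - mu_j) ** 2))
    f["DependenceEntropy"] = _entropy(p)
    f["LowGrayLevelEmphasis"] = float(np.sum(P / ii**2) / nz)
    f["HighGrayLevelEmphasis"] = float(np.sum(P * ii**2) / nz)
    f["SmallDependenceLowGrayLevelEmphasis"] = float(np.sum(P / (ii**2 * jj**2)) / nz)
    f["SmallDependenceHighGrayLevelEmphasis"] = float(np.sum(P * ii**2 / jj**2) / nz)
    f["LargeDependenceLowGrayLevelEmphasis"] = float(np.sum(P * jj**2 / ii**2) / nz)
    f["LargeDependenceHighGrayLevelEmphasis"] = float(np.sum(P * ii**2 * jj**2) / nz)
    return f


def _ngtdm_features(M: TextureMatrix) -> Dict[str, float]:
    n_i = M.P[:, 0]
    s_i = M.P[:, 1]
    nvp = n_i.sum()
    ng = len(n_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    p_i = n_i / nvp if nvp > 0 else n_i
    present = p_i > 0
    ngp = int(present.sum())

    f: Dict[str, float] = {}
    denom = float(np.sum(p_i * s_i))
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp <= 1:
        f["Contrast"] = 0.0
    else:
        pij = np.outer(p_i, p_i) * (i[:, None] - i[None, :]) ** 2
        f["Contrast"] = float(pij.sum() / (ngp * (ngp - 1)) * (s_i.sum() / nvp))
    ipi = i * p_i
    busy_den = float(np.sum(np.abs(ipi[present][:, None] - ipi[present][None, :])))
    f["Busyness"] = denom / busy_den if busy_den > 0 else 0.0
    if ngp == 0 or nvp == 0:
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    else:
        ia, ja = np.meshgrid(i[present], i[present], indexing="ij")
        pa, pb = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        sa, sb = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        f["Complexity"] = float(np.sum(np.abs(ia - ja) * (pa * sa + pb * sb) / (pa + pb)) / nvp)
        s_tot = float(s_i.sum())
        f["Strength"] = (
            float(np.sum((pa + pb) * (ia - ja) ** 2)) / s_tot if s_tot > 0 else 0.0
        )
    return f


_DISPATCH = {
    "GLCM": ("glcm", _glcm_features),
    "GLRLM": ("glrlm", _glrlm_features),
    "GLSZM": ("glszm", _glszm_features),
    "GLDM": ("gldm", _gldm_features),
    "NGTDM": ("ngtdm", _ngtdm_features),
}


def texture_features(M: TextureMatrix) -> Dict[str, float]:
    """All features of one matrix family, keyed by canonical feature name."""
    if M.Nz == 0 or M.P.size == 0:
        raise ValueError(f"empty {M.kind} matrix")
    family, fn = _DISPATCH[M.kind]
    feats = fn(M)
    assert len(feats) == FAMILY_SIZES[family]
    return feats
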