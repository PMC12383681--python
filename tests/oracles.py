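"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain voxel/neighbour loops straight from
the matrix definitions, deliberately sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
DIRS_13 = NEIGHBOURS_26[13:]  # lexicographically positive half


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    P = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                for d in DIRS_13:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0:
                        j = levels[q]
                        P[i - 1, j - 1] += 1
                        P[j - 1, i - 1] += 1
    return P


def glrlm_brute(levels: np.ndarray, ng: int, max_len: int) -> np.ndarray:
    R = np.zeros((ng, max_len))
    shape = levels.shape
    for d in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    i = levels[x, y, z]
                    if i == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == i:
                        continue  # not a run start
                    length = 0
                    p = (x, y, z)
                    while _inside(shape, p) and levels[p] == i:
                        length += 1
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    R[i - 1, length - 1] += 1
    return R


def glszm_brute(levels: np.ndarray, ng: int, max_size: int) -> np.ndarray:
    S = np.zeros((ng, max_size))
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBOURS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not seen[q] and levels[q] == i:
                            seen[q] = True
                            stack.append(q)
                S[i - 1, size - 1] += 1
    return S


def gldm_brute(levels: np.ndarray, ng: int, alpha: float = 0.0) -> np.ndarray:
    P = np.zeros((ng, 28))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                dep = 0
                for d in NEIGHBOURS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(i)) <= alpha:
                        dep += 1
                P[i - 1, dep] += 1
    return P


def ngtdm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    P = np.zeros((ng, 2))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                nb = [
                    levels[x + d[0], y + d[1], z + d[2]]
                    for d in NEIGHBOURS_26
                    if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                    and levels[x + d[0], y + d[1], z + d[2]] > 0
                ]
                if not nb:
                    continue
                P[i - 1, 0] += 1
                P[i - 1, 1] += abs(i - sum(nb) / len(nb))
    return P


def gldm_features_brute(levels: np.ndarray, ng: int, alpha: float = 0.0) -> Dict[str, float]:
    """All 14 GLDM features from explicit sums over the brute-force matrix."""
    P = gldm_brute(levels, ng, alpha)
    nz = P.sum()
    f: Dict[str, float] = {}
    sde = lde = gln = glv = dv = de = lgl = hgl = sdl = sdh = ldl = ldh = 0.0
    pj = P.sum(axis=0)
    pi_ = P.sum(axis=1)
    mu_i = sum((i + 1) * pi_[i] for i in range(P.shape[0])) / nz
    mu_j = sum((j + 1) * pj[j] for j in range(P.shape[1])) / nz
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            c = P[i, j]
            if c == 0:
                continue
            gi, dj = i + 1, j + 1
            p = c / nz
            sde += c / dj**2
            lde += c * dj**2
            glv += p * (gi - mu_i) ** 2
            dv += p * (dj - mu_j) ** 2
            de -= p * math.log2(p + 1e-16)
            lgl += c / gi**2
            hgl += c * gi**2
            sdl += c / (gi**2 * dj**2)
            sdh += c * gi**2 / dj**2
            ldl += c * dj**2 / gi**2
            ldh += c * gi**2 * dj**2
    f["SmallDependenceEmphasis"] = sde / nz
    f["LargeDependenceEmphasis"] = lde / nz
    f["GrayLevelNonUniformity"] = sum(v**2 for v in pi_) / nz
    f["DependenceNonUniformity"] = sum(v**2 for v in pj) / nz
    f["DependenceNonUniformityNormalized"] = sum(v**2 for v in pj) / nz**2
    f["GrayLevelVariance"] = glv
    f["DependenceVariance"] = dv
    f["DependenceEntropy"] = de
    f["LowGrayLevelEmphasis"] = lgl / nz
    f["HighGrayLevelEmphasis"] = hgl / nz
    f["SmallDependenceLowGrayLevelEmphasis"] = sdl / nz
    f["SmallDependenceHighGrayLevelEmphasis"] = sdh / nz
    f["LargeDependenceLowGrayLevelEmphasis"] = ldl / nz
    f["LargeDependenceHighGrayLevelEmphasis"] = ldh / nz
    return f


def exact_shapley(fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by direct enumeration of the permutation formula."""
    from itertools import combinations

    M = len(x)

    def v(S):
        X = background.copy()
        if S:
            X[:, list(S)] = x[list(S)]
        return float(np.mean(fn(X)))

    phi = np.zeros(M)
    for i in range(M):
        others = [j for j in range(M) if j != i]
        for r in range(M):
            for S in combinations(others, r):
                w = math.factorial(len(S)) * math.factorial(M - len(S) - 1) / math.factorial(M)
                phi[i] += w * (v(S + (i,)) - v(S))
    return phi


def glcm_features_brute(levels: np.ndarray, ng: int) -> Dict[str, float]:
    """All 24 GLCM features via explicit per-cell loops."""
    P = glcm_brute(levels, ng)
    nz = P.sum()
    p = P / nz
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum(px[i] * ((i + 1) - mu_x) ** 2 for i in range(ng)))
    sig_y = math.sqrt(sum(py[j] * ((j + 1) - mu_y) ** 2 for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]
    eps = 1e-16

    def H(vals):
        return -sum(v * math.log2(v + eps) for v in vals)

    hxy = H(p.ravel())
    hx, hy = H(px), H(py)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j] + eps) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + eps) for i in range(ng) for j in range(ng)
    )
    da = sum(k * v for k, v in p_diff.items())
    f: Dict[str, float] = {}
    f["Autocorrelation"] = sum(p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng))
    f["JointAverage"] = mu_x
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum(
            p[i][j] * ((i + 1) + (j + 1) - mu_x - mu_y) ** power
            for i in range(ng)
            for j in range(ng)
        )
    f["Contrast"] = sum(p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng))
    f["Correlation"] = (
        1.0
        if sig_x * sig_y == 0
        else (f["Autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    )
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = H(list(p_diff.values()))
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["Imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng))
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = sum(k * v for k, v in p_sum.items())
    f["SumEntropy"] = H(list(p_sum.values()))
    f["SumSquares"] = sum(p[i][j] * ((i + 1) - mu_x) ** 2 for i in range(ng) for j in range(ng))
    if ng == 1:
        f["MCC"] = 1.0
    else:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                Q[i, j] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k])
                    for k in range(ng)
                    if px[i] > 0 and py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        f["MCC"] = math.sqrt(max(0.0, ev[1])) if len(ev) > 1 else 1.0
    return f


def _run_zone_features_brute(P: np.ndarray, n_vox: int, zone: bool, pct_div: int = 1) -> Dict[str, float]:
    nz = P.sum()
    ng, ns = P.shape
    pg = [sum(P[i][j] for j in range(ns)) for i in range(ng)]
    ps = [sum(P[i][j] for i in range(ng)) for j in range(ns)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / nz
    mu_j = sum((j + 1) * ps[j] for j in range(ns)) / nz
    eps = 1e-16
    f: Dict[str, float] = {}
    small = sum(P[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    large = sum(P[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    f["SmallAreaEmphasis" if zone else "ShortRunEmphasis"] = small
    f["LargeAreaEmphasis" if zone else "LongRunEmphasis"] = large
    f["GrayLevelNonUniformity"] = sum(v**2 for v in pg) / nz
    f["GrayLevelNonUniformityNormalized"] = sum(v**2 for v in pg) / nz**2
    f["SizeZoneNonUniformity" if zone else "RunLengthNonUniformity"] = sum(v**2 for v in ps) / nz
    f["SizeZoneNonUniformityNormalized" if zone else "RunLengthNonUniformityNormalized"] = (
        sum(v**2 for v in ps) / nz**2
    )
    f["ZonePercentage" if zone else "RunPercentage"] = nz / (n_vox * pct_div)
    f["GrayLevelVariance"] = sum(
        P[i][j] / nz * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(ns)
    )
    f["ZoneVariance" if zone else "RunVariance"] = sum(
        P[i][j] / nz * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(ns)
    )
    f["ZoneEntropy" if zone else "RunEntropy"] = -sum(
        P[i][j] / nz * math.log2(P[i][j] / nz + eps) for i in range(ng) for j in range(ns)
    )
    lg = "LowGrayLevelZoneEmphasis" if zone else "LowGrayLevelRunEmphasis"
    hg = "HighGrayLevelZoneEmphasis" if zone else "HighGrayLevelRunEmphasis"
    f[lg] = sum(P[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    f[hg] = sum(P[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    sa, la = ("SmallArea", "LargeArea") if zone else ("ShortRun", "LongRun")
    f[sa + "LowGrayLevelEmphasis"] = (
        sum(P[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)) / nz
    )
    f[sa + "HighGrayLevelEmphasis"] = (
        sum(P[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    f[la + "LowGrayLevelEmphasis"] = (
        sum(P[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    f[la + "HighGrayLevelEmphasis"] = (
        sum(P[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / nz
    )
    return f


def glrlm_features_brute(levels: np.ndarray, ng: int, n_vox: int) -> Dict[str, float]:
    R = glrlm_brute(levels, ng, max_len=int(np.ceil(np.sqrt(sum(n**2 for n in levels.shape)))) + 1)
    nzcols = [j for j in range(R.shape[1]) if R[:, j].sum() > 0]
    last = max(nzcols) + 1 if nzcols else 1
    return _run_zone_features_brute(R[:, :last], n_vox, zone=False, pct_div=13)


def glszm_features_brute(levels: np.ndarray, ng: int, n_vox: int) -> Dict[str, float]:
    S = glszm_brute(levels, ng, max_size=n_vox)
    nzcols = [j for j in range(S.shape[1]) if S[:, j].sum() > 0]
    last = max(nzcols) + 1 if nzcols else 1
    return _run_zone_features_brute(S[:, :last], n_vox, zone=True)


def ngtdm_features_brute(levels: np.ndarray, ng: int) -> Dict[str, float]:
    P = ngtdm_brute(levels, ng)
    n_i = P[:, 0]
    s_i = P[:, 1]
    nvp = n_i.sum()
    p_i = [n / nvp for n in n_i]
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)
    f: Dict[str, float] = {}
    denom = sum(p_i[i] * s_i[i] for i in range(ng))
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp <= 1:
        f["Contrast"] = 0.0
    else:
        acc = sum(
            p_i[i] * p_i[j] * ((i + 1) - (j + 1)) ** 2 for i in range(ng) for j in range(ng)
        )
        f["Contrast"] = acc / (ngp * (ngp - 1)) * (s_i.sum() / nvp)
    busy_den = sum(
        abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in present for j in present
    )
    f["Busyness"] = denom / busy_den if busy_den > 0 else 0.0
    if ngp == 0 or nvp == 0:
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    else:
        f["Complexity"] = (
            sum(
                abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
                for i in present
                for j in present
            )
            / nvp
        )
        s_tot = s_i.sum()
        f["Strength"] = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in present for j in present) / s_tot
            if s_tot > 0
            else 0.0
        )
    return f
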