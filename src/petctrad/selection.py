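"""Biomarker discovery: four ranking algorithms, top-k feature sets, intersection.

The procedure has three steps: (i) the feature count k is set from the
sample size by the one-in-ten rule; (ii) each of four selectors (mRMR,
chi-square, ReliefF, ANOVA F) ranks every feature block (CT/PET x TIF/DF),
keeping its top k; (iii) within each block the four per-method sets are
intersected, and the per-block intersections are unioned into the
candidate biomarker set.

Clinic features take a different route: a CF survives if its between-class
test is significant (p < alpha) in both the internal and the external
cohort.  Group comparisons gate on Shapiro normality: Welch t for normal
data, Mann-Whitney U otherwise; categorical tables use Fisher's exact test
when any expected cell is below 5, chi-square otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import chi2 as sk_chi2, f_classif

from .io import block_columns

__all__ = [
    "SelectorRanking",
    "CandidateBiomarkerSet",
    "feature_count_rule",
    "rank_features",
    "build_feature_sets",
    "intersect_candidates",
    "significant_cfs",
    "group_compare",
    "METHODS",
]

METHODS = ("mrmr", "chi2", "relieff", "anova")
SELECTION_BLOCKS = ("CT_TIF", "CT_DF", "PET_TIF", "PET_DF")


@dataclass
class SelectorRanking:
    method: str
    features: List[str]  # descending by score
    scores: Dict[str, float]

    def top(self, k: int) -> List[str]:
        return self.features[:k]


@dataclass
class CandidateBiomarkerSet:
    features: List[str]
    provenance: Dict[str, List[str]] = field(default_factory=dict)  # feature -> sets containing it


def feature_count_rule(n_samples: int) -> int:
    """One-in-ten rule: k = floor(n/10), at least 1 (with a warning below n=10)."""
    k = n_samples // 10
    if k < 1:
        warnings.warn(f"n_samples={n_samples} < 10; defaulting to k=1", stacklevel=2)
        return 1
    return k


# ---------------------------------------------------------------------------
# ranking algorithms
# ---------------------------------------------------------------------------


def _order(scores: np.ndarray, names: Sequence[str]) -> Tuple[List[str], Dict[str, float]]:
    """Deterministic ordering: score descending, then name ascending."""
    idx = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return [names[i] for i in idx], {names[i]: float(scores[i]) for i in idx}


def _anova_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _chi2_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Chi-square on min-max scaled, binned features (ensures non-negativity)."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (X - lo) / span
    binned = np.minimum((scaled * n_bins).astype(int), n_bins - 1)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if hi[j] == lo[j]:
            continue
        table = pd.crosstab(binned[:, j], y).to_numpy()
        if table.shape[0] < 2:
            continue
        scores[j] = stats.chi2_contingency(table, correction=False)[0]
    return scores


def _relieff_scores(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """ReliefF weights: margin between nearest hits and nearest misses.

    All samples are used; distances are Manhattan on range-normalized
    features (the classic formulation for continuous attributes).
    """
    n, m = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / span
    w = np.zeros(m)
    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    for i in range(n):
        diff = np.abs(Z - Z[i])  # (n, m)
        dist = diff.sum(axis=1)
        dist[i] = np.inf
        for c in classes:
            members = np.flatnonzero(y == c)
            members = members[members != i]
            kk = min(k_neighbors, len(members))
            if kk == 0:
                continue
            nearest = members[np.argsort(dist[members], kind="stable")[:kk]]
            contrib = diff[nearest].mean(axis=0)
            if c == y[i]:
                w -= contrib
            else:
                w += priors[c] / (1.0 - priors[y[i]]) * contrib
    return w / n


def _quantile_bins(X: np.ndarray, n_bins: int = 4) -> np.ndarray:
    out = np.zeros(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], np.linspace(0, 1, n_bins + 1)[1:-1])
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def _mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """MI (bits) between two discrete vectors via the joint histogram."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    table = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb).astype(float)
    pxy = table / table.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def _mi_against_all(B: np.ndarray, ref: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """MI (bits) of one discrete reference vector against every column of B."""
    n, m = B.shape
    n_ref = int(ref.max()) + 1
    codes = ref[:, None] * n_bins + B  # (n, m) joint codes
    joint = np.empty((m, n_ref * n_bins))
    for v in range(n_ref * n_bins):
        joint[:, v] = (codes == v).sum(axis=0)
    joint /= n
    pr = joint.reshape(m, n_ref, n_bins).sum(axis=2)  # ref marginal per column
    pb = joint.reshape(m, n_ref, n_bins).sum(axis=1)  # bin marginal per column
    indep = (pr[:, :, None] * pb[:, None, :]).reshape(m, n_ref * n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / indep)
    return np.nansum(np.where(joint > 0, terms, 0.0), axis=1)


def _mrmr_order(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> Tuple[List[str], Dict[str, float]]:
    """Greedy mRMR (MID: relevance minus mean redundancy), full permutation.

    Mutual information is computed on 4-bin quantile-discretized features;
    redundancy sums are maintained incrementally so the greedy sweep costs
    one vectorized MI pass per selected feature.  Constant features carry
    no information and are appended last.
    """
    m = X.shape[1]
    const = [j for j in range(m) if X[:, j].max() == X[:, j].min()]
    if const:
        warnings.warn(f"{len(const)} constant features excluded from mRMR MI", stacklevel=2)
    live = [j for j in range(m) if j not in set(const)]
    B = _quantile_bins(X[:, live]) if live else np.zeros((len(y), 0), dtype=np.int64)
    _, y_codes = np.unique(y, return_inverse=True)
    rel = _mi_against_all(B, y_codes) if live else np.array([])

    n_live = len(live)
    live_names = [names[j] for j in live]
    # lexicographic tie-break: argmax on (score, reversed-name-rank)
    name_rank = np.argsort(np.argsort(live_names))
    red_sum = np.zeros(n_live)
    remaining = np.ones(n_live, dtype=bool)
    selected: List[int] = []
    scores: Dict[str, float] = {}
    while remaining.any():
        s = rel - (red_sum / len(selected) if selected else 0.0)
        s = np.where(remaining, s, -np.inf)
        top = s.max()
        cand = np.flatnonzero(s == top)
        best = cand[np.argmin(name_rank[cand])]
        selected.append(best)
        remaining[best] = False
        scores[live_names[best]] = float(top)
        if remaining.any():
            red_sum += _mi_against_all(B, B[:, best])
    order = [live_names[j] for j in selected] + sorted(names[j] for j in const)
    for j in const:
        scores[names[j]] = -np.inf
    return order, scores


def rank_features(X: pd.DataFrame, y: Sequence[int], method: str) -> SelectorRanking:
    """Rank a (standardized) feature table by one of the four selectors."""
    method = method.lower()
    names = list(X.columns)
    Xv = X.to_numpy(dtype=np.float64)
    yv = np.asarray(y)
    if np.isnan(Xv).any():
        raise ValueError("NaN in feature matrix")
    if method == "anova":
        feats, scores = _order(_anova_scores(Xv, yv), names)
    elif method == "chi2":
        feats, scores = _order(_chi2_scores(Xv, yv), names)
    elif method == "relieff":
        feats, scores = _order(_relieff_scores(Xv, yv), names)
    elif method == "mrmr":
        feats, scores = _mrmr_order(Xv, yv, names)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    return SelectorRanking(method=method, features=feats, scores=scores)


# ---------------------------------------------------------------------------
# feature sets and intersection
# ---------------------------------------------------------------------------


def build_feature_sets(
    table: pd.DataFrame,
    k: int | None = None,
    methods: Sequence[str] = METHODS,
    blocks: Sequence[str] = SELECTION_BLOCKS,
) -> Dict[Tuple[str, str], List[str]]:
    """Top-k set per (block, method); k defaults to the one-in-ten rule."""
    if k is None:
        k = feature_count_rule(len(table))
    y = table["label"].to_numpy()
    sets: Dict[Tuple[str, str], List[str]] = {}
    for block in blocks:
        cols = block_columns(table, block)
        if not cols:
            continue
        if len(cols) < k:
            warnings.warn(f"block {block} has {len(cols)} < k={k} features; keeping all", stacklevel=2)
        sub = table[cols]
        for method in methods:
            ranking = rank_features(sub, y, method)
            sets[(block, method)] = ranking.top(min(k, len(cols)))
    return sets


def intersect_candidates(sets: Dict[Tuple[str, str], List[str]]) -> CandidateBiomarkerSet:
    """Intersect per-method sets within each block; union across blocks."""
    blocks = sorted({b for b, _ in sets})
    features: List[str] = []
    provenance: Dict[str, List[str]] = {}
    for block in blocks:
        method_sets = [set(v) for (b, _), v in sorted(sets.items()) if b == block]
        inter = set.intersection(*method_sets) if method_sets else set()
        if not inter:
            warnings.warn(f"empty intersection in block {block}", stacklevel=2)
        for f in sorted(inter):
            if f not in provenance:
                features.append(f)
            provenance.setdefault(f, []).append(block)
    return CandidateBiomarkerSet(features=features, provenance=provenance)


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def group_compare(values, labels=None, kind: str = "continuous"):
    """Two-group comparison; returns (statistic, p).

    Continuous: Shapiro gate on both groups -> Welch t if both normal,
    else Mann-Whitney U (exact for n <= 8 per group, normal approximation
    with tie correction otherwise).  Categorical: ``values`` is a 2x2 (or
    RxC) contingency table; Fisher exact when any expected count < 5.
    """
    if kind == "categorical":
        table = np.asarray(values, dtype=float)
        expected = stats.contingency.expected_freq(table)
        if table.shape == (2, 2) and (expected < 5).any():
            return stats.fisher_exact(table.astype(int))
        res = stats.chi2_contingency(table, correction=False)
        return res[0], res[1]

    v = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels)
    groups = [v[y == c] for c in np.unique(y)]
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a, b = groups
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    normal = all(
        len(np.unique(g)) > 1 and stats.shapiro(g[:5000]).pvalue > 0.05 for g in (a, b)
    )
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significant_cfs(
    cf_internal: pd.DataFrame, cf_external: pd.DataFrame, alpha: float = 0.05
) -> List[str]:
    """CFs significant (p < alpha) between classes in BOTH cohorts."""
    keep = []
    for table in (cf_internal, cf_external):
        if table["label"].nunique() < 2:
            raise ValueError("cohort contains a single class")
    cols = [c for c in cf_internal.columns if c.startswith("CF_")]
    for c in cols:
        ps = []
        for table in (cf_internal, cf_external):
            _, p = group_compare(table[c].to_numpy(), table["label"].to_numpy())
            ps.append(p)
        if all(p < alpha for p in ps):
            keep.append(c)
    return keep
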