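"""Model interpretation: selector importance scores, Kernel SHAP, LIME.

Both attribution methods are implemented here from their definitions
rather than wrapped from an external explainer:

* Kernel SHAP solves the Shapley-kernel-weighted least squares for the
  attribution vector under the efficiency constraint
  ``phi_0 + sum_i phi_i = f(x)``; with every coalition enumerated
  (feasible for the candidate-biomarker scale, M <= 12) the solution
  equals the exact Shapley values.
* LIME fits a weighted ridge surrogate on binary masking perturbations,
  with an exponential kernel on cosine-style mask distance.

Masked features are replaced by values drawn from a background sample;
attributions refer to the model's probability output by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .selection import METHODS, rank_features

__all__ = [
    "AttributionReport",
    "importance_scores",
    "kernel_shap",
    "lime_explain",
    "mean_abs_shap_ranking",
    "EXACT_ENUMERATION_MAX",
]

EXACT_ENUMERATION_MAX = 12


@dataclass
class AttributionReport:
    base_value: float
    attributions: np.ndarray
    model_output: float

    @property
    def residual(self) -> float:
        return abs(self.base_value + float(self.attributions.sum()) - self.model_output)


def importance_scores(
    table: pd.DataFrame, labels: Sequence[int], methods: Sequence[str] = METHODS
) -> Dict[str, List[Tuple[str, float]]]:
    """Per-method descending (feature, score) lists for the candidate set."""
    if table.shape[1] == 0:
        raise ValueError("empty candidate feature set")
    out = {}
    for method in methods:
        ranking = rank_features(table, labels, method)
        out[method] = [(f, ranking.scores[f]) for f in ranking.features]
    return out


def _coalition_value(
    model_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """v(S) per mask row: mean model output with masked-out features drawn
    from the background sample."""
    n_bg = background.shape[0]
    vals = np.empty(len(masks))
    for i, z in enumerate(masks):
        X = np.where(z.astype(bool)[None, :], x[None, :], background)
        vals[i] = float(np.mean(model_fn(X)))
    return vals


def kernel_shap(
    model_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> AttributionReport:
    """Shapley attributions for one instance.

    With ``n_coalitions=None`` and M <= 12 features, all 2^M - 2 proper
    coalitions are enumerated and the result equals exact Shapley values;
    otherwise coalitions are sampled with Shapley-kernel probabilities
    pi(z) = (M-1) / (C(M,|z|) |z| (M-|z|)).  The efficiency constraint is
    imposed by eliminating one coefficient, so local accuracy holds by
    construction.
    """
    x = np.asarray(x, dtype=np.float64)
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    M = x.shape[0]
    if M < 1 or background.shape[0] < 1:
        raise ValueError("need at least one feature and one background row")
    phi0 = float(np.mean(model_fn(background)))
    fx = float(np.mean(model_fn(x[None, :])))
    if M == 1:
        return AttributionReport(phi0, np.array([fx - phi0]), fx)

    exact = n_coalitions is None and M <= EXACT_ENUMERATION_MAX
    if exact:
        masks = []
        weights = []
        for size in range(1, M):
            w = (M - 1) / (comb(M, size) * size * (M - size))
            for S in combinations(range(M), size):
                z = np.zeros(M)
                z[list(S)] = 1
                masks.append(z)
                weights.append(w)
        masks = np.array(masks)
        weights = np.array(weights)
    else:
        if n_coalitions is None:
            n_coalitions = max(2 * M + 4, 512)
        if n_coalitions < M + 2:
            raise ValueError(f"n_coalitions={n_coalitions} underdetermines {M} features")
        rng = np.random.default_rng(seed)
        size_p = np.array([(M - 1) / (s * (M - s)) for s in range(1, M)])
        size_p /= size_p.sum()
        sizes = rng.choice(np.arange(1, M), size=n_coalitions, p=size_p)
        masks = np.zeros((n_coalitions, M))
        for i, s in enumerate(sizes):
            masks[i, rng.choice(M, size=s, replace=False)] = 1
        weights = np.ones(n_coalitions)

    v = _coalition_value(model_fn, x, background, masks)
    # efficiency: phi_M = (fx - phi0) - sum_{i<M} phi_i; substitute out
    target = v - phi0 - masks[:, -1] * (fx - phi0)
    design = masks[:, :-1] - masks[:, -1:][:, [0] * (M - 1)]
    W = np.diag(weights)
    A = design.T @ W @ design
    b = design.T @ W @ target
    phi_rest = np.linalg.solve(A + 1e-12 * np.eye(M - 1), b)
    phi = np.append(phi_rest, (fx - phi0) - phi_rest.sum())
    return AttributionReport(phi0, phi, fx)


def mean_abs_shap_ranking(
    model_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    feature_names: Sequence[str],
    seed: int = 0,
) -> List[Tuple[str, float]]:
    """Global ranking by mean |SHAP| over the given instances."""
    totals = np.zeros(len(feature_names))
    for i, x in enumerate(np.atleast_2d(X)):
        rep = kernel_shap(model_fn, x, background, seed=seed + i)
        totals += np.abs(rep.attributions)
    totals /= len(np.atleast_2d(X))
    order = np.argsort(-totals)
    return [(feature_names[i], float(totals[i])) for i in order]


def lime_explain(
    model_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    n_perturb: int = 1000,
    kernel_width: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Local surrogate weights for one instance.

    Perturbations mask random feature subsets (replaced by background
    draws); the ridge surrogate is fitted with weights
    ``exp(-d^2 / w^2)`` where d is the cosine-style distance between the
    perturbation mask and the all-ones mask, and ``w = 0.75 sqrt(M)`` by
    default.
    """
    x = np.asarray(x, dtype=np.float64)
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    M = x.shape[0]
    if n_perturb < 2 * M:
        warnings.warn(f"n_perturb={n_perturb} < 2M; surrogate may be unstable", stacklevel=2)
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(M)
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 2, size=(n_perturb, M)).astype(float)
    Z[0] = 1.0  # include the instance itself
    bg_rows = background[rng.integers(0, background.shape[0], size=n_perturb)]
    Xp = np.where(Z.astype(bool), x[None, :], bg_rows)
    yp = np.asarray(model_fn(Xp), dtype=np.float64).ravel()

    ones = np.ones(M)
    denom = np.sqrt(Z.sum(axis=1)) * np.sqrt(M)
    cos = np.divide(Z.sum(axis=1), denom, out=np.zeros(len(Z)), where=denom > 0)
    d = 1.0 - cos
    sample_w = np.exp(-(d**2) / kernel_width**2)

    ridge = Ridge(alpha=1.0)
    ridge.fit(Z, yp, sample_weight=sample_w)
    weights = ridge.coef_.copy()
    never_varied = Z.var(axis=0) == 0
    weights[never_varied] = 0.0
    return weights
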