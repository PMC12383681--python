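"""Classifier grid: standardization, stratified CV, ten model families, metrics.

The internal cohort is evaluated with stratified fivefold cross-validation
(normalization fitted inside each training fold — the leakage-free
default), the model is refit on the full internal cohort, and the external
cohort serves as an untouched test set.  Metrics come from the confusion
matrix at probability threshold 0.5 plus the rank-based AUC; confidence
intervals are stratified percentile bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FAMILIES",
    "ModelReport",
    "zscore_fit_apply",
    "stratified_kfold",
    "train_classifier",
    "evaluate_metrics",
    "bootstrap_ci",
    "rank_auc",
    "run_grid",
    "GridResult",
]

#: the ten classifier families
FAMILIES = (
    "tree",
    "lda",
    "logistic",
    "linear_svm",
    "naive_bayes",
    "svm_rbf",
    "knn",
    "ensemble",
    "neural_net",
    "kernel_approx",
)


def zscore_fit_apply(
    train: np.ndarray, *others: np.ndarray
) -> Tuple[List[np.ndarray], Dict[str, np.ndarray]]:
    """Z-score with mean/sd fitted on the training block only.

    Constant training columns are centered and flagged; other blocks are
    transformed with the training parameters (leakage contract).
    """
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    out = [(train - mu) / sd_safe]
    for block in others:
        out.append((block - mu) / sd_safe)
    return out, {"mean": mu, "sd": sd, "constant": flat}


def stratified_kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per sample; stratified, shuffled, seed-deterministic."""
    y = np.asarray(labels)
    if min(np.bincount(y)) < k:
        raise ValueError(f"smallest class has fewer than k={k} members")
    folds = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold
    return folds


def train_classifier(X: np.ndarray, y: Sequence[int], family: str, seed: int = 0):
    """Fit one of the ten families; returned model has ``predict_proba``."""
    y = np.asarray(y)
    if family == "tree":
        model = DecisionTreeClassifier(random_state=seed)
    elif family == "lda":
        model = LinearDiscriminantAnalysis()
    elif family == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=seed)
    elif family == "linear_svm":
        # efficiently trained linear classifier: stochastic solver with a
        # smoothed hinge (modified Huber) so probabilities are available
        model = SGDClassifier(
            loss="modified_huber", max_iter=3000, tol=1e-4, random_state=seed
        )
    elif family == "naive_bayes":
        model = GaussianNB()
    elif family == "svm_rbf":
        model = SVC(kernel="rbf", probability=True, random_state=seed)
    elif family == "knn":
        model = KNeighborsClassifier(n_neighbors=5, weights="distance")
    elif family == "ensemble":
        model = BaggingClassifier(
            DecisionTreeClassifier(random_state=seed), n_estimators=50, random_state=seed
        )
    elif family == "neural_net":
        model = MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=500, random_state=seed
        )
    elif family == "kernel_approx":
        model = make_pipeline(
            RBFSampler(n_components=100, random_state=seed),
            LogisticRegression(max_iter=2000, random_state=seed),
        )
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _proba(model, X: np.ndarray) -> np.ndarray:
    p = model.predict_proba(X)
    return p[:, list(model.classes_).index(1)] if p.ndim == 2 else p


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation with midrank tie handling."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class ModelReport:
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    fn: int
    tn: int
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: Optional[int] = None
    fold_assignments: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("accuracy", "auc", "sensitivity", "specificity", "ppv", "npv", "tp", "fp", "fn", "tn")
        }
        for metric, (lo, hi) in self.ci.items():
            d[f"{metric}_ci_low"], d[f"{metric}_ci_high"] = lo, hi
        return d


def evaluate_metrics(scores, labels, threshold: float = 0.5) -> ModelReport:
    """Confusion-matrix metrics at ``threshold`` plus rank AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    auc = rank_auc(s, y)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())

    def safe(a, b):
        return a / b if b > 0 else 0.0

    return ModelReport(
        accuracy=(tp + tn) / len(y),
        auc=auc,
        sensitivity=safe(tp, tp + fn),
        specificity=safe(tn, tn + fp),
        ppv=safe(tp, tp + fp),
        npv=safe(tn, tn + fn),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Stratified percentile bootstrap CI; degenerate resamples are redrawn."""
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small", stacklevel=2)
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    vals = np.empty(B)
    for b in range(B):
        take = np.concatenate(
            [rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))]
        )
        vals[b] = metric_fn(s[take], y[take])
    alpha = (1 - level) / 2
    return float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha))


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    rows: pd.DataFrame  # one row per (feature_set, family)
    best: Tuple[str, str]  # (feature_set, family)
    best_internal: ModelReport
    best_external: Optional[ModelReport]


def _cv_scores(X, y, family, folds, seed, select_k=None):
    """Out-of-fold probability scores with per-fold normalization (and
    optional per-fold ANOVA top-k selection for honest selection-inside-CV)."""
    from sklearn.feature_selection import SelectKBest, f_classif as f_cls

    oof = np.empty(len(y), dtype=np.float64)
    for fold in np.unique(folds):
        tr, te = folds != fold, folds == fold
        (Xtr, Xte), _ = zscore_fit_apply(X[tr], X[te])
        if select_k is not None and select_k < X.shape[1]:
            sel = SelectKBest(f_cls, k=select_k).fit(Xtr, y[tr])
            Xtr, Xte = sel.transform(Xtr), sel.transform(Xte)
        model = train_classifier(Xtr, y[tr], family, seed)
        oof[te] = _proba(model, Xte)
    return oof


def run_grid(
    table: pd.DataFrame,
    feature_sets: Dict[str, List[str]],
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    internal_site: str = "internal",
    k_folds: int = 5,
    mode: str = "honest",
    select_k: Optional[int] = None,
) -> GridResult:
    """Evaluate every (feature set x family) cell.

    Per cell: stratified fivefold CV on the internal site (normalization —
    and top-k selection when ``select_k`` is given — fitted inside each
    fold in the default "honest" mode; fitted once on the full internal
    cohort in "paper" mode), refit on all internal lesions, test on the
    external site.  Best cell by internal CV AUC, ties broken by accuracy
    then by family order (simpler first).
    """
    internal = table[table["site"] == internal_site]
    external = table[table["site"] != internal_site]
    y_int = internal["label"].to_numpy()
    folds = stratified_kfold(y_int, k=k_folds, seed=seed)

    records = []
    best_key, best_metric, best_reports = None, (-np.inf, -np.inf, np.inf), None
    family_order = {f: i for i, f in enumerate(FAMILIES)}
    for set_name, cols in feature_sets.items():
        X_int = internal[cols].to_numpy(dtype=np.float64)
        X_ext = external[cols].to_numpy(dtype=np.float64) if len(external) else None
        for family in families:
            try:
                if mode == "paper":
                    (Xn, ), _ = zscore_fit_apply(X_int)
                    oof = np.empty(len(y_int))
                    for fold in np.unique(folds):
                        tr, te = folds != fold, folds == fold
                        model = train_classifier(Xn[tr], y_int[tr], family, seed)
                        oof[te] = _proba(model, Xn[te])
                else:
                    oof = _cv_scores(X_int, y_int, family, folds, seed, select_k)
                cv_report = evaluate_metrics(oof, y_int)
                cv_report.seed = seed
                cv_report.fold_assignments = folds
                ext_report = None
                if X_ext is not None and len(X_ext):
                    (Xn_int, Xn_ext), _ = zscore_fit_apply(X_int, X_ext)
                    model = train_classifier(Xn_int, y_int, family, seed)
                    ext_scores = _proba(model, Xn_ext)
                    ext_report = evaluate_metrics(ext_scores, external["label"].to_numpy())
                row = {"feature_set": set_name, "family": family, "n_features": len(cols)}
                row.update({f"cv_{k}": v for k, v in cv_report.as_dict().items()})
                if ext_report:
                    row.update({f"ext_{k}": v for k, v in ext_report.as_dict().items()})
                records.append(row)
                key_metric = (cv_report.auc, cv_report.accuracy, -family_order[family])
                if key_metric > best_metric:
                    best_metric = key_metric
                    best_key = (set_name, family)
                    best_reports = (cv_report, ext_report)
            except Exception as exc:  # a failing cell must not abort the grid
                warnings.warn(f"grid cell ({set_name}, {family}) failed: {exc}", stacklevel=2)
                records.append({"feature_set": set_name, "family": family, "error": str(exc)})
    rows = pd.DataFrame(records)
    return GridResult(rows=rows, best=best_key, best_internal=best_reports[0], best_external=best_reports[1])
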