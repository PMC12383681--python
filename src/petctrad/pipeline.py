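"""End-to-end orchestration: cohort -> features -> selection -> models -> SHAP.

This is the programmatic spine behind the CLI's ``run-all``: each stage is
a plain function over in-memory objects so tests (and the acceptance
study) can run any prefix of the pipeline without touching disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clinical import compute_clinical_features
from .deep import TrainConfig, build_cnn, extract_deep_features, train_cnn
from .io import block_columns
from .modeling import FAMILIES, GridResult, run_grid
from .preprocess import make_patch_set, preprocess_sample
from .radiomics import FeatureConfig, extract_cohort_tifs
from .selection import (
    CandidateBiomarkerSet,
    build_feature_sets,
    feature_count_rule,
    intersect_candidates,
    significant_cfs,
)
from .synthetic import CohortConfig, generate_cohort
from .types import LesionSample, PLANES

__all__ = ["PipelineResult", "extract_feature_table", "run_pipeline", "train_feature_cnns"]


@dataclass
class PipelineResult:
    table: pd.DataFrame
    candidate_set: CandidateBiomarkerSet
    significant_cf: List[str]
    grid: Optional[GridResult] = None
    shap_ranking: Optional[List[Tuple[str, float]]] = None
    cnn_history: Dict[str, list] = field(default_factory=dict)


def train_feature_cnns(
    samples: Sequence[LesionSample],
    patch_sets,
    epochs: int = 5,
    seed: int = 0,
    train_site: str = "internal",
):
    """Fit CNN_CT and CNN_PET on the internal-site patches (all three planes
    of each lesion are independent training samples)."""
    models = {}
    history = {}
    for modality in ("CT", "PET"):
        X, y = [], []
        for s, ps in zip(samples, patch_sets):
            if s.site != train_site:
                continue
            for plane in PLANES:
                X.append(ps.get(modality, plane))
                y.append(s.label)
        model, hist = train_cnn(
            np.asarray(X), y, TrainConfig(epochs=epochs, seed=seed), modality=modality
        )
        models[modality] = model
        history[modality] = hist
    return models["CT"], models["PET"], history


def extract_feature_table(
    samples: Sequence[LesionSample],
    feature_config: FeatureConfig = FeatureConfig(),
    cnn_epochs: int = 5,
    seed: int = 0,
    with_deep: bool = True,
    with_tifs: bool = True,
    modalities: Tuple[str, ...] = ("CT", "PET"),
) -> Tuple[pd.DataFrame, Dict[str, list]]:
    """CF + TIF + DF table for preprocessed lesions (one row per lesion)."""
    parts = []
    cf_rows = []
    for s in samples:
        cf = compute_clinical_features(s.pet, s.mask)
        cf_rows.append(cf.as_dict())
    parts.append(pd.DataFrame(cf_rows, index=[s.lesion_id for s in samples]))

    if with_tifs:
        tifs = extract_cohort_tifs(samples, feature_config, modalities=modalities)
        parts.append(tifs.drop(columns=["label", "site"]))

    history: Dict[str, list] = {}
    if with_deep:
        patch_sets = [make_patch_set(s) for s in samples]
        cnn_ct, cnn_pet, history = train_feature_cnns(
            samples, patch_sets, epochs=cnn_epochs, seed=seed
        )
        df_rows = [extract_deep_features(cnn_ct, cnn_pet, ps) for ps in patch_sets]
        parts.append(pd.DataFrame(df_rows, index=[s.lesion_id for s in samples]))

    table = pd.concat(parts, axis=1)
    table.index.name = "lesion_id"
    table["label"] = [s.label for s in samples]
    table["site"] = [s.site for s in samples]
    return table, history


def _fusion_sets(table: pd.DataFrame, candidate: CandidateBiomarkerSet, cf_keep: List[str]):
    """Feature-set definitions for the experiment grid."""
    sets: Dict[str, List[str]] = {}
    for block in ("CF", "CT_TIF", "CT_DF", "PET_TIF", "PET_DF"):
        cols = block_columns(table, block)
        if cols:
            sets[block] = cols
    fusion = [c for b in ("CF", "CT_TIF", "CT_DF", "PET_TIF", "PET_DF") for c in sets.get(b, [])]
    sets["fusion_all"] = fusion
    if candidate.features or cf_keep:
        sets["candidates"] = list(dict.fromkeys(cf_keep + candidate.features))
    return sets


def run_pipeline(
    config: CohortConfig,
    feature_config: FeatureConfig = FeatureConfig(),
    cnn_epochs: int = 5,
    families: Sequence[str] = ("svm_rbf",),
    with_grid: bool = True,
    with_shap: bool = True,
    grid_select_k: Optional[int] = None,
    shap_instances: int = 24,
) -> PipelineResult:
    """Full study on a synthetic cohort (deterministic in ``config.seed``)."""
    from .modeling import train_classifier, zscore_fit_apply
    from .interpret import mean_abs_shap_ranking

    samples = [preprocess_sample(s) for s in generate_cohort(config)]
    table, history = extract_feature_table(
        samples, feature_config, cnn_epochs=cnn_epochs, seed=config.seed
    )

    k = feature_count_rule(len(table))
    sets = build_feature_sets(table, k=k)
    candidate = intersect_candidates(sets)
    internal = table[table["site"] == "internal"]
    external = table[table["site"] != "internal"]
    cf_cols = block_columns(table, "CF") + ["label"]
    cf_keep = significant_cfs(internal[cf_cols], external[cf_cols]) if len(external) else []

    result = PipelineResult(
        table=table, candidate_set=candidate, significant_cf=cf_keep, cnn_history=history
    )
    if not with_grid:
        return result

    feature_sets = _fusion_sets(table, candidate, cf_keep)
    result.grid = run_grid(
        table, feature_sets, families=families, seed=config.seed, select_k=grid_select_k
    )

    if with_shap and candidate.features:
        cols = result.grid.best[0]
        cand_cols = feature_sets.get("candidates", candidate.features)
        y_int = internal["label"].to_numpy()
        X_int = internal[cand_cols].to_numpy(dtype=np.float64)
        (Xn,), _ = zscore_fit_apply(X_int)
        model = train_classifier(Xn, y_int, "svm_rbf", seed=config.seed)

        def model_fn(Z):
            return model.predict_proba(Z)[:, list(model.classes_).index(1)]

        rng = np.random.default_rng(config.seed)
        bg = Xn[rng.choice(len(Xn), size=min(60, len(Xn)), replace=False)]
        inst = Xn[rng.choice(len(Xn), size=min(shap_instances, len(Xn)), replace=False)]
        result.shap_ranking = mean_abs_shap_ranking(
            model_fn, inst, bg, cand_cols, seed=config.seed
        )
    return result
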