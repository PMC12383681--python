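"""NIfTI and feature-table I/O plus run configuration plumbing."""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import ImageVolume, UNITS_BQML, UNITS_HU, UNITS_SUV

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "read_feature_table",
    "write_feature_table",
    "parse_feature_name",
    "block_columns",
    "RunConfig",
]

_MODALITY_UNITS = {"CT": UNITS_HU, "PET": UNITS_BQML}


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI; spacing goes into the affine diagonal."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def read_volume(path: str, modality: str = "PET", units: Optional[str] = None) -> ImageVolume:
    """Read a NIfTI volume.

    NIfTI does not carry modality or PET unit flags, so the caller states
    them; ``units`` defaults to HU for CT and activity concentration for PET.
    """
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"not a NIfTI path: {path!r}")
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid spacing in {path!r}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return ImageVolume(data, tuple(float(z) for z in zooms), modality, units or _MODALITY_UNITS[modality])


def write_mask(mask: np.ndarray, spacing: Sequence[float], path: str) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, path)


def read_mask(path: str) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    img = nib.load(path)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj) > 0, zooms


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

#: canonical feature-name grammar: <MOD>_<FILTER>_<family>_<Feature>
_TIF_RE = re.compile(r"^(CT|PET)_([A-Za-z0-9.\-]+)_([a-z]+)_([A-Za-z0-9]+)$")
_DF_RE = re.compile(r"^DF_(CT|PET)_(axial|sagittal|coronal)_c(\d+)$")


def parse_feature_name(name: str) -> dict:
    """Parse a canonical feature name into its provenance fields.

    Returns a dict with ``kind`` in {"CF", "TIF", "DF"} plus kind-specific
    fields (modality/filter/family/feature for TIFs, modality/plane/channel
    for DFs).
    """
    if name.startswith("CF_"):
        return {"kind": "CF", "feature": name[3:]}
    m = _DF_RE.match(name)
    if m:
        return {"kind": "DF", "modality": m.group(1), "plane": m.group(2), "channel": int(m.group(3))}
    m = _TIF_RE.match(name)
    if m:
        return {
            "kind": "TIF",
            "modality": m.group(1),
            "filter": m.group(2),
            "family": m.group(3),
            "feature": m.group(4),
        }
    raise ValueError(f"feature name {name!r} does not parse")


#: the five feature blocks of the experiment grid
BLOCKS = ("CF", "CT_TIF", "CT_DF", "PET_TIF", "PET_DF")


def block_columns(table: pd.DataFrame, block: str) -> list:
    """Columns of one feature block (CF, CT_TIF, CT_DF, PET_TIF, PET_DF)."""
    cols = [c for c in table.columns if c not in ("label", "site")]
    if block == "CF":
        return [c for c in cols if c.startswith("CF_")]
    if block == "CT_TIF":
        return [c for c in cols if c.startswith("CT_")]
    if block == "PET_TIF":
        return [c for c in cols if c.startswith("PET_")]
    if block == "CT_DF":
        return [c for c in cols if c.startswith("DF_CT_")]
    if block == "PET_DF":
        return [c for c in cols if c.startswith("DF_PET_")]
    raise ValueError(f"unknown block {block!r}")


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    """Write a lesion x feature table; deterministic column order."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes}")
    meta = [c for c in ("label", "site") if c in table.columns]
    feats = sorted(c for c in table.columns if c not in meta)
    # repr-exact floats so a round trip is bitwise faithful
    table[meta + feats].to_csv(
        path, index=True, index_label="lesion_id", float_format=lambda x: repr(float(x))
    )


def read_feature_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="lesion_id", float_precision="round_trip")
    for required in ("label", "site"):
        if required not in table.columns:
            raise ValueError(f"feature table missing required column {required!r}")
    if table.columns.duplicated().any():
        raise ValueError("duplicate feature names in table")
    for c in table.columns:
        if c not in ("label", "site"):
            parse_feature_name(c)  # raises on malformed names
    return table


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; serialized next to every run's outputs."""

    seed: int = 0
    out_dir: str = "petctrad_run"
    n_per_class_per_site: int = 50
    volume_shape: Tuple[int, int, int] = (40, 40, 40)
    filters: Tuple[str, ...] = ("original", "lbp-2d")
    cnn_epochs: int = 5
    cnn_batch_size: int = 16
    families: Tuple[str, ...] = ("svm_rbf",)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for key in ("volume_shape", "filters", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
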